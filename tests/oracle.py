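"""Independent full-matrix Needleman-Wunsch oracle used by the tests.

Textbook three-state affine-gap global alignment (match +1, mismatch -1,
gap open -2, gap extend -1), written independently of the package's
anchor-composed aligner: one full DP over the whole sequence pair, no
seeding, no segmenting. Returns per-alignment event counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH, MISMATCH, OPEN, EXT = 1, -1, -2, -1
NEG = -(2**40)


@dataclass
class OracleCounts:
    score: int
    matches: int
    mismatches: int
    insertion_runs: int
    deletion_runs: int
    insertion_bases: int
    deletion_bases: int


@njit(cache=True)
def _nw_kernel(av, bv):
    n, m = av.size, bv.size
    M = np.full((n + 1, m + 1), NEG, np.int64)
    X = np.full((n + 1, m + 1), NEG, np.int64)
    Y = np.full((n + 1, m + 1), NEG, np.int64)
    tM = np.zeros((n + 1, m + 1), np.int8)
    tX = np.zeros((n + 1, m + 1), np.int8)
    tY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = OPEN + (i - 1) * EXT
        if i > 1:
            tX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = OPEN + (j - 1) * EXT
        if j > 1:
            tY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if av[i - 1] == bv[j - 1] else MISMATCH
            dm, dx, dy = M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            if dm >= dx and dm >= dy:
                M[i, j] = dm + s
                tM[i, j] = 0
            elif dx >= dy:
                M[i, j] = dx + s
                tM[i, j] = 1
            else:
                M[i, j] = dy + s
                tM[i, j] = 2
            vm, vx, vy = (
                M[i - 1, j] + OPEN,
                X[i - 1, j] + EXT,
                Y[i - 1, j] + OPEN,
            )
            if vm >= vx and vm >= vy:
                X[i, j] = vm
                tX[i, j] = 0
            elif vx >= vy:
                X[i, j] = vx
                tX[i, j] = 1
            else:
                X[i, j] = vy
                tX[i, j] = 2
            hm, hx, hy = (
                M[i, j - 1] + OPEN,
                X[i, j - 1] + OPEN,
                Y[i, j - 1] + EXT,
            )
            if hm >= hx and hm >= hy:
                Y[i, j] = hm
                tY[i, j] = 0
            elif hx >= hy:
                Y[i, j] = hx
                tY[i, j] = 1
            else:
                Y[i, j] = hy
                tY[i, j] = 2

    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    # counts: score, matches, mismatches, ins_runs, del_runs, ins_b, del_b
    out = np.zeros(7, np.int64)
    out[0] = score
    i, j = n, m
    prev = -1
    while i > 0 or j > 0:
        if state == 0:
            if av[i - 1] == bv[j - 1]:
                out[1] += 1
            else:
                out[2] += 1
            state = tM[i, j]
            i -= 1
            j -= 1
            prev = 0
        elif state == 1:
            out[5] += 1
            if prev != 1:
                out[3] += 1
            state = tX[i, j]
            i -= 1
            prev = 1
        else:
            out[6] += 1
            if prev != 2:
                out[4] += 1
            state = tY[i, j]
            j -= 1
            prev = 2
    return out


def nw_align(a: str, b: str) -> OracleCounts:
    """Optimal global alignment counts via full DP."""
    if not a or not b:
        runs_a = 1 if a else 0
        runs_b = 1 if b else 0
        longest = max(len(a), len(b))
        score = (OPEN + (longest - 1) * EXT) if longest else 0
        return OracleCounts(
            score=score,
            matches=0,
            mismatches=0,
            insertion_runs=runs_a,
            deletion_runs=runs_b,
            insertion_bases=len(a),
            deletion_bases=len(b),
        )
    out = _nw_kernel(
        np.frombuffer(a.encode(), np.uint8),
        np.frombuffer(b.encode(), np.uint8),
    )
    return OracleCounts(*[int(x) for x in out])


def mutate(
    rng: np.random.Generator,
    seq: str,
    n_subs: int,
    n_ins: int,
    n_del: int,
    max_indel: int = 8,
) -> str:
    """Random edits, kept clear of the sequence ends."""
    out = list(seq)
    L = len(out)
    positions = rng.choice(
        np.arange(10, L - 10), size=n_subs + n_ins + n_del, replace=False
    )
    subs, ins, dels = np.split(positions, [n_subs, n_subs + n_ins])
    edits = (
        [(int(p), "S") for p in subs]
        + [(int(p), "I") for p in ins]
        + [(int(p), "D") for p in dels]
    )
    for pos, kind in sorted(edits, key=lambda t: -t[0]):
        if kind == "S":
            out[pos] = rng.choice([c for c in "ACGT" if c != out[pos]])
        elif kind == "I":
            length = int(rng.integers(1, max_indel + 1))
            out[pos:pos] = list("".join(rng.choice(list("ACGT"), size=length)))
        else:
            length = int(rng.integers(1, max_indel + 1))
            del out[pos : pos + length]
    return "".join(out)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
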
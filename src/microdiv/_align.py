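"""Affine-gap global alignment primitives.

Scoring: match +1, mismatch -1, gap open -2, gap extend -1 (the first base
of a gap costs the open penalty, each further base the extend penalty).
The DP kernel is numba-compiled; wrappers work on byte strings and return
run-length operations ``[(op, length), ...]`` with op in:

    'M'  aligned column (match or mismatch)
    'I'  base present only in the query (first sequence)
    'D'  base present only in the subject (second sequence)
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2
GAP_EXTEND = -1

_NEG = -(2**30)

# Refuse DP matrices above this many cells; inter-anchor segments are meant
# to be small, so hitting this means the anchor density was too low.
MAX_DP_CELLS = 60_000_000


@njit(cache=True)
def _affine_dp(a, b):  # pragma: no cover - exercised via align_global
    n = a.size
    m = b.size
    M = np.full((n + 1, m + 1), _NEG, np.int32)
    X = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in subject (consumes a)
    Y = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in query (consumes b)
    tM = np.zeros((n + 1, m + 1), np.int8)
    tX = np.zeros((n + 1, m + 1), np.int8)
    tY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
        if i > 1:
            tX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + (j - 1) * GAP_EXTEND
        if j > 1:
            tY[0, j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            best = M[i - 1, j - 1]
            t = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                t = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                t = 2
            M[i, j] = best + s
            tM[i, j] = t

            best = M[i - 1, j] + GAP_OPEN
            t = 0
            if X[i - 1, j] + GAP_EXTEND > best:
                best = X[i - 1, j] + GAP_EXTEND
                t = 1
            if Y[i - 1, j] + GAP_OPEN > best:
                best = Y[i - 1, j] + GAP_OPEN
                t = 2
            X[i, j] = best
            tX[i, j] = t

            best = M[i, j - 1] + GAP_OPEN
            t = 0
            if X[i, j - 1] + GAP_OPEN > best:
                best = X[i, j - 1] + GAP_OPEN
                t = 1
            if Y[i, j - 1] + GAP_EXTEND > best:
                best = Y[i, j - 1] + GAP_EXTEND
                t = 2
            Y[i, j] = best
            tY[i, j] = t

    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2

    ops = np.empty(n + m, np.int8)
    w = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops[w] = 0
            state = tM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[w] = 1
            state = tX[i, j]
            i -= 1
        else:
            ops[w] = 2
            state = tY[i, j]
            j -= 1
        w += 1
    return ops[:w][::-1].copy(), score


@njit(cache=True)
def _semiglobal_dp(a, b):  # pragma: no cover - exercised via align_semiglobal
    """Glocal DP: all of ``a`` against a sub-interval of ``b`` (subject
    overhangs at both ends are free)."""
    n = a.size
    m = b.size
    M = np.full((n + 1, m + 1), _NEG, np.int32)
    X = np.full((n + 1, m + 1), _NEG, np.int32)
    Y = np.full((n + 1, m + 1), _NEG, np.int32)
    tM = np.zeros((n + 1, m + 1), np.int8)
    tX = np.zeros((n + 1, m + 1), np.int8)
    tY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
        if i > 1:
            tX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = 0  # free leading subject overhang
        tY[0, j] = 3
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            best = M[i - 1, j - 1]
            t = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                t = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                t = 2
            M[i, j] = best + s
            tM[i, j] = t

            best = M[i - 1, j] + GAP_OPEN
            t = 0
            if X[i - 1, j] + GAP_EXTEND > best:
                best = X[i - 1, j] + GAP_EXTEND
                t = 1
            if Y[i - 1, j] + GAP_OPEN > best:
                best = Y[i - 1, j] + GAP_OPEN
                t = 2
            X[i, j] = best
            tX[i, j] = t

            best = M[i, j - 1] + GAP_OPEN
            t = 0
            if X[i, j - 1] + GAP_OPEN > best:
                best = X[i, j - 1] + GAP_OPEN
                t = 1
            if Y[i, j - 1] + GAP_EXTEND > best:
                best = Y[i, j - 1] + GAP_EXTEND
                t = 2
            Y[i, j] = best
            tY[i, j] = t

    # free trailing subject overhang: end anywhere on the last row
    j_end = 0
    score = _NEG
    state = 0
    for j in range(m + 1):
        if M[n, j] > score:
            score = M[n, j]
            j_end = j
            state = 0
        if X[n, j] > score:
            score = X[n, j]
            j_end = j
            state = 1
    ops = np.empty(n + m, np.int8)
    w = 0
    i, j = n, j_end
    while i > 0 or j > 0:
        if state == 0:
            if i == 0:
                break
            ops[w] = 0
            state = tM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[w] = 1
            state = tX[i, j]
            i -= 1
        else:
            if tY[i, j] == 3 or i == 0:
                break  # free leading overhang
            ops[w] = 2
            state = tY[i, j]
            j -= 1
        w += 1
    j_start = j
    return ops[:w][::-1].copy(), j_start, j_end, score


_OP_CHARS = ("M", "I", "D")


def _rle(codes) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    for code in codes:
        ch = _OP_CHARS[code]
        if ops and ops[-1][0] == ch:
            ops[-1] = (ch, ops[-1][1] + 1)
        else:
            ops.append((ch, 1))
    return ops


def merge_ops(*op_lists) -> list[tuple[str, int]]:
    """Concatenate run-length op lists, merging adjacent equal ops."""
    out: list[tuple[str, int]] = []
    for ops in op_lists:
        for op, length in ops:
            if length == 0:
                continue
            if out and out[-1][0] == op:
                out[-1] = (op, out[-1][1] + length)
            else:
                out.append((op, length))
    return out


def align_global(a: str, b: str) -> tuple[list[tuple[str, int]], int]:
    """Optimal affine-gap global alignment of two sequences.

    Returns (ops, score). Empty sequences are handled without DP.
    """
    if not a and not b:
        return [], 0
    if not a:
        return [("D", len(b))], GAP_OPEN + (len(b) - 1) * GAP_EXTEND
    if not b:
        return [("I", len(a))], GAP_OPEN + (len(a) - 1) * GAP_EXTEND
    if (len(a) + 1) * (len(b) + 1) > MAX_DP_CELLS:
        raise ValueError(
            f"alignment problem too large ({len(a)} x {len(b)}); "
            "increase anchor density (smaller k) or split the input"
        )
    codes, score = _affine_dp(
        np.frombuffer(a.encode(), np.uint8),
        np.frombuffer(b.encode(), np.uint8),
    )
    return _rle(codes), int(score)


def align_semiglobal(
    query: str, window: str
) -> tuple[list[tuple[str, int]], int, int, int]:
    """Align all of ``query`` against a sub-interval of ``window``.

    Subject overhangs at both ends are free. Returns
    (ops, window_start, window_end, score) where ops cover
    query[0:len(query)] x window[window_start:window_end].
    """
    if not query or not window:
        raise ValueError("semiglobal alignment needs non-empty sequences")
    if (len(query) + 1) * (len(window) + 1) > MAX_DP_CELLS:
        raise ValueError(
            f"alignment problem too large ({len(query)} x {len(window)})"
        )
    codes, j_start, j_end, score = _semiglobal_dp(
        np.frombuffer(query.encode(), np.uint8),
        np.frombuffer(window.encode(), np.uint8),
    )
    return _rle(codes), int(j_start), int(j_end), int(score)


def alignment_score(ops: list[tuple[str, int]], a: str, b: str) -> int:
    """Score of an explicit alignment under the module's scoring scheme."""
    i = j = 0
    score = 0
    for op, length in ops:
        if op == "M":
            for q, s in zip(a[i : i + length], b[j : j + length]):
                score += MATCH if q == s else MISMATCH
            i += length
            j += length
        else:
            score += GAP_OPEN + (length - 1) * GAP_EXTEND
            if op == "I":
                i += length
            else:
                j += length
    return score


def trim_terminal_gaps(
    ops: list[tuple[str, int]],
) -> tuple[list[tuple[str, int]], int, int, int, int]:
    """Strip leading/trailing indel runs from an op list.

    Returns (ops, q_leading, q_trailing, s_leading, s_trailing): the number
    of query/subject bases removed at each end.
    """
    ops = list(ops)
    qlead = slead = qtrail = strail = 0
    while ops and ops[0][0] != "M":
        op, length = ops.pop(0)
        if op == "I":
            qlead += length
        else:
            slead += length
    while ops and ops[-1][0] != "M":
        op, length = ops.pop()
        if op == "I":
            qtrail += length
        else:
            strail += length
    return ops, qlead, qtrail, slead, strail
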
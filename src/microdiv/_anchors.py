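"""Seed-and-extend helpers: unique k-mer anchors, collinear chaining, and
locating a short query inside a large target."""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from ._align import align_global, align_semiglobal, merge_ops
from .models import GenomeAssembly


def unique_kmer_map(
    assembly: GenomeAssembly, k: int
) -> dict[str, tuple[str, int]]:
    """Map each k-mer that occurs exactly once genome-wide (and contains no
    N) to its (chromosome, position)."""
    seen: dict[str, tuple[str, int]] = {}
    dups: set[str] = set()
    for chrom, seq in assembly.sequences.items():
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            if kmer in dups:
                continue
            if kmer in seen:
                del seen[kmer]
                dups.add(kmer)
            else:
                seen[kmer] = (chrom, pos)
    return seen


def chain_anchors(
    anchors: list[tuple[int, int]], k: int
) -> list[tuple[int, int]]:
    """Longest strictly-collinear chain of (qpos, spos) anchors.

    Anchors must be sorted by qpos. The chain is found by patience LIS on
    spos (ties broken toward the leftmost query start), then thinned so
    consecutive anchors advance by at least k in both coordinates.
    """
    if not anchors:
        return []
    tails: list[int] = []  # smallest chain-ending spos per length
    tail_idx: list[int] = []
    parent = [-1] * len(anchors)
    for idx, (_, spos) in enumerate(anchors):
        pos = bisect_left(tails, spos)
        if pos == len(tails):
            tails.append(spos)
            tail_idx.append(idx)
        elif spos < tails[pos]:
            tails[pos] = spos
            tail_idx[pos] = idx
        else:
            continue
        parent[idx] = tail_idx[pos - 1] if pos > 0 else -1
    chain: list[tuple[int, int]] = []
    idx = tail_idx[-1]
    while idx != -1:
        chain.append(anchors[idx])
        idx = parent[idx]
    chain.reverse()
    thinned = [chain[0]]
    for qpos, spos in chain[1:]:
        pq, ps = thinned[-1]
        if qpos >= pq + k and spos >= ps + k:
            thinned.append((qpos, spos))
    return thinned


def align_with_anchors(
    qseq: str, sseq: str, anchors: list[tuple[int, int]], k: int
) -> list[tuple[str, int]]:
    """Compose a full global alignment from a collinear anchor chain by
    closing every inter-anchor segment with optimal affine DP."""
    pieces = []
    qprev = sprev = 0
    for qpos, spos in anchors:
        seg_ops, _ = align_global(qseq[qprev:qpos], sseq[sprev:spos])
        pieces.append(seg_ops)
        pieces.append([("M", k)])
        qprev, sprev = qpos + k, spos + k
    tail_ops, _ = align_global(qseq[qprev:], sseq[sprev:])
    pieces.append(tail_ops)
    return merge_ops(*pieces)


def kmer_position_index(
    seq: str, k: int, max_positions: int = 32
) -> dict[str, list[int]]:
    """All positions of each k-mer in one sequence, list capped per k-mer."""
    index: dict[str, list[int]] = {}
    for pos in range(len(seq) - k + 1):
        kmer = seq[pos : pos + k]
        if "N" in kmer:
            continue
        hits = index.setdefault(kmer, [])
        if len(hits) < max_positions:
            hits.append(pos)
    return index


@dataclass
class LocalPlacement:
    """One candidate placement of a query inside a target sequence."""

    start: int
    end: int
    identity: float
    coverage: float
    score: int
    ops: list[tuple[str, int]] = field(repr=False, default_factory=list)


def _candidate_starts(
    query: str, index: dict[str, list[int]], k: int, max_candidates: int = 8
) -> list[int]:
    stride = max(1, (len(query) - k) // 16) if len(query) > k else 1
    offsets = list(range(0, max(1, len(query) - k + 1), stride))
    if len(query) >= k and offsets[-1] != len(query) - k:
        offsets.append(len(query) - k)
    votes: dict[int, int] = {}
    for off in offsets:
        kmer = query[off : off + k]
        for pos in index.get(kmer, ()):
            diag = pos - off
            # merge near-identical diagonals (indel tolerance)
            key = None
            for cand in (diag, diag - 1, diag + 1):
                bucket = cand // 32
                if bucket in votes:
                    key = bucket
                    break
            key = diag // 32 if key is None else key
            votes[key] = votes.get(key, 0) + 1
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    return [bucket * 32 for bucket, _ in ranked[:max_candidates]]


def locate_query(
    query: str,
    target: str,
    index: dict[str, list[int]],
    k: int = 31,
    pad: int = 64,
) -> list[LocalPlacement]:
    """Place ``query`` inside ``target`` via seed clustering plus DP
    extension; returns candidate placements sorted by score (best first)."""
    if len(query) < k:
        k = max(8, len(query) // 2)
        index = kmer_position_index(target, k)
    placements: list[LocalPlacement] = []
    for diag in _candidate_starts(query, index, k):
        lo = max(0, diag - pad)
        hi = min(len(target), diag + len(query) + pad)
        window = target[lo:hi]
        if not window:
            continue
        try:
            ops, w_start, w_end, score = align_semiglobal(query, window)
        except ValueError:
            continue
        matches = mismatches = 0
        qi, si = 0, w_start
        for op, length in ops:
            if op == "M":
                qa = np.frombuffer(
                    query[qi : qi + length].encode(), np.uint8
                )
                sa = np.frombuffer(
                    window[si : si + length].encode(), np.uint8
                )
                eq = int((qa == sa).sum())
                matches += eq
                mismatches += length - eq
                qi += length
                si += length
            elif op == "I":
                qi += length
            else:
                si += length
        aligned_cols = matches + mismatches
        if aligned_cols == 0:
            continue
        identity = matches / aligned_cols
        coverage = aligned_cols / len(query)
        placements.append(
            LocalPlacement(
                start=lo + w_start,
                end=lo + w_end,
                identity=identity,
                coverage=coverage,
                score=score,
                ops=ops,
            )
        )
    # deduplicate candidates that converged on the same interval
    uniq: dict[tuple[int, int], LocalPlacement] = {}
    for p in placements:
        key = (p.start, p.end)
        if key not in uniq or p.score > uniq[key].score:
            uniq[key] = p
    return sorted(uniq.values(), key=lambda p: -p.score)
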
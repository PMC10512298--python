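"""Whole-genome micro-divergence metrics for near-identical assemblies.

Two summary statistics are produced per ordered genome pair:

* gap-excluded identity — matches / (matches + mismatches) over gap-free
  alignment columns; indels are ignored entirely;
* gap-compressed divergence — every maximal indel run counts as a single
  difference event alongside mismatches:
  (mismatches + indel runs) / (matches + mismatches + indel runs).

Both can be computed with homopolymers retained or with every run of
``min_run`` (default 5) identical bases deleted from both genomes before
alignment, and with or without masking of columns containing N.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict

import numpy as np

from ._anchors import align_with_anchors, chain_anchors, unique_kmer_map
from .models import GenomeAssembly

WITH_HOMOPOLYMERS = "with_homopolymers"
WITHOUT_HOMOPOLYMERS = "without_homopolymers"


# ---------------------------------------------------------------------------
# homopolymer stripping


def strip_homopolymers(
    assembly: GenomeAssembly, min_run: int = 5
) -> GenomeAssembly:
    """Delete every maximal run of >= min_run identical non-N bases.

    Deletion (not collapse) is applied repeatedly until no qualifying run
    remains, so the output never contains such a run even when deletions
    juxtapose identical bases.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    pattern = re.compile(r"([ACGT])\1{%d,}" % (min_run - 1))
    out = {}
    for chrom, seq in assembly.sequences.items():
        prev = None
        while prev != seq:
            prev = seq
            seq = pattern.sub("", seq)
        out[chrom] = seq
    return GenomeAssembly(out, name=f"{assembly.name}-nohp")


# ---------------------------------------------------------------------------
# alignment blocks


@dataclass
class AlignmentBlock:
    """One collinear aligned segment between a query and subject chromosome.

    ``ops`` is a run-length operation list over ``query_seq``/``subject_seq``
    ('M' aligned column, 'I' query-only base, 'D' subject-only base).
    Chromosomes for which no anchors were found are reported with
    ``aligned=False`` rather than silently dropped.
    """

    query_name: str
    query_start: int
    query_end: int
    subject_name: str
    subject_start: int
    subject_end: int
    ops: list[tuple[str, int]] = field(repr=False, default_factory=list)
    query_seq: str = field(repr=False, default="")
    subject_seq: str = field(repr=False, default="")
    strand: str = "+"
    aligned: bool = True

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class ColumnCounts:
    matches: int = 0
    mismatches: int = 0
    n_masked_columns: int = 0
    insertion_runs: int = 0
    deletion_runs: int = 0
    insertion_bases: int = 0
    deletion_bases: int = 0

    def __add__(self, other: "ColumnCounts") -> "ColumnCounts":
        return ColumnCounts(
            *(
                getattr(self, f) + getattr(other, f)
                for f in self.__dataclass_fields__
            )
        )

    @property
    def gap_free_columns(self) -> int:
        return self.matches + self.mismatches + self.n_masked_columns

    @property
    def indel_runs(self) -> int:
        return self.insertion_runs + self.deletion_runs


def anchor_align(
    query: GenomeAssembly,
    subject: GenomeAssembly,
    k: int = 21,
    min_block: int = 0,
) -> list[AlignmentBlock]:
    """Co-oriented whole-chromosome alignment via unique k-mer anchors.

    Anchors are k-mers occurring exactly once in each genome; per
    chromosome they are chained collinearly (longest chain, leftmost query
    start on ties) and inter-anchor segments are closed with optimal
    affine-gap DP. Chromosomes are paired by name, or by rank when the two
    assemblies share no names. Blocks whose query span is below
    ``min_block`` are discarded.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if not query.sequences or not subject.sequences:
        raise ValueError("assemblies must be non-empty")

    qmap = unique_kmer_map(query, k)
    smap = unique_kmer_map(subject, k)

    shared = set(query.chromosomes) & set(subject.chromosomes)
    if shared:
        pairs = [(c, c) for c in query.chromosomes if c in shared]
    else:
        pairs = list(zip(query.chromosomes, subject.chromosomes))

    anchors_by_pair: dict[tuple[str, str], list[tuple[int, int]]] = {
        pair: [] for pair in pairs
    }
    wanted = {pair: True for pair in pairs}
    for kmer, (qc, qp) in qmap.items():
        hit = smap.get(kmer)
        if hit is None:
            continue
        sc, sp = hit
        if wanted.get((qc, sc)):
            anchors_by_pair[(qc, sc)].append((qp, sp))

    blocks: list[AlignmentBlock] = []
    for qc, sc in pairs:
        qseq, sseq = query[qc], subject[sc]
        anchors = sorted(anchors_by_pair[(qc, sc)])
        chain = chain_anchors(anchors, k)
        if not chain:
            blocks.append(
                AlignmentBlock(
                    query_name=qc,
                    query_start=0,
                    query_end=len(qseq),
                    subject_name=sc,
                    subject_start=0,
                    subject_end=len(sseq),
                    aligned=False,
                )
            )
            continue
        ops = align_with_anchors(qseq, sseq, chain, k)
        block = AlignmentBlock(
            query_name=qc,
            query_start=0,
            query_end=len(qseq),
            subject_name=sc,
            subject_start=0,
            subject_end=len(sseq),
            ops=ops,
            query_seq=qseq,
            subject_seq=sseq,
        )
        if block.query_span >= min_block:
            blocks.append(block)
    return blocks


def count_columns(block: AlignmentBlock, mask_n: bool = False) -> ColumnCounts:
    """Tally per-column events for one block.

    With ``mask_n`` any gap-free column where either base is N is counted
    only in ``n_masked_columns``; otherwise N compares literally.
    """
    if not block.aligned:
        raise ValueError(
            f"block {block.query_name} is unaligned; no columns to count"
        )
    counts = ColumnCounts()
    qa = np.frombuffer(block.query_seq.encode(), np.uint8)
    sa = np.frombuffer(block.subject_seq.encode(), np.uint8)
    qi = si = 0
    n_code = ord("N")
    for op, length in block.ops:
        if op == "M":
            q = qa[qi : qi + length]
            s = sa[si : si + length]
            if q.size != length or s.size != length:
                raise ValueError(
                    f"malformed ops in block {block.query_name}: operations "
                    "overrun the sequences"
                )
            if mask_n:
                masked = (q == n_code) | (s == n_code)
                counts.n_masked_columns += int(masked.sum())
                eq = (q == s) & ~masked
                counts.matches += int(eq.sum())
                counts.mismatches += int((~masked).sum() - eq.sum())
            else:
                eq = q == s
                counts.matches += int(eq.sum())
                counts.mismatches += length - int(eq.sum())
            qi += length
            si += length
        elif op == "I":
            counts.insertion_runs += 1
            counts.insertion_bases += length
            qi += length
        elif op == "D":
            counts.deletion_runs += 1
            counts.deletion_bases += length
            si += length
        else:
            raise ValueError(
                f"malformed op {op!r} in block {block.query_name}"
            )
    if qi != qa.size or si != sa.size:
        raise ValueError(
            f"malformed ops in block {block.query_name}: operations do not "
            "cover the sequences"
        )
    return counts


# ---------------------------------------------------------------------------
# pairwise report


@dataclass
class PairMetrics:
    gap_excluded_identity: float
    gap_compressed_divergence: float
    gap_excluded_diffs_per_mb: float
    gap_compressed_diffs_per_mb: float
    total_block_length: int
    counts: ColumnCounts


@dataclass
class DivergenceOptions:
    min_block: int = 1_000_000
    mask_n: bool = True
    k: int = 21
    homopolymer_modes: tuple[str, ...] = (WITH_HOMOPOLYMERS,)
    min_run: int = 5


@dataclass
class DivergenceReport:
    query_name: str
    subject_name: str
    modes: dict[str, PairMetrics | None]
    unaligned_chromosomes: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload: dict = {
            "query": self.query_name,
            "subject": self.subject_name,
            "modes": {},
            "unaligned_chromosomes": self.unaligned_chromosomes,
        }
        for mode, metrics in self.modes.items():
            if metrics is None:
                payload["modes"][mode] = {"no_qualifying_alignment": True}
            else:
                d = asdict(metrics)
                d["counts"] = asdict(metrics.counts)
                payload["modes"][mode] = d
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_table(self) -> str:
        """Tab-separated layout: query, subject, then the four metric
        columns (gap-excluded / gap-compressed per-Mb rates, with and
        without homopolymers)."""
        header = (
            "query\tsubject\t"
            "gap_excluded_per_mb_with_hp\tgap_compressed_per_mb_with_hp\t"
            "gap_excluded_per_mb_no_hp\tgap_compressed_per_mb_no_hp"
        )

        def cell(mode: str, attr: str) -> str:
            m = self.modes.get(mode)
            if m is None:
                return "NA"
            return f"{getattr(m, attr):.6g}"

        row = "\t".join(
            [
                self.query_name,
                self.subject_name,
                cell(WITH_HOMOPOLYMERS, "gap_excluded_diffs_per_mb"),
                cell(WITH_HOMOPOLYMERS, "gap_compressed_diffs_per_mb"),
                cell(WITHOUT_HOMOPOLYMERS, "gap_excluded_diffs_per_mb"),
                cell(WITHOUT_HOMOPOLYMERS, "gap_compressed_diffs_per_mb"),
            ]
        )
        return f"{header}\n{row}\n"


def _metrics_from_counts(
    counts: ColumnCounts, total_block_length: int
) -> PairMetrics:
    ge_denom = counts.matches + counts.mismatches
    gc_denom = ge_denom + counts.indel_runs
    gc_events = counts.mismatches + counts.indel_runs
    return PairMetrics(
        gap_excluded_identity=(
            counts.matches / ge_denom if ge_denom else float("nan")
        ),
        gap_compressed_divergence=(
            gc_events / gc_denom if gc_denom else float("nan")
        ),
        gap_excluded_diffs_per_mb=(
            counts.mismatches * 1e6 / ge_denom if ge_denom else float("nan")
        ),
        gap_compressed_diffs_per_mb=(
            gc_events * 1e6 / gc_denom if gc_denom else float("nan")
        ),
        total_block_length=total_block_length,
        counts=counts,
    )


def pairwise_divergence(
    query: GenomeAssembly,
    subject: GenomeAssembly,
    options: DivergenceOptions | None = None,
) -> DivergenceReport:
    """Compute the divergence report for one ordered pair of assemblies.

    For the homopolymer-free mode both genomes are stripped first and the
    alignment recomputed from scratch; the block-length filter is applied
    after stripping. When no block survives ``min_block`` for a mode the
    pair is flagged as having no qualifying alignment (metrics absent, not
    zero).
    """
    options = options or DivergenceOptions()
    modes: dict[str, PairMetrics | None] = {}
    unaligned: dict[str, list[str]] = {}
    for mode in options.homopolymer_modes:
        if mode == WITHOUT_HOMOPOLYMERS:
            q = strip_homopolymers(query, options.min_run)
            s = strip_homopolymers(subject, options.min_run)
        elif mode == WITH_HOMOPOLYMERS:
            q, s = query, subject
        else:
            raise ValueError(f"unknown homopolymer mode {mode!r}")
        blocks = anchor_align(q, s, k=options.k, min_block=options.min_block)
        unaligned[mode] = [b.query_name for b in blocks if not b.aligned]
        retained = [b for b in blocks if b.aligned]
        if not retained:
            modes[mode] = None
            continue
        total = ColumnCounts()
        span = 0
        for block in retained:
            total = total + count_columns(block, mask_n=options.mask_n)
            span += block.query_span
        modes[mode] = _metrics_from_counts(total, span)
    return DivergenceReport(
        query_name=query.name,
        subject_name=subject.name,
        modes=modes,
        unaligned_chromosomes=unaligned,
    )


# ---------------------------------------------------------------------------
# desk arithmetic


@dataclass
class ExpectedChanges:
    raw: float
    rounded: int


def expected_change_count(
    rate_per_mb: float, genome_size_mb: float, fraction: float
) -> ExpectedChanges:
    """Expected number of changes in a genome compartment, e.g. introns at
    5% of a 31.14 Mb genome under 5 changes/Mb -> 7.785 (~8)."""
    if rate_per_mb < 0 or genome_size_mb < 0 or fraction < 0:
        raise ValueError("arguments must be >= 0")
    raw = rate_per_mb * genome_size_mb * fraction
    return ExpectedChanges(raw=raw, rounded=round(raw))


def spacing_kb_from_percent(divergence_percent: float) -> float:
    """Mean spacing between differences implied by a divergence percentage:
    0.002% -> one difference per 50 kb."""
    if divergence_percent <= 0:
        raise ValueError("divergence must be positive")
    return 1.0 / (divergence_percent / 100.0) / 1000.0
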
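"""Flanking-consensus gap filling for a draft assembly.

Each maximal N run in the draft is bracketed by two flanks which are
placed on two higher-quality relative assemblies. When the relatives
agree on the sequence between the flanks the gap is filled verbatim; when
they agree on the length but differ at up to a configurable number of
positions a consensus with N at each disagreement is used; anything else
is skipped. Overlapping flank placements indicate erroneously duplicated
draft sequence, which is trimmed instead.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from ._anchors import kmer_position_index, locate_query
from .models import GenomeAssembly, revcomp

_N_RUN = re.compile(r"N+")

VERDICTS = (
    "fill_identical",
    "fill_consensus",
    "skip_length_mismatch",
    "skip_too_ambiguous",
    "trim_overlap",
    "unplaced",
)


@dataclass(frozen=True)
class GapRegion:
    chromosome: str
    start: int
    end: int  # 0-based, half-open; every position in [start,end) is N

    @property
    def length(self) -> int:
        return self.end - self.start


def find_gaps(assembly: GenomeAssembly) -> list[GapRegion]:
    """Maximal N runs, sorted by chromosome then start."""
    gaps = [
        GapRegion(chrom, m.start(), m.end())
        for chrom in assembly.chromosomes
        for m in _N_RUN.finditer(assembly[chrom])
    ]
    gaps.sort(key=lambda g: (g.chromosome, g.start))
    return gaps


@dataclass
class _FlankHit:
    chromosome: str
    start: int
    end: int
    identity: float
    coverage: float
    orientation: str
    score: int


@dataclass
class FlankPlacement:
    """Placement of one gap's flanks on one relative genome."""

    gap: GapRegion
    genome_name: str
    five: _FlankHit | None = None
    three: _FlankHit | None = None
    status: str = "ok"  # ok | unplaced | ambiguous | discordant
    reason: str = ""

    @property
    def same_chromosome(self) -> bool:
        return (
            self.five is not None
            and self.three is not None
            and self.five.chromosome == self.three.chromosome
        )

    @property
    def distance(self) -> int | None:
        """Bases between the placed flanks; negative when they overlap."""
        if self.status != "ok":
            return None
        if self.five.orientation == "+":
            return self.three.start - self.five.end
        return self.five.start - self.three.end

    def interflank_interval(self) -> tuple[str, int, int]:
        if self.five.orientation == "+":
            return (self.five.chromosome, self.five.end, self.three.start)
        return (self.five.chromosome, self.three.end, self.five.start)


def _best_hits(
    flank: str,
    relative: GenomeAssembly,
    indices: dict[str, dict],
    k: int,
    min_identity: float,
    min_coverage: float,
) -> list[_FlankHit]:
    hits: list[_FlankHit] = []
    for chrom in relative.chromosomes:
        index = indices[chrom]
        seq = relative[chrom]
        for orient, query in (("+", flank), ("-", revcomp(flank))):
            for p in locate_query(query, seq, index, k):
                if p.identity >= min_identity and p.coverage >= min_coverage:
                    hits.append(
                        _FlankHit(
                            chromosome=chrom,
                            start=p.start,
                            end=p.end,
                            identity=p.identity,
                            coverage=p.coverage,
                            orientation=orient,
                            score=p.score,
                        )
                    )
    hits.sort(key=lambda h: -h.score)
    return hits


def place_flanks(
    gap: GapRegion,
    draft: GenomeAssembly,
    relative: GenomeAssembly,
    flank_length: int = 1000,
    min_flank: int = 50,
    k: int = 31,
    ambiguity_margin: float = 0.05,
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
    _indices: dict[str, dict] | None = None,
) -> FlankPlacement:
    """Place a gap's 5' and 3' flanks on one relative genome.

    Flanks are truncated at chromosome ends; a flank shorter than
    ``min_flank`` or absent from the relative yields an unplaced verdict,
    and two near-equal candidate locations (scores within
    ``ambiguity_margin``) mark the placement ambiguous.
    """
    seq = draft[gap.chromosome]
    five = seq[max(0, gap.start - flank_length) : gap.start]
    three = seq[gap.end : gap.end + flank_length]
    placement = FlankPlacement(gap=gap, genome_name=relative.name)
    if len(five) < min_flank or len(three) < min_flank:
        placement.status = "unplaced"
        placement.reason = "flank_truncated_at_chromosome_end"
        return placement
    if "N" in five or "N" in three:
        placement.status = "unplaced"
        placement.reason = "flank_contains_n"
        return placement

    if _indices is None:
        _indices = {
            chrom: kmer_position_index(relative[chrom], k)
            for chrom in relative.chromosomes
        }
    results = []
    for flank in (five, three):
        hits = _best_hits(
            flank, relative, _indices, k, min_identity, min_coverage
        )
        if not hits:
            placement.status = "unplaced"
            placement.reason = "flank_not_found"
            return placement
        best = hits[0]
        if len(hits) > 1:
            second = hits[1]
            if (best.score - second.score) <= ambiguity_margin * max(
                1, abs(best.score)
            ):
                placement.status = "ambiguous"
                placement.reason = "two_near_equal_placements"
                return placement
        results.append(best)
    placement.five, placement.three = results

    if not placement.same_chromosome:
        placement.status = "discordant"
        placement.reason = "flanks_on_different_chromosomes"
    elif placement.five.orientation != placement.three.orientation:
        placement.status = "discordant"
        placement.reason = "flanks_in_opposite_orientation"
    else:
        d = placement.distance
        if d is not None and d < -(len(five) + len(three)):
            placement.status = "discordant"
            placement.reason = "flanks_in_reversed_order"
    return placement


@dataclass
class GapDecision:
    gap: GapRegion
    verdict: str
    infill: str | None = None
    trim_length: int = 0
    n_ambiguous: int = 0
    reason: str = ""

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "fill_identical" and self.infill is not None:
            assert "N" not in self.infill
        if self.verdict == "trim_overlap" and self.trim_length <= 0:
            raise ValueError("trim_overlap requires a positive trim length")


def decide_gap(
    placement_a: FlankPlacement,
    placement_b: FlankPlacement,
    relative_a: GenomeAssembly,
    relative_b: GenomeAssembly,
    max_ambiguous: int = 10,
) -> GapDecision:
    """Combine the two relatives' flank placements into one verdict."""
    gap = placement_a.gap
    for placement in (placement_a, placement_b):
        if placement.status != "ok":
            return GapDecision(
                gap,
                "unplaced",
                reason=f"{placement.genome_name}:{placement.status}:"
                f"{placement.reason}",
            )
    d_a = placement_a.distance
    d_b = placement_b.distance
    if d_a < 0 and d_b < 0:
        # erroneously duplicated draft sequence; trim conservatively
        return GapDecision(
            gap, "trim_overlap", trim_length=min(-d_a, -d_b)
        )
    if (d_a < 0) != (d_b < 0):
        return GapDecision(
            gap, "skip_length_mismatch", reason="overlap_in_one_relative"
        )

    def interflank(placement, relative):
        chrom, s, e = placement.interflank_interval()
        seq = relative[chrom][s:e]
        if placement.five.orientation == "-":
            seq = revcomp(seq)
        return seq

    seq_a = interflank(placement_a, relative_a)
    seq_b = interflank(placement_b, relative_b)
    if len(seq_a) != len(seq_b):
        return GapDecision(gap, "skip_length_mismatch")
    diffs = [i for i, (x, y) in enumerate(zip(seq_a, seq_b)) if x != y]
    if not diffs:
        return GapDecision(gap, "fill_identical", infill=seq_a)
    if len(diffs) <= max_ambiguous:
        consensus = list(seq_a)
        for i in diffs:
            consensus[i] = "N"
        return GapDecision(
            gap,
            "fill_consensus",
            infill="".join(consensus),
            n_ambiguous=len(diffs),
        )
    return GapDecision(gap, "skip_too_ambiguous", n_ambiguous=len(diffs))


@dataclass
class PolishReport:
    bases_added: int = 0
    bases_removed: int = 0
    defined_bases_added: int = 0
    defined_bases_removed: int = 0
    gaps_filled: int = 0
    gaps_skipped_by_reason: dict[str, int] = field(default_factory=dict)
    n_remaining: int = 0
    n_stretches_remaining: int = 0

    def to_dict(self) -> dict:
        return {
            "bases_added": self.bases_added,
            "bases_removed": self.bases_removed,
            "defined_bases_added": self.defined_bases_added,
            "defined_bases_removed": self.defined_bases_removed,
            "gaps_filled": self.gaps_filled,
            "gaps_skipped_by_reason": dict(self.gaps_skipped_by_reason),
            "n_remaining": self.n_remaining,
            "n_stretches_remaining": self.n_stretches_remaining,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_table(self) -> str:
        d = self.to_dict()
        skipped = d.pop("gaps_skipped_by_reason")
        lines = [f"{k}\t{v}" for k, v in d.items()]
        for reason, count in sorted(skipped.items()):
            lines.append(f"skipped_{reason}\t{count}")
        return "\n".join(lines) + "\n"


def apply_decisions(
    draft: GenomeAssembly, decisions: list[GapDecision]
) -> tuple[GenomeAssembly, PolishReport]:
    """Apply gap decisions right-to-left per chromosome.

    Accounting convention: ``bases_added``/``bases_removed`` count all
    inserted/removed characters (including the gap's Ns), so that
    length(out) = length(in) + bases_added - bases_removed holds per
    chromosome; ``defined_bases_added``/``defined_bases_removed`` count
    only non-N sequence, matching the usual "added/deleted sequence"
    bookkeeping of assembly reports.
    """
    report = PolishReport()
    spans: dict[str, list[tuple[int, int]]] = {}
    for dec in decisions:
        gap = dec.gap
        end = gap.end + (
            dec.trim_length if dec.verdict == "trim_overlap" else 0
        )
        chrom_spans = spans.setdefault(gap.chromosome, [])
        for s, e in chrom_spans:
            if gap.start < e and end > s:
                raise ValueError(
                    f"conflicting decisions overlap at "
                    f"{gap.chromosome}:{gap.start}-{end}"
                )
        chrom_spans.append((gap.start, end))

    per_chrom: dict[str, list[GapDecision]] = {}
    for dec in decisions:
        per_chrom.setdefault(dec.gap.chromosome, []).append(dec)

    out = dict(draft.sequences)
    for chrom, decs in per_chrom.items():
        seq = out[chrom]
        for dec in sorted(decs, key=lambda d: -d.gap.start):
            gap = dec.gap
            if set(seq[gap.start : gap.end]) != {"N"}:
                raise ValueError(
                    f"decision references a non-gap region at "
                    f"{chrom}:{gap.start}-{gap.end}"
                )
            if dec.verdict in ("fill_identical", "fill_consensus"):
                seq = seq[: gap.start] + dec.infill + seq[gap.end :]
                report.gaps_filled += 1
                report.bases_added += len(dec.infill)
                report.bases_removed += gap.length
                report.defined_bases_added += len(dec.infill) - (
                    dec.infill.count("N")
                )
            elif dec.verdict == "trim_overlap":
                removed = seq[gap.start : gap.end + dec.trim_length]
                seq = seq[: gap.start] + seq[gap.end + dec.trim_length :]
                report.bases_removed += len(removed)
                report.defined_bases_removed += len(removed) - (
                    removed.count("N")
                )
                report.gaps_skipped_by_reason["trim_overlap"] = (
                    report.gaps_skipped_by_reason.get("trim_overlap", 0) + 1
                )
            else:
                key = dec.verdict
                report.gaps_skipped_by_reason[key] = (
                    report.gaps_skipped_by_reason.get(key, 0) + 1
                )
        out[chrom] = seq

    polished = GenomeAssembly(out, name=draft.name)
    report.n_remaining = polished.n_count()
    report.n_stretches_remaining = len(find_gaps(polished))
    return polished, report


def polish(
    draft: GenomeAssembly,
    relative_a: GenomeAssembly,
    relative_b: GenomeAssembly,
    flank_length: int = 1000,
    max_ambiguous: int = 10,
    k: int = 31,
) -> tuple[GenomeAssembly, PolishReport, list[GapDecision]]:
    """Full gap-polishing pass: find gaps, place flanks on both relatives,
    decide, and apply."""
    indices = [
        {
            chrom: kmer_position_index(rel[chrom], k)
            for chrom in rel.chromosomes
        }
        for rel in (relative_a, relative_b)
    ]
    decisions = []
    for gap in find_gaps(draft):
        pa = place_flanks(
            gap,
            draft,
            relative_a,
            flank_length=flank_length,
            k=k,
            _indices=indices[0],
        )
        pb = place_flanks(
            gap,
            draft,
            relative_b,
            flank_length=flank_length,
            k=k,
            _indices=indices[1],
        )
        decisions.append(
            decide_gap(pa, pb, relative_a, relative_b, max_ambiguous)
        )
    polished, report = apply_decisions(draft, decisions)
    return polished, report, decisions
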
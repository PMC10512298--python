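"""Gene-by-gene mutation calling between near-identical strains.

The reference gene set (defined on the middle strain of a serial trio) is
mapped syntenically and sequentially onto the other two assemblies; each
non-identical gene is diffed, every difference is localised
(intron/exon/splice site), classified by re-translation, screened for
homopolymer-length artifacts, optionally checked against short-read
k-mers, and polarised onto a culture interval by three-way allele
comparison. The staged exclusions telescope into a funnel report.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from ._align import align_global, trim_terminal_gaps
from ._anchors import kmer_position_index, locate_query
from .models import GeneModel, GenomeAssembly, revcomp

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_TABLE.stop_codons)

EFFECTS = (
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "intronic",
    "splice_site",
    "none",
)


def translate_cds(cds: str) -> str:
    """Standard-table translation; stops at the first stop codon (which is
    not included); codons containing N translate to X."""
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            protein.append("X")
            continue
        if codon in STOP_CODONS:
            break
        protein.append(_TABLE.forward_table[codon])
    return "".join(protein)


def splice_cds(model: GeneModel, assembly: GenomeAssembly) -> str:
    seq = assembly[model.chromosome]
    spliced = "".join(seq[s:e] for s, e in model.exons)
    if model.strand == "-":
        spliced = revcomp(spliced)
    return spliced


def splice_and_translate(
    model: GeneModel, assembly: GenomeAssembly
) -> tuple[str, str]:
    """(spliced CDS, protein) for one gene model on one assembly."""
    cds = splice_cds(model, assembly)
    return cds, translate_cds(cds)


def validate_model(model: GeneModel, assembly: GenomeAssembly) -> None:
    """Raise if the model is not a clean protein-coding gene on the
    assembly (ATG start, terminal stop, length divisible by 3, no internal
    stop)."""
    cds = splice_cds(model, assembly)
    if len(cds) % 3:
        raise ValueError(f"{model.gene_id}: CDS length not divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError(f"{model.gene_id}: CDS does not start with ATG")
    if cds[-3:] not in STOP_CODONS:
        raise ValueError(f"{model.gene_id}: CDS does not end with a stop")
    protein = translate_cds(cds)
    if 3 * (len(protein) + 1) != len(cds):
        raise ValueError(f"{model.gene_id}: internal stop codon")


# ---------------------------------------------------------------------------
# candidate mutations


@dataclass
class CandidateMutation:
    """One sequence difference between the reference gene and a strain."""

    gene_id: str
    chromosome: str
    position: int  # genomic, 0-based, VCF-style anchor for indels
    locus_position: int  # 0-based offset within the gene locus
    ref: str
    alt: str
    region: str  # intron | exon | splice_site
    effect: str
    strain: str = ""  # which comparison produced it ('A' or 'C')
    cds_position: int | None = None
    protein_change: str = ""
    appearance: str = ""  # A>B | B>C | conflict | none | indeterminate
    homopolymer_flag: bool = False
    support_verdict: str = "untested"
    restores_frame: bool = False

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def render_mutation(self) -> str:
        """Table-style rendering: 'C1377T', 'ins 209 C', 'del 196 ACGT'."""
        pos1 = self.locus_position + 1
        if not self.is_indel:
            return f"{self.ref}{pos1}{self.alt}"
        if len(self.alt) > len(self.ref):
            return f"ins {pos1 + 1} {self.alt[len(self.ref):]}"
        return f"del {pos1 + 1} {self.ref[len(self.alt):]}"


class GeneUnclassifiable(ValueError):
    pass


def _locus_model(model: GeneModel) -> GeneModel:
    return model.shifted(-model.start)


def _region_of(rel: GeneModel, start: int, end: int) -> str:
    """Region of a locus interval: splice_site > exon > intron."""
    if end <= start:
        end = start + 1
    for i_start, i_end in rel.introns:
        for ds, de in ((i_start, i_start + 2), (i_end - 2, i_end)):
            if start < de and end > ds:
                return "splice_site"
    for xs, xe in rel.exons:
        if start < xe and end > xs:
            # crossing an exon/intron boundary disturbs splicing
            if start < xs or end > xe:
                return "splice_site"
            return "exon"
    return "intron"


def _cds_offset(rel: GeneModel, locus_pos: int) -> int | None:
    acc = 0
    forward = None
    for xs, xe in rel.exons:
        if xs <= locus_pos < xe:
            forward = acc + locus_pos - xs
            break
        acc += xe - xs
    if forward is None:
        return None
    if rel.strand == "-":
        return rel.spliced_length - 1 - forward
    return forward


def _shift_model(rel: GeneModel, pos: int, ref: str, alt: str) -> GeneModel:
    delta = len(alt) - len(ref)
    if delta == 0:
        return rel
    cut = pos + len(ref)
    exons = [
        (
            s + delta if s >= cut else s,
            e + delta if e >= cut else e,
        )
        for s, e in rel.exons
    ]
    return GeneModel(
        gene_id=rel.gene_id,
        chromosome=rel.chromosome,
        strand=rel.strand,
        exons=exons,
        protein_id=rel.protein_id,
    )


def _truncated(protein: str, cds_len: int) -> bool:
    return 3 * (len(protein) + 1) < cds_len


def classify_variant(
    model: GeneModel,
    locus_ref: str,
    pos: int,
    ref: str,
    alt: str,
) -> CandidateMutation:
    """Classify one locus-frame variant (VCF-style alleles) on a gene.

    The model may be in genomic or locus frame; only its internal
    structure is used (it is re-based onto the locus)."""
    rel = _locus_model(model)
    if locus_ref[pos : pos + len(ref)] != ref:
        raise GeneUnclassifiable(
            f"{model.gene_id}: ref allele mismatch at locus position {pos}"
        )
    is_indel = len(ref) != len(alt)
    if is_indel:
        changed_start, changed_end = pos + 1, pos + max(len(ref), 2)
    else:
        changed_start, changed_end = pos, pos + len(ref)
    region = _region_of(rel, changed_start, changed_end)

    mut = CandidateMutation(
        gene_id=model.gene_id,
        chromosome=model.chromosome,
        position=model.start + pos,
        locus_position=pos,
        ref=ref,
        alt=alt,
        region=region,
        effect="none",
        cds_position=_cds_offset(rel, changed_start),
    )
    if region == "intron":
        mut.effect = "intronic"
        return mut
    if region == "splice_site":
        mut.effect = "splice_site"
        return mut

    # exonic: re-translate
    tmp = GenomeAssembly({rel.chromosome: locus_ref}, name="locus")
    cds_ref = splice_cds(rel, tmp)
    prot_ref = translate_cds(cds_ref)

    alt_locus = locus_ref[:pos] + alt + locus_ref[pos + len(ref) :]
    alt_model = _shift_model(rel, pos, ref, alt)
    alt_tmp = GenomeAssembly({rel.chromosome: alt_locus}, name="locus")
    cds_alt = splice_cds(alt_model, alt_tmp)
    prot_alt = translate_cds(cds_alt)

    delta = len(alt) - len(ref)
    if prot_ref == prot_alt and len(cds_ref) == len(cds_alt):
        mut.effect = "synonymous"
        return mut
    if is_indel:
        if abs(delta) % 3:
            mut.effect = "frameshift"
            mut.protein_change = "Premature stop"
        else:
            mut.effect = "inframe_indel"
            mut.protein_change = f"inframe indel of {abs(delta)} nt"
        long_prot, long_len, short_prot, short_len = (
            (prot_ref, len(cds_ref), prot_alt, len(cds_alt))
            if len(cds_ref) >= len(cds_alt)
            else (prot_alt, len(cds_alt), prot_ref, len(cds_ref))
        )
        if _truncated(long_prot, long_len) and not _truncated(
            short_prot, short_len
        ):
            mut.restores_frame = True
        return mut

    # substitution with protein consequence
    idx = next(
        (
            i
            for i, (r, a) in enumerate(zip(prot_ref, prot_alt))
            if r != a
        ),
        min(len(prot_ref), len(prot_alt)),
    )
    ref_codon = cds_ref[3 * idx : 3 * idx + 3]
    alt_codon = cds_alt[3 * idx : 3 * idx + 3]
    if len(prot_alt) < len(prot_ref) and alt_codon in STOP_CODONS:
        mut.effect = "nonsense"
        mut.protein_change = (
            f"{seq3(prot_ref[idx])}({ref_codon}) {idx + 1} STOP({alt_codon})"
        )
    else:
        mut.effect = "missense"
        mut.protein_change = (
            f"{seq3(prot_ref[idx])}({ref_codon}) {idx + 1} "
            f"{seq3(prot_alt[idx])}({alt_codon})"
        )
    return mut


def diff_gene(
    model: GeneModel,
    seq_ref: str,
    seq_other: str,
    strain: str = "",
) -> list[CandidateMutation]:
    """Differences between the reference gene locus and another strain's
    copy, localised and classified. Terminal overhangs are ignored."""
    try:
        ops, _ = align_global(seq_ref, seq_other)
    except ValueError as exc:
        raise GeneUnclassifiable(
            f"{model.gene_id}: gene alignment failed ({exc})"
        ) from exc
    ops, qlead, _, slead, _ = trim_terminal_gaps(ops)
    mutations: list[CandidateMutation] = []
    qi, si = qlead, slead
    for op, length in ops:
        if op == "M":
            for off in range(length):
                r = seq_ref[qi + off]
                a = seq_other[si + off]
                if r != a:
                    mutations.append(
                        classify_variant(model, seq_ref, qi + off, r, a)
                    )
            qi += length
            si += length
        elif op == "I":  # present in ref only: deletion in the other strain
            anchor = qi - 1
            if anchor >= 0:
                ref_allele = seq_ref[anchor : qi + length]
                alt_allele = seq_ref[anchor]
                mutations.append(
                    classify_variant(
                        model, seq_ref, anchor, ref_allele, alt_allele
                    )
                )
            qi += length
        else:  # 'D': present in the other strain only: insertion
            anchor = qi - 1
            if anchor >= 0:
                ref_allele = seq_ref[anchor]
                alt_allele = seq_ref[anchor] + seq_other[si : si + length]
                mutations.append(
                    classify_variant(
                        model, seq_ref, anchor, ref_allele, alt_allele
                    )
                )
            si += length
    for mut in mutations:
        mut.strain = strain
    return mutations


# ---------------------------------------------------------------------------
# artifact flagging / read support / polarisation


_RUN_RE = re.compile(r"(.)\1*")


def homopolymer_only_difference(
    seq_a: str, seq_b: str, min_run: int = 5
) -> bool:
    """True iff the two sequences differ only in the lengths of
    homopolymer runs of >= min_run bases (on at least one side).

    This is the gene-level artifact criterion: run-length encode both
    sequences; they must visit the same bases in the same order, and
    every run whose length differs must reach min_run on one side.
    """
    if seq_a == seq_b:
        return False
    runs_a = [(m.group(1), len(m.group(0))) for m in _RUN_RE.finditer(seq_a)]
    runs_b = [(m.group(1), len(m.group(0))) for m in _RUN_RE.finditer(seq_b)]
    if len(runs_a) != len(runs_b):
        return False
    for (base_a, len_a), (base_b, len_b) in zip(runs_a, runs_b):
        if base_a != base_b:
            return False
        if len_a != len_b and max(len_a, len_b) < min_run:
            return False
    return True


def _run_length_through(seq: str, pos: int, base: str) -> int:
    if pos < 0 or pos >= len(seq) or seq[pos] != base:
        # measure the run adjacent to pos instead
        left = pos - 1
        n = 0
        while left >= 0 and seq[left] == base:
            left -= 1
            n += 1
        right = pos
        m = 0
        while right < len(seq) and seq[right] == base:
            right += 1
            m += 1
        return max(n, m)
    lo = pos
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = pos
    while hi < len(seq) - 1 and seq[hi + 1] == base:
        hi += 1
    return hi - lo + 1


def flag_homopolymer_artifact(
    mutation: CandidateMutation,
    context: str,
    min_run: int = 5,
) -> bool:
    """True iff the mutation looks like a homopolymer-length calling error.

    ``context`` is the reference sequence the mutation's locus coordinates
    refer to (typically the gene locus). An indel is flagged when it
    changes the length of a reference run of >= min_run identical bases; a
    substitution is flagged when it creates or extends such a run.
    """
    pos = mutation.locus_position
    if mutation.is_indel:
        if len(mutation.alt) > len(mutation.ref):
            changed = mutation.alt[len(mutation.ref) :]
        else:
            changed = mutation.ref[len(mutation.alt) :]
        if len(set(changed)) != 1:
            return False
        base = changed[0]
        # run length measured on the pre-mutation (reference) sequence
        return _run_length_through(context, pos + 1, base) >= min_run
    alt_ctx = (
        context[:pos] + mutation.alt + context[pos + len(mutation.ref) :]
    )
    return _run_length_through(alt_ctx, pos, mutation.alt) >= min_run


def support_contexts(
    mutation: CandidateMutation, context: str, k: int = 31
) -> tuple[str, str]:
    """k-mers centred on the variant carrying the ref and alt alleles."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    pos = mutation.locus_position
    flank = k // 2
    left = context[max(0, pos - flank) : pos]
    right_ref = context[pos : pos + len(mutation.ref) + flank]
    ref_kmer = (left + right_ref)[: k + len(mutation.ref) - 1]
    alt_seq = mutation.alt + context[
        pos + len(mutation.ref) : pos + len(mutation.ref) + flank
    ]
    alt_kmer = (left + alt_seq)[: k + len(mutation.alt) - 1]
    return ref_kmer[:k], alt_kmer[:k]


def kmer_support(
    mutation: CandidateMutation,
    reads,
    context: str,
    k: int = 31,
    min_count: int = 3,
) -> str:
    """Read-support verdict for a mutation from a stream of read sequences.

    Counts exact occurrences (both strands) of the ref- and alt-carrying
    k-mers spanning the site. alt>=min_count and ref<min_count ->
    supported; the reverse -> refuted; both -> mixed; neither -> untested.
    """
    ref_kmer, alt_kmer = support_contexts(mutation, context, k)
    targets = {
        "ref": (ref_kmer, revcomp(ref_kmer)),
        "alt": (alt_kmer, revcomp(alt_kmer)),
    }
    counts = {"ref": 0, "alt": 0}
    for read in reads:
        for which, (fwd, rev) in targets.items():
            if fwd in read or rev in read:
                counts[which] += 1
    ref_ok = counts["ref"] >= min_count
    alt_ok = counts["alt"] >= min_count
    if alt_ok and not ref_ok:
        return "supported"
    if ref_ok and not alt_ok:
        return "refuted"
    if ref_ok and alt_ok:
        return "mixed"
    return "untested"


def polarize_mutation(allele_a: str, allele_b: str, allele_c: str) -> str:
    """Assign a three-strain allele pattern to a culture interval."""
    if any("N" in x or not x for x in (allele_a, allele_b, allele_c)):
        return "indeterminate"
    if allele_a == allele_b == allele_c:
        return "none"
    if allele_a == allele_b:
        return "B>C"
    if allele_b == allele_c:
        return "A>B"
    return "conflict"  # a == c != b (possible reversion) or all distinct


# ---------------------------------------------------------------------------
# syntenic sequential mapping


@dataclass
class GenePlacement:
    gene_id: str
    target_genome: str
    chromosome: str
    coverage: float
    identity: float
    target_start: int = 0
    target_end: int = 0
    synteny_ok: bool = True
    contains_n: bool = False

    @property
    def placed(self) -> bool:
        return self.coverage > 0


def sequential_map(
    genes: list[GeneModel],
    source: GenomeAssembly,
    target: GenomeAssembly,
    window: int = 500_000,
    k: int = 31,
    min_identity: float = 0.5,
) -> list[GenePlacement]:
    """Place each gene on the target within a sliding syntenic window.

    Genes must be sorted by (chromosome, start). The search window begins
    at the previous gene's placement end; a gene missing from the window
    triggers a whole-chromosome search and, if found out of order, is
    flagged ``synteny_ok=False``. A gene absent altogether yields a
    coverage-0 placement, never an exception.
    """
    placements: list[GenePlacement] = []
    indices: dict[str, dict] = {}
    prev_end: dict[str, int] = {}
    for gene in genes:
        chrom = gene.chromosome
        if chrom not in target:
            placements.append(
                GenePlacement(gene.gene_id, target.name, chrom, 0.0, 0.0)
            )
            continue
        tseq = target[chrom]
        if chrom not in indices:
            indices[chrom] = kmer_position_index(tseq, k)
            prev_end[chrom] = 0
        qseq = gene.locus_sequence(source)
        candidates = locate_query(qseq, tseq, indices[chrom], k)
        candidates = [c for c in candidates if c.identity >= min_identity]
        lo = prev_end[chrom]
        hi = lo + window + len(qseq)
        in_window = [c for c in candidates if lo <= c.start <= hi]
        synteny_ok = True
        chosen = in_window[0] if in_window else None
        if chosen is None and candidates:
            chosen = candidates[0]
            synteny_ok = False
        if chosen is None:
            placements.append(
                GenePlacement(gene.gene_id, target.name, chrom, 0.0, 0.0)
            )
            continue
        contains_n = "N" in qseq or "N" in tseq[chosen.start : chosen.end]
        placements.append(
            GenePlacement(
                gene_id=gene.gene_id,
                target_genome=target.name,
                chromosome=chrom,
                coverage=chosen.coverage,
                identity=chosen.identity,
                target_start=chosen.start,
                target_end=chosen.end,
                synteny_ok=synteny_ok,
                contains_n=contains_n,
            )
        )
        if synteny_ok:
            prev_end[chrom] = chosen.end
    return placements


# ---------------------------------------------------------------------------
# the funnel


def _floor1(value: float) -> float:
    """One-decimal truncation, the convention of the printed percentages
    (8245/8701 prints as 94.7, not 94.8)."""
    return math.floor(value * 10) / 10


@dataclass
class FunnelReport:
    total_genes: int
    identical: int
    candidates: int
    intronic_only: int
    exonic_candidates: int
    removed_synonymous_or_n: int
    remaining: int
    homopolymer_artifacts: int
    confirmed: int

    def __post_init__(self):
        self.check()

    @property
    def identical_pct(self) -> float:
        if not self.total_genes:
            return 0.0
        return _floor1(100.0 * self.identical / self.total_genes)

    @property
    def intronic_pct(self) -> float:
        if not self.candidates:
            return 0.0
        return _floor1(100.0 * self.intronic_only / self.candidates)

    def check(self) -> None:
        """Telescoping stage identities; raises on violation."""
        if self.candidates != self.total_genes - self.identical:
            raise ValueError("funnel: candidates != total - identical")
        if self.candidates != self.intronic_only + self.exonic_candidates:
            raise ValueError("funnel: candidates != intronic + exonic")
        if self.exonic_candidates != (
            self.removed_synonymous_or_n + self.remaining
        ):
            raise ValueError("funnel: exonic != removed + remaining")
        if self.remaining != self.homopolymer_artifacts + self.confirmed:
            raise ValueError("funnel: remaining != artifacts + confirmed")

    @classmethod
    def from_stage_counts(
        cls,
        total_genes: int,
        candidates: int,
        exonic_candidates: int,
        removed_synonymous_or_n: int,
        homopolymer_artifacts: int,
    ) -> "FunnelReport":
        remaining = exonic_candidates - removed_synonymous_or_n
        return cls(
            total_genes=total_genes,
            identical=total_genes - candidates,
            candidates=candidates,
            intronic_only=candidates - exonic_candidates,
            exonic_candidates=exonic_candidates,
            removed_synonymous_or_n=removed_synonymous_or_n,
            remaining=remaining,
            homopolymer_artifacts=homopolymer_artifacts,
            confirmed=remaining - homopolymer_artifacts,
        )

    def to_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "identical": self.identical,
            "candidates": self.candidates,
            "intronic_only": self.intronic_only,
            "exonic_candidates": self.exonic_candidates,
            "removed_synonymous_or_n": self.removed_synonymous_or_n,
            "remaining": self.remaining,
            "homopolymer_artifacts": self.homopolymer_artifacts,
            "confirmed": self.confirmed,
            "identical_pct": self.identical_pct,
            "intronic_pct": self.intronic_pct,
        }


@dataclass
class FunnelOptions:
    window: int = 500_000
    k: int = 31
    min_run: int = 5
    support_k: int = 31
    support_min_count: int = 3
    reads: dict[str, list[str]] = field(default_factory=dict)


def run_funnel(
    genes: list[GeneModel],
    reference: GenomeAssembly,
    strain_a: GenomeAssembly,
    strain_c: GenomeAssembly,
    options: FunnelOptions | None = None,
    read_streams: dict[str, list[str]] | None = None,
) -> tuple[FunnelReport, list[CandidateMutation]]:
    """The full filtering funnel over the reference gene set.

    ``reference`` is the middle strain (B) carrying the annotation;
    ``strain_a`` and ``strain_c`` are the earlier and later strains.
    ``read_streams`` optionally maps strain labels ('A'/'B'/'C') to lists
    of read sequences for k-mer support checks.
    """
    options = options or FunnelOptions()
    for other in (strain_a, strain_c):
        if set(other.chromosomes) != set(reference.chromosomes):
            raise ValueError(
                "chromosome names differ between assemblies: "
                f"{sorted(reference.chromosomes)} vs "
                f"{sorted(other.chromosomes)}"
            )
    genes = sorted(genes, key=lambda g: (g.chromosome, g.start))
    placements_a = sequential_map(
        genes, reference, strain_a, window=options.window, k=options.k
    )
    placements_c = sequential_map(
        genes, reference, strain_c, window=options.window, k=options.k
    )

    n_identical = 0
    n_intronic_only = 0
    n_removed = 0
    n_artifact = 0
    n_confirmed = 0
    confirmed_mutations: list[CandidateMutation] = []

    for gene, pa, pc in zip(genes, placements_a, placements_c):
        locus_ref = gene.locus_sequence(reference)
        seq_a = (
            strain_a[gene.chromosome][pa.target_start : pa.target_end]
            if pa.placed
            else ""
        )
        seq_c = (
            strain_c[gene.chromosome][pc.target_start : pc.target_end]
            if pc.placed
            else ""
        )
        if seq_a == locus_ref and seq_c == locus_ref:
            n_identical += 1
            continue

        muts: list[CandidateMutation] = []
        unclassifiable = False
        for strain, seq in (("A", seq_a), ("C", seq_c)):
            if seq == locus_ref:
                continue
            try:
                muts.extend(diff_gene(gene, locus_ref, seq, strain=strain))
            except GeneUnclassifiable:
                unclassifiable = True
        contains_n = (
            pa.contains_n or pc.contains_n or "N" in locus_ref
        )

        # polarisation via three-way alleles at each differing site
        by_site: dict[tuple[int, str], dict[str, str]] = {}
        for m in muts:
            key = (m.locus_position, m.ref)
            by_site.setdefault(key, {})[m.strain] = m.alt
        for m in muts:
            alleles = by_site[(m.locus_position, m.ref)]
            a = alleles.get("A", m.ref)
            c = alleles.get("C", m.ref)
            m.appearance = polarize_mutation(a, m.ref, c)

        exonic = [m for m in muts if m.region != "intron"]
        if not exonic and muts and not unclassifiable:
            n_intronic_only += 1
            continue
        consequential = [
            m
            for m in exonic
            if m.effect not in ("synonymous", "none")
        ]
        if contains_n or unclassifiable or not consequential:
            n_removed += 1
            continue
        # a strain whose copy differs from the reference only in run
        # lengths of long homopolymers carries nothing but length-calling
        # artifacts there
        run_length_only = {
            strain: homopolymer_only_difference(
                locus_ref, seq, options.min_run
            )
            for strain, seq in (("A", seq_a), ("C", seq_c))
        }
        for m in consequential:
            m.homopolymer_flag = run_length_only.get(
                m.strain, False
            ) or flag_homopolymer_artifact(
                m, locus_ref, min_run=options.min_run
            )
        if all(m.homopolymer_flag for m in consequential):
            n_artifact += 1
            continue
        n_confirmed += 1
        kept = [m for m in consequential if not m.homopolymer_flag]
        if read_streams:
            for m in kept:
                strain_reads = read_streams.get(m.strain, [])
                if strain_reads:
                    m.support_verdict = kmer_support(
                        m,
                        strain_reads,
                        locus_ref,
                        k=options.support_k,
                        min_count=options.support_min_count,
                    )
        confirmed_mutations.extend(kept)

    total = len(genes)
    candidates = total - n_identical
    exonic_candidates = candidates - n_intronic_only
    remaining = exonic_candidates - n_removed
    report = FunnelReport(
        total_genes=total,
        identical=n_identical,
        candidates=candidates,
        intronic_only=n_intronic_only,
        exonic_candidates=exonic_candidates,
        removed_synonymous_or_n=n_removed,
        remaining=remaining,
        homopolymer_artifacts=n_artifact,
        confirmed=n_confirmed,
    )
    confirmed_mutations.sort(key=lambda m: (m.chromosome, m.position))
    return report, confirmed_mutations


# ---------------------------------------------------------------------------
# writers


def mutations_to_table(mutations: list[CandidateMutation]) -> str:
    header = (
        "gene\tchromosome\tlocation\tmutation_appearance\tmutation\t"
        "protein_change\teffect\tregion\thomopolymer_flag\tsupport"
    )
    rows = [header]
    for m in mutations:
        rows.append(
            "\t".join(
                [
                    m.gene_id,
                    m.chromosome,
                    f"{m.position + 1}",
                    m.appearance,
                    m.render_mutation(),
                    m.protein_change,
                    m.effect,
                    m.region,
                    "yes" if m.homopolymer_flag else "no",
                    m.support_verdict,
                ]
            )
        )
    return "\n".join(rows) + "\n"


def mutations_to_vcf(
    mutations: list[CandidateMutation], reference_name: str
) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={reference_name}",
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect class">',
        '##INFO=<ID=INTERVAL,Number=1,Type=String,'
        'Description="Culture interval of appearance">',
        '##INFO=<ID=HPFLAG,Number=0,Type=Flag,'
        'Description="Homopolymer artifact">',
        '##INFO=<ID=SUPPORT,Number=1,Type=String,'
        'Description="Read k-mer support verdict">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample",
    ]
    for m in mutations:
        info = (
            f"EFFECT={m.effect};INTERVAL={m.appearance.replace('>', '_')};"
            f"SUPPORT={m.support_verdict}"
        )
        if m.homopolymer_flag:
            info += ";HPFLAG"
        lines.append(
            f"{m.chromosome}\t{m.position + 1}\t{m.gene_id}\t{m.ref}\t"
            f"{m.alt}\t.\tPASS\t{info}\tGT\t1"
        )
    return "\n".join(lines) + "\n"
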
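"""Synthetic strain-trio generator with known ground truth.

Builds a haploid multi-gene reference genome (the middle strain of a
serial A -> B -> C trio, which carries the annotation), plants classified
variants onto the flanking strains, and injects assembly artifacts
(homopolymer length errors, N-gaps) so every downstream stage can be
tested against truth without external data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from . import genes as genes_mod
from .models import GeneModel, GenomeAssembly, revcomp

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_NONSTOP_CODONS = [
    c for c in _CODONS if c not in genes_mod.STOP_CODONS and c != "ATG"
]
_STOPS = sorted(genes_mod.STOP_CODONS)

_HP_RE = re.compile(r"([ACGT])\1{4,}")

SNV_CLASSES = ("intergenic", "intronic", "synonymous", "missense", "nonsense")
INDEL_CLASSES = ("intergenic", "intronic", "frameshift")

DEFAULT_CLASS_MIX = {
    "intergenic": 0.30,
    "intronic": 0.20,
    "synonymous": 0.15,
    "missense": 0.20,
    "nonsense": 0.075,
    "frameshift": 0.075,
}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    n_chromosomes: int = 1
    chromosome_length: int = 100_000
    gc_fraction: float = 0.5
    gene_count: int = 40
    exon_fraction: float = 0.40
    intron_fraction: float = 0.05
    homopolymer_tract_rate: float = 0.5  # tracts per kb, lengths >= 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("gc_fraction", "exon_fraction", "intron_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.exon_fraction + self.intron_fraction > 1:
            raise ValueError("exon_fraction + intron_fraction must be <= 1")
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("chromosome counts/lengths must be positive")
        if self.gene_count < 0:
            raise ValueError("gene_count must be >= 0")
        if self.homopolymer_tract_rate < 0:
            raise ValueError("homopolymer_tract_rate must be >= 0")


@dataclass
class VariantSpec:
    snv_rate_per_mb: float = 0.0
    indel_rate_per_mb: float = 0.0
    indel_lengths: tuple[int, ...] = (1, 2)
    tandem_duplications: list[tuple[str, int, int]] = field(
        default_factory=list
    )  # (locus_class, unit_length, copies)
    reversions: list[tuple[str, int]] = field(default_factory=list)
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )

    def validate(self) -> None:
        if self.snv_rate_per_mb < 0 or self.indel_rate_per_mb < 0:
            raise ValueError("variant rates must be >= 0")
        if self.class_mix:
            total = sum(self.class_mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"class mix must sum to 1, got {total}")
            unknown = set(self.class_mix) - set(DEFAULT_CLASS_MIX)
            if unknown:
                raise ValueError(f"unknown variant classes: {sorted(unknown)}")


@dataclass
class ArtifactSpec:
    homopolymer_error_rate: float = 0.0  # per qualifying tract
    n_gap_count: int = 0
    n_gap_lengths: tuple[int, ...] = (50,)
    n_gap_min_spacing: int = 0  # minimum distance between injected gaps

    def validate(self) -> None:
        if not 0 <= self.homopolymer_error_rate <= 1:
            raise ValueError("homopolymer_error_rate must be in [0,1]")
        if self.n_gap_count < 0:
            raise ValueError("n_gap_count must be >= 0")
        if any(l < 1 for l in self.n_gap_lengths):
            raise ValueError("N-gap lengths must be positive")


# ---------------------------------------------------------------------------
# truth records


@dataclass
class TruthRecord:
    chromosome: str
    pos0: int  # 0-based, anchored VCF-style for indels
    ref: str  # allele of the earlier strain in the interval
    alt: str  # allele of the later strain
    class_label: str
    interval: str  # "A>B" or "B>C"


@dataclass
class ArtifactRecord:
    chromosome: str
    pos0: int
    type: str  # homopolymer_error | n_gap
    strain: str
    detail: str = ""


@dataclass
class TruthSet:
    variants: list[TruthRecord] = field(default_factory=list)
    artifacts: list[ArtifactRecord] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["CHROM\tPOS0\tREF\tALT\tCLASS\tINTERVAL"]
        for v in sorted(
            self.variants, key=lambda r: (r.chromosome, r.pos0)
        ):
            lines.append(
                f"{v.chromosome}\t{v.pos0}\t{v.ref}\t{v.alt}\t"
                f"{v.class_label}\t{v.interval}"
            )
        return "\n".join(lines) + "\n"

    def artifacts_tsv(self) -> str:
        lines = ["CHROM\tPOS0\tTYPE\tSTRAIN\tDETAIL"]
        for a in sorted(
            self.artifacts, key=lambda r: (r.strain, r.chromosome, r.pos0)
        ):
            lines.append(
                f"{a.chromosome}\t{a.pos0}\t{a.type}\t{a.strain}\t{a.detail}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "TruthSet":
        variants = []
        for line in text.strip().splitlines()[1:]:
            chrom, pos0, ref, alt, label, interval = line.split("\t")
            variants.append(
                TruthRecord(chrom, int(pos0), ref, alt, label, interval)
            )
        return cls(variants=variants)


def apply_variants(
    assembly: GenomeAssembly,
    records: list[TruthRecord],
    reverse: bool = False,
) -> GenomeAssembly:
    """Apply truth records (ref -> alt, or alt -> ref with ``reverse``).

    Records are applied right-to-left per chromosome so earlier positions
    stay valid; the incumbent allele is verified before replacement.
    """
    per_chrom: dict[str, list[TruthRecord]] = {}
    for rec in records:
        per_chrom.setdefault(rec.chromosome, []).append(rec)
    out = dict(assembly.sequences)
    for chrom, recs in per_chrom.items():
        seq = out[chrom]
        for rec in sorted(recs, key=lambda r: -r.pos0):
            src, dst = (rec.alt, rec.ref) if reverse else (rec.ref, rec.alt)
            if seq[rec.pos0 : rec.pos0 + len(src)] != src:
                raise ValueError(
                    f"truth record at {chrom}:{rec.pos0} does not match "
                    "the assembly"
                )
            seq = seq[: rec.pos0] + dst + seq[rec.pos0 + len(src) :]
        out[chrom] = seq
    return GenomeAssembly(out, name=assembly.name)


# ---------------------------------------------------------------------------
# ancestor generation


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(
        np.array(list("ACGT"))[
            rng.choice(4, size=length, p=probs)
        ]
    )


def _make_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + stop


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    locus_start: int,
    cds_len: int,
    intron_lens: list[int],
) -> tuple[str, GeneModel]:
    """Forward-strand locus string plus the (possibly minus-strand) model."""
    cds = _make_cds(rng, cds_len // 3)
    n_introns = len(intron_lens)
    if n_introns:
        lo, hi = 3, cds_len - 3
        cuts = sorted(
            int(x) for x in rng.choice(
                np.arange(lo, hi), size=n_introns, replace=False
            )
        )
        # keep exon chunks at least 3 bases apart
        ok = all(b - a >= 3 for a, b in zip(cuts, cuts[1:]))
        if not ok:
            cuts = [
                lo + (hi - lo) * (i + 1) // (n_introns + 1)
                for i in range(n_introns)
            ]
    else:
        cuts = []
    pieces = []
    rel_exons = []
    prev = 0
    offset = 0
    for i, cut in enumerate(cuts + [cds_len]):
        exon = cds[prev:cut]
        rel_exons.append((offset, offset + len(exon)))
        pieces.append(exon)
        offset += len(exon)
        if i < len(cuts):
            ilen = intron_lens[i]
            intron = "GT" + _random_seq(rng, ilen - 4, 0.5) + "AG"
            pieces.append(intron)
            offset += ilen
        prev = cut
    forward = "".join(pieces)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        locus = forward
        exons = [(locus_start + s, locus_start + e) for s, e in rel_exons]
    else:
        locus = revcomp(forward)
        L = len(forward)
        exons = sorted(
            (locus_start + L - e, locus_start + L - s) for s, e in rel_exons
        )
    model = GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        exons=exons,
        protein_id=f"{gene_id}.p1",
    )
    return locus, model


def generate_ancestor(
    config: SimulationConfig,
) -> tuple[GenomeAssembly, list[GeneModel]]:
    """Deterministically generate the reference genome and its gene set."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []

    counts = [
        config.gene_count // config.n_chromosomes
        + (1 if i < config.gene_count % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    gene_no = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.chromosome_length
        n_genes = counts[ci]
        seq = list(_random_seq(rng, L, config.gc_fraction))

        loci: list[tuple[int, int]] = []
        if n_genes:
            exon_target = config.exon_fraction * L / n_genes
            intron_target = config.intron_fraction * L / n_genes
            cds_len = 3 * max(12, round(exon_target / 3))
            if intron_target < 40:
                intron_lens: list[int] = []
            else:
                n_introns = min(3, max(1, round(intron_target / 120)))
                each = max(40, round(intron_target / n_introns))
                intron_lens = [each] * n_introns
            locus_len = cds_len + sum(intron_lens)
            total = locus_len * n_genes
            min_gap = 20
            if total + (n_genes + 1) * min_gap > L:
                raise ValueError(
                    f"gene_count {config.gene_count} infeasible: "
                    f"{total} gene bases + spacing exceed chromosome "
                    f"length {L}"
                )
            slack = L - total - (n_genes + 1) * min_gap
            gaps = rng.multinomial(
                slack, [1.0 / (n_genes + 1)] * (n_genes + 1)
            )
            pos = 0
            for gi in range(n_genes):
                pos += min_gap + int(gaps[gi])
                gene_no += 1
                locus, model = _build_gene(
                    rng,
                    f"g{gene_no}",
                    chrom,
                    pos,
                    cds_len,
                    list(intron_lens),
                )
                seq[pos : pos + len(locus)] = locus
                loci.append((pos, pos + len(locus)))
                genes.append(model)
                pos += len(locus)
        sequences[chrom] = "".join(seq)

    assembly = GenomeAssembly(sequences, name="ancestor")
    assembly = _plant_homopolymer_tracts(assembly, genes, config, rng)
    for model in genes:
        genes_mod.validate_model(model, assembly)
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return assembly, genes


def _allowed_tract_intervals(
    assembly: GenomeAssembly, genes: list[GeneModel], chrom: str
) -> list[tuple[int, int]]:
    """Intervals where a homopolymer tract may be written without touching
    coding sequence or splice dinucleotides: intergenic space and intron
    interiors (3 bp clear of each boundary)."""
    L = assembly.length(chrom)
    intervals: list[tuple[int, int]] = []
    gene_spans = [
        (g.start, g.end, g) for g in genes if g.chromosome == chrom
    ]
    gene_spans.sort()
    prev = 0
    for s, e, g in gene_spans:
        if s - prev > 30:
            intervals.append((prev + 5, s - 5))
        for i_s, i_e in g.introns:
            if i_e - i_s > 26:
                intervals.append((i_s + 3, i_e - 3))
        prev = e
    if L - prev > 30:
        intervals.append((prev + 5, L - 5))
    return intervals


def _plant_homopolymer_tracts(
    assembly: GenomeAssembly,
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GenomeAssembly:
    out = dict(assembly.sequences)
    for chrom in assembly.chromosomes:
        n_tracts = round(
            config.homopolymer_tract_rate * assembly.length(chrom) / 1000
        )
        if not n_tracts:
            continue
        intervals = _allowed_tract_intervals(assembly, genes, chrom)
        if not intervals:
            continue
        weights = np.array([e - s for s, e in intervals], float)
        weights /= weights.sum()
        seq = list(out[chrom])
        used: list[tuple[int, int]] = []
        planted = 0
        attempts = 0
        while planted < n_tracts and attempts < 50 * n_tracts:
            attempts += 1
            iv = intervals[rng.choice(len(intervals), p=weights)]
            length = 5 + min(int(rng.geometric(0.45)) - 1, 7)
            if iv[1] - iv[0] <= length:
                continue
            start = int(rng.integers(iv[0], iv[1] - length))
            if any(start < e + 2 and start + length > s - 2 for s, e in used):
                continue
            base = "ACGT"[rng.integers(0, 4)]
            seq[start : start + length] = base * length
            used.append((start, start + length))
            planted += 1
        out[chrom] = "".join(seq)
    return GenomeAssembly(out, name=assembly.name)


# ---------------------------------------------------------------------------
# variant planting


class _SitePicker:
    def __init__(
        self,
        assembly: GenomeAssembly,
        genes: list[GeneModel],
        rng: np.random.Generator,
        forbidden: set[tuple[str, int]] | None = None,
        min_separation: int = 25,
    ):
        self.assembly = assembly
        self.genes = genes
        self.rng = rng
        self.occupied: set[tuple[str, int]] = set(forbidden or set())
        self.min_sep = min_separation
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chromosome, []).append(g)
        self.genes_with_introns = [g for g in genes if g.introns]

    def _free(self, chrom: str, pos: int, span: int = 1) -> bool:
        return not any(
            (chrom, p) in self.occupied
            for p in range(pos - self.min_sep, pos + span + self.min_sep)
        )

    def reserve(self, chrom: str, pos: int, span: int = 1) -> None:
        for p in range(pos, pos + span):
            self.occupied.add((chrom, p))

    def in_gene(self, chrom: str, pos: int) -> bool:
        return any(
            g.start - 5 <= pos < g.end + 5
            for g in self.by_chrom.get(chrom, [])
        )

    def random_position(self) -> tuple[str, int]:
        chroms = self.assembly.chromosomes
        lengths = np.array(
            [self.assembly.length(c) for c in chroms], float
        )
        ci = self.rng.choice(len(chroms), p=lengths / lengths.sum())
        chrom = chroms[ci]
        pos = int(self.rng.integers(10, self.assembly.length(chrom) - 10))
        return chrom, pos


def _other_bases(base: str) -> list[str]:
    return [b for b in "ACGT" if b != base]


def _creates_homopolymer(
    seq: str, pos: int, ref: str, alt: str, min_run: int = 5
) -> bool:
    lo = max(0, pos - min_run - 2)
    ctx = seq[lo : pos + len(ref) + min_run + 2]
    mut = genes_mod.CandidateMutation(
        gene_id="",
        chromosome="",
        position=pos,
        locus_position=pos - lo,
        ref=ref,
        alt=alt,
        region="",
        effect="",
    )
    return genes_mod.flag_homopolymer_artifact(mut, ctx, min_run=min_run)


def plant_variants(
    ancestor: GenomeAssembly,
    genes: list[GeneModel],
    spec: VariantSpec,
    seed: int,
    interval: str = "A>B",
    forbidden: set[tuple[str, int]] | None = None,
    max_retries: int = 300,
) -> tuple[GenomeAssembly, TruthSet]:
    """Plant classified variants onto a copy of ``ancestor``.

    Every coding plant is verified against the gene models at planting
    time (a missense really changes the protein, a nonsense really creates
    a stop, ...). Sites are chosen so that no plant mimics a homopolymer
    length artifact and no two plants interfere with each other.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    mb = ancestor.total_length / 1e6
    mix = spec.class_mix or dict(DEFAULT_CLASS_MIX)

    coding_requested = any(
        mix.get(c, 0) > 0
        for c in ("synonymous", "missense", "nonsense", "frameshift")
    )
    if coding_requested and not genes and (
        spec.snv_rate_per_mb > 0 or spec.indel_rate_per_mb > 0
    ):
        raise ValueError("coding variant classes requested but no gene models")

    picker = _SitePicker(ancestor, genes, rng, forbidden)

    def renorm(classes: tuple[str, ...]) -> tuple[list[str], np.ndarray]:
        usable = [
            c
            for c in classes
            if mix.get(c, 0) > 0
            and not (c == "intronic" and not picker.genes_with_introns)
            and not (
                c in ("synonymous", "missense", "nonsense", "frameshift")
                and not genes
            )
        ]
        if not usable:
            usable = ["intergenic"]
        w = np.array([mix.get(c, 0) for c in usable], float)
        if w.sum() == 0:
            w = np.ones(len(usable))
        return usable, w / w.sum()

    records: list[TruthRecord] = []

    def plant_one(cls: str, is_indel: bool) -> TruthRecord:
        for _ in range(max_retries):
            rec = _try_site(cls, is_indel)
            if rec is not None:
                return rec
        raise ValueError(
            f"could not place a variant of class {cls!r} after "
            f"{max_retries} retries"
        )

    def _try_site(cls: str, is_indel: bool) -> TruthRecord | None:
        if cls in ("synonymous", "missense", "nonsense", "frameshift"):
            gene = genes[int(rng.integers(0, len(genes)))]
            return _try_coding(gene, cls, is_indel)
        if cls == "intronic":
            pool = picker.genes_with_introns
            gene = pool[int(rng.integers(0, len(pool)))]
            introns = gene.introns
            i_s, i_e = introns[int(rng.integers(0, len(introns)))]
            if i_e - i_s <= 8:
                return None
            pos = int(rng.integers(i_s + 3, i_e - 3))
            chrom = gene.chromosome
        else:  # intergenic
            chrom, pos = picker.random_position()
            if picker.in_gene(chrom, pos):
                return None
        seq = ancestor[chrom]
        if is_indel:
            host = gene if cls == "intronic" else None
            return _try_noncoding_indel(chrom, pos, cls, seq, host)
        ref = seq[pos]
        if ref == "N" or not picker._free(chrom, pos):
            return None
        alt = _other_bases(ref)[int(rng.integers(0, 3))]
        if _creates_homopolymer(seq, pos, ref, alt):
            return None
        if cls == "intronic":
            mut = genes_mod.classify_variant(
                gene, gene.locus_sequence(ancestor), pos - gene.start, ref,
                alt,
            )
            if mut.effect != "intronic":
                return None
        picker.reserve(chrom, pos)
        return TruthRecord(chrom, pos, ref, alt, cls, interval)

    def _try_noncoding_indel(
        chrom: str, pos: int, cls: str, seq: str, host: GeneModel | None = None
    ) -> TruthRecord | None:
        length = int(
            spec.indel_lengths[rng.integers(0, len(spec.indel_lengths))]
        )
        if not picker._free(chrom, pos, length + 1):
            return None
        anchor = seq[pos]
        if anchor == "N":
            return None
        if rng.random() < 0.5:  # deletion
            ref = seq[pos : pos + 1 + length]
            alt = anchor
            if "N" in ref:
                return None
        else:  # insertion
            ins = "".join(
                "ACGT"[rng.integers(0, 4)] for _ in range(length)
            )
            ref = anchor
            alt = anchor + ins
        if _creates_homopolymer(seq, pos, ref, alt):
            return None
        if host is not None:
            mut = genes_mod.classify_variant(
                host, host.locus_sequence(ancestor), pos - host.start, ref,
                alt,
            )
            if mut.effect != "intronic":
                return None
        picker.reserve(chrom, pos, len(ref))
        return TruthRecord(chrom, pos, ref, alt, cls, interval)

    def _try_coding(
        gene: GeneModel, cls: str, is_indel: bool
    ) -> TruthRecord | None:
        locus = gene.locus_sequence(ancestor)
        chrom = gene.chromosome
        if cls == "frameshift" or is_indel:
            xs, xe = gene.exons[int(rng.integers(0, len(gene.exons)))]
            if xe - xs < 12:
                return None
            pos = int(rng.integers(xs + 4, xe - 6))
            length = int(
                spec.indel_lengths[
                    rng.integers(0, len(spec.indel_lengths))
                ]
            )
            if length % 3 == 0:
                length = 1
            seq = ancestor[chrom]
            if not picker._free(chrom, pos, length + 1):
                return None
            if rng.random() < 0.5 and pos + 1 + length < xe:
                ref = seq[pos : pos + 1 + length]
                alt = seq[pos]
            else:
                ins = "".join(
                    "ACGT"[rng.integers(0, 4)] for _ in range(length)
                )
                ref = seq[pos]
                alt = ref + ins
            if _creates_homopolymer(seq, pos, ref, alt):
                return None
            mut = genes_mod.classify_variant(
                gene, locus, pos - gene.start, ref, alt
            )
            if mut.effect != "frameshift":
                return None
            picker.reserve(chrom, pos, len(ref))
            return TruthRecord(chrom, pos, ref, alt, "frameshift", interval)

        # substitution classes: pick a codon, enumerate single-base edits
        n_codons = gene.spliced_length // 3
        codon_idx = int(rng.integers(1, n_codons - 1))
        cds = genes_mod.splice_cds(gene, ancestor)
        codon = cds[3 * codon_idx : 3 * codon_idx + 3]
        aa = genes_mod.translate_cds(codon + "TAA")[:1]
        choices = []
        for off in range(3):
            for b in _other_bases(codon[off]):
                new = codon[:off] + b + codon[off + 1 :]
                if new in genes_mod.STOP_CODONS:
                    if cls == "nonsense":
                        choices.append((off, b))
                    continue
                new_aa = genes_mod._TABLE.forward_table[new]
                if cls == "synonymous" and new_aa == aa:
                    choices.append((off, b))
                elif cls == "missense" and new_aa != aa:
                    choices.append((off, b))
        if not choices:
            return None
        off, b = choices[int(rng.integers(0, len(choices)))]
        pos, ref, alt = _genomic_substitution(gene, codon_idx, off, b, codon)
        seq = ancestor[chrom]
        if not picker._free(chrom, pos):
            return None
        if _creates_homopolymer(seq, pos, ref, alt):
            return None
        mut = genes_mod.classify_variant(
            gene, locus, pos - gene.start, ref, alt
        )
        if mut.effect != cls:
            return None
        picker.reserve(chrom, pos)
        return TruthRecord(chrom, pos, ref, alt, cls, interval)

    def _genomic_substitution(
        gene: GeneModel, codon_idx: int, off: int, new_base: str, codon: str
    ) -> tuple[int, str, str]:
        cds_off = 3 * codon_idx + off
        # map CDS offset to genomic position
        exons = gene.exons if gene.strand == "+" else gene.exons[::-1]
        acc = 0
        for xs, xe in exons:
            if cds_off < acc + (xe - xs):
                within = cds_off - acc
                if gene.strand == "+":
                    pos = xs + within
                    return pos, codon[off], new_base
                pos = xe - 1 - within
                return pos, revcomp(codon[off]), revcomp(new_base)
            acc += xe - xs
        raise AssertionError("CDS offset outside exons")

    n_snv = int(rng.poisson(spec.snv_rate_per_mb * mb))
    n_indel = int(rng.poisson(spec.indel_rate_per_mb * mb))
    snv_classes, snv_p = renorm(SNV_CLASSES)
    indel_classes, indel_p = renorm(INDEL_CLASSES)
    for _ in range(n_snv):
        cls = snv_classes[int(rng.choice(len(snv_classes), p=snv_p))]
        records.append(plant_one(cls, is_indel=False))
    for _ in range(n_indel):
        cls = indel_classes[int(rng.choice(len(indel_classes), p=indel_p))]
        records.append(plant_one(cls, is_indel=(cls != "frameshift")))
        # frameshift plants are indels by construction

    for locus_class, unit_len, copies in spec.tandem_duplications:
        records.append(
            _plant_duplication(
                ancestor, genes, picker, rng, locus_class, unit_len, copies,
                interval,
            )
        )
    for locus_class, unit_len in spec.reversions:
        records.append(
            _plant_reversion(
                ancestor, genes, picker, rng, locus_class, unit_len, interval
            )
        )

    derived = apply_variants(ancestor, records)
    return derived, TruthSet(variants=records)


def _plant_duplication(
    ancestor, genes, picker, rng, locus_class, unit_len, copies, interval
):
    """Tandem-duplicate ``unit_len`` bases to ``copies`` total copies."""
    for _ in range(300):
        if locus_class == "cds":
            if not genes:
                raise ValueError("cds duplication requested but no genes")
            gene = genes[int(rng.integers(0, len(genes)))]
            xs, xe = max(gene.exons, key=lambda iv: iv[1] - iv[0])
            if xe - xs < unit_len + 10:
                continue
            pos = int(rng.integers(xs + 3, xe - unit_len - 4))
            chrom = gene.chromosome
        else:
            chrom, pos = picker.random_position()
            if picker.in_gene(chrom, pos):
                continue
        seq = ancestor[chrom]
        unit = seq[pos + 1 : pos + 1 + unit_len]
        if "N" in unit or len(set(unit)) == 1:
            continue
        if not picker._free(chrom, pos, unit_len + 1):
            continue
        ref = seq[pos]
        alt = ref + unit * (copies - 1)
        if _creates_homopolymer(seq, pos, ref, alt):
            continue
        label = "tandem_duplication"
        if locus_class == "cds":
            mut = genes_mod.classify_variant(
                gene, gene.locus_sequence(ancestor), pos - gene.start, ref,
                alt,
            )
            label = f"tandem_duplication:{mut.effect}"
        picker.reserve(chrom, pos, unit_len + 1)
        return TruthRecord(chrom, pos, ref, alt, label, interval)
    raise ValueError(
        f"could not place a tandem duplication of unit {unit_len} "
        f"in class {locus_class!r}"
    )


def _plant_reversion(
    ancestor, genes, picker, rng, locus_class, unit_len, interval
):
    """Delete one copy of a naturally occurring adjacent tandem repeat."""
    chroms = ancestor.chromosomes
    order = rng.permutation(len(chroms))
    for ci in order:
        chrom = chroms[ci]
        seq = ancestor[chrom]
        start = int(rng.integers(0, max(1, len(seq) - 3 * unit_len)))
        for pos in range(start, len(seq) - 2 * unit_len - 1):
            unit = seq[pos + 1 : pos + 1 + unit_len]
            if "N" in unit or len(set(unit)) == 1:
                continue
            if seq[pos + 1 + unit_len : pos + 1 + 2 * unit_len] != unit:
                continue
            in_gene = picker.in_gene(chrom, pos)
            if (locus_class == "cds") != in_gene:
                continue
            if not picker._free(chrom, pos, unit_len + 1):
                continue
            ref = seq[pos] + unit
            alt = seq[pos]
            if _creates_homopolymer(seq, pos, ref, alt):
                continue
            picker.reserve(chrom, pos, unit_len + 1)
            return TruthRecord(
                chrom, pos, ref, alt, "reversion", interval
            )
    raise ValueError(
        f"no adjacent tandem repeat of unit {unit_len} found for a "
        f"reversion in class {locus_class!r}"
    )


# ---------------------------------------------------------------------------
# artifacts


def inject_artifacts(
    assembly: GenomeAssembly,
    spec: ArtifactSpec,
    seed: int,
    strain: str = "",
) -> tuple[GenomeAssembly, list[ArtifactRecord]]:
    """Inject homopolymer length errors and N-gaps; records are exhaustive
    and expressed in input coordinates."""
    spec.validate()
    rng = np.random.default_rng(seed)
    records: list[ArtifactRecord] = []
    edits: dict[str, list[tuple[int, int, str]]] = {}

    if spec.homopolymer_error_rate > 0:
        for chrom in assembly.chromosomes:
            for m in _HP_RE.finditer(assembly[chrom]):
                if rng.random() >= spec.homopolymer_error_rate:
                    continue
                run_len = m.end() - m.start()
                delta = int(
                    rng.choice([-2, -1, 1, 2], p=[0.1, 0.4, 0.4, 0.1])
                )
                if run_len + delta < 1:
                    continue
                base = m.group(1)
                edits.setdefault(chrom, []).append(
                    (m.start(), m.end(), base * (run_len + delta))
                )
                records.append(
                    ArtifactRecord(
                        chrom,
                        m.start(),
                        "homopolymer_error",
                        strain,
                        f"{base}:{run_len}->{run_len + delta}",
                    )
                )

    if spec.n_gap_count:
        lengths = [
            int(spec.n_gap_lengths[rng.integers(0, len(spec.n_gap_lengths))])
            for _ in range(spec.n_gap_count)
        ]
        chroms = assembly.chromosomes
        sizes = np.array([assembly.length(c) for c in chroms], float)
        placed_spans: dict[str, list[tuple[int, int]]] = {}
        for length in lengths:
            if all(assembly.length(c) <= length + 2 for c in chroms):
                raise ValueError(
                    f"requested N-gap of {length} does not fit in any "
                    "chromosome"
                )
            for _ in range(1000):
                chrom = chroms[
                    int(rng.choice(len(chroms), p=sizes / sizes.sum()))
                ]
                if assembly.length(chrom) <= length + 2:
                    continue
                start = int(
                    rng.integers(1, assembly.length(chrom) - length - 1)
                )
                spans = placed_spans.setdefault(chrom, [])
                margin = max(1, spec.n_gap_min_spacing)
                if any(
                    start < e + margin and start + length > s - margin
                    for s, e in spans
                ):
                    continue
                segment = assembly[chrom][start : start + length]
                if "N" in segment:
                    continue
                spans.append((start, start + length))
                edits.setdefault(chrom, []).append(
                    (start, start + length, "N" * length)
                )
                records.append(
                    ArtifactRecord(chrom, start, "n_gap", strain, str(length))
                )
                break
            else:
                raise ValueError(
                    f"could not place an N-gap of length {length}"
                )

    out = dict(assembly.sequences)
    for chrom, chrom_edits in edits.items():
        seq = out[chrom]
        for start, end, repl in sorted(chrom_edits, key=lambda e: -e[0]):
            seq = seq[:start] + repl + seq[end:]
        out[chrom] = seq
    return GenomeAssembly(out, name=assembly.name), records


# ---------------------------------------------------------------------------
# trio construction


@dataclass
class Trio:
    """A serial strain trio: B carries the annotation; A and C differ from
    it by the planted variants of the 'A>B' and 'B>C' intervals."""

    reference: GenomeAssembly  # clean middle strain (annotation frame)
    genes: list[GeneModel]
    strains: dict[str, GenomeAssembly]  # observed assemblies, with artifacts
    clean: dict[str, GenomeAssembly]  # artifact-free assemblies
    truth: TruthSet
    seed: int = 0


def make_trio(
    config: SimulationConfig,
    spec_ab: VariantSpec | None = None,
    spec_bc: VariantSpec | None = None,
    artifacts_a: ArtifactSpec | None = None,
    artifacts_b: ArtifactSpec | None = None,
    artifacts_c: ArtifactSpec | None = None,
    seed: int | None = None,
) -> Trio:
    """Build an A -> B -> C trio with known ground truth.

    The reference genome is the middle strain B. Strain A is reconstructed
    by planting the 'A>B' alleles (so the truth records read ref=A allele,
    alt=B allele), and strain C by planting the 'B>C' alleles onto B.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sub = [int(x) for x in rng.integers(0, 2**31 - 1, size=6)]
    config = replace(config, seed=sub[0])
    reference, genes = generate_ancestor(config)
    reference.name = "strainB"

    spec_ab = spec_ab or VariantSpec()
    spec_bc = spec_bc or VariantSpec()

    a_clean, truth_a = plant_variants(
        reference, genes, spec_ab, seed=sub[1], interval="A>B"
    )
    a_clean.name = "strainA"
    # records from planting read (ref=B allele, alt=planted-A allele);
    # flip them so ref is always the earlier strain's allele
    for rec in truth_a.variants:
        rec.ref, rec.alt = rec.alt, rec.ref
    forbidden = {
        (r.chromosome, p)
        for r in truth_a.variants
        for p in range(r.pos0 - 5, r.pos0 + max(len(r.ref), len(r.alt)) + 5)
    }
    c_clean, truth_c = plant_variants(
        reference, genes, spec_bc, seed=sub[2], interval="B>C",
        forbidden=forbidden,
    )
    c_clean.name = "strainC"

    artifacts: list[ArtifactRecord] = []
    observed = {}
    for label, clean_asm, art_spec, art_seed in (
        ("A", a_clean, artifacts_a, sub[3]),
        ("B", reference, artifacts_b, sub[4]),
        ("C", c_clean, artifacts_c, sub[5]),
    ):
        if art_spec is None:
            observed[label] = clean_asm.copy()
        else:
            obs, recs = inject_artifacts(
                clean_asm, art_spec, art_seed, strain=label
            )
            observed[label] = obs
            artifacts.extend(recs)

    return Trio(
        reference=reference,
        genes=genes,
        strains=observed,
        clean={"A": a_clean, "B": reference, "C": c_clean},
        truth=TruthSet(
            variants=truth_a.variants + truth_c.variants,
            artifacts=artifacts,
        ),
        seed=seed,
    )
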
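"""Tests for gene comparison, effect classification, and the funnel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microdiv.genes import (
    CandidateMutation,
    FunnelReport,
    GeneUnclassifiable,
    classify_variant,
    diff_gene,
    flag_homopolymer_artifact,
    kmer_support,
    polarize_mutation,
    run_funnel,
    sequential_map,
    splice_and_translate,
    translate_cds,
)
from microdiv.models import GeneModel, GenomeAssembly, revcomp
from microdiv.simulate import ArtifactSpec, SimulationConfig, make_trio
from conftest import match_mutations
from oracle import random_seq


def single_exon_gene(cds: str, pad: str = "ACGTAC" * 20, strand: str = "+"):
    """A single-exon gene embedded in padding; returns (assembly, model)."""
    locus = cds if strand == "+" else revcomp(cds)
    seq = pad + locus + pad
    model = GeneModel(
        gene_id="g1",
        chromosome="c",
        strand=strand,
        exons=[(len(pad), len(pad) + len(locus))],
    )
    return GenomeAssembly({"c": seq}), model


def codon_gene(codons: list[str], at: int, replacement: str):
    """CDS of given codons; returns ref CDS and the CDS with codon ``at``
    (1-based) replaced."""
    ref = "ATG" + "".join(codons) + "TAA"
    mutated = list(codons)
    mutated[at - 2] = replacement  # -2: codon 1 is ATG
    alt = "ATG" + "".join(mutated) + "TAA"
    return ref, alt


class TestTranslation:
    def test_simple_cds(self):
        asm, model = single_exon_gene("ATGAGCTAA")
        cds, protein = splice_and_translate(model, asm)
        assert cds == "ATGAGCTAA"
        assert protein == "MS"

    @pytest.mark.parametrize(
        "codon,aa",
        [("AGC", "S"), ("ACC", "T"), ("CAG", "Q"), ("CTT", "L"),
         ("TTT", "F"), ("GAC", "D"), ("TAC", "Y"), ("TGG", "W")],
    )
    def test_codon_table(self, codon, aa):
        assert translate_cds(codon) == aa

    @pytest.mark.parametrize("stop", ["TAA", "TAG", "TGA"])
    def test_stops(self, stop):
        assert translate_cds("ATGAGC" + stop + "AGC") == "MS"

    def test_n_codon_is_indeterminate(self):
        assert translate_cds("ATGANCTAA") == "MX"

    def test_reverse_strand(self):
        asm, model = single_exon_gene("ATGAGCGGATAA", strand="-")
        cds, protein = splice_and_translate(model, asm)
        assert cds == "ATGAGCGGATAA"
        assert protein == "MSG"

    def test_spliced_gene(self):
        # two exons with a GT..AG intron between
        exon1, exon2 = "ATGAGC", "GGATAA"
        intron = "GT" + "ACGT" * 5 + "AG"
        pad = "CCAATT" * 10
        seq = pad + exon1 + intron + exon2 + pad
        model = GeneModel(
            gene_id="g1",
            chromosome="c",
            strand="+",
            exons=[
                (len(pad), len(pad) + 6),
                (len(pad) + 6 + len(intron), len(pad) + 12 + len(intron)),
            ],
        )
        cds, protein = splice_and_translate(
            model, GenomeAssembly({"c": seq})
        )
        assert cds == "ATGAGCGGATAA"
        assert protein == "MSG"

    def test_strand_safety_property(self, ancestor):
        """Reverse-complementing a locus and flipping strand preserves the
        protein."""
        asm, genes = ancestor
        for g in genes[:10]:
            locus = g.locus_sequence(asm)
            _, fwd_protein = splice_and_translate(
                g.shifted(-g.start), GenomeAssembly({g.chromosome: locus})
            )
            L = len(locus)
            flipped = GeneModel(
                gene_id=g.gene_id,
                chromosome=g.chromosome,
                strand="-" if g.strand == "+" else "+",
                exons=[
                    (L - e + 0, L - s)
                    for s, e in [
                        (s - g.start, e - g.start) for s, e in g.exons
                    ]
                ],
            )
            _, rev_protein = splice_and_translate(
                flipped, GenomeAssembly({g.chromosome: revcomp(locus)})
            )
            assert rev_protein == fwd_protein


class TestClassifyVariant:
    def test_missense_rendering(self):
        codons = ["CTT"] * 407  # codon 408 (1-based) is the last CTT
        ref, alt = codon_gene(codons, 408, "TTT")
        asm, model = single_exon_gene(ref)
        pos = model.start + 3 * 407  # first base of codon 408
        mut = classify_variant(
            model, ref, 3 * 407, "C", "T"
        )
        assert mut.effect == "missense"
        assert mut.protein_change == "Leu(CTT) 408 Phe(TTT)"
        del asm, pos, alt

    def test_nonsense_rendering(self):
        codons = ["GGC"] * 419
        codons[418] = "CAG"  # codon 420
        ref = "ATG" + "".join(codons) + "TAA"
        mut = classify_variant(
            GeneModel("g", "c", "+", [(0, len(ref))]),
            ref,
            3 * 419,
            "C",
            "T",
        )
        assert mut.effect == "nonsense"
        assert mut.protein_change == "Gln(CAG) 420 STOP(TAG)"

    def test_ser_thr_example(self):
        ref = "ATG" + "AGC" + "TAA"
        mut = classify_variant(
            GeneModel("g", "c", "+", [(0, 9)]), ref, 4, "G", "C"
        )
        assert mut.effect == "missense"
        assert mut.protein_change == "Ser(AGC) 2 Thr(ACC)"

    def test_synonymous_wobble(self):
        ref = "ATG" + "GCT" + "TAA"
        mut = classify_variant(
            GeneModel("g", "c", "+", [(0, 9)]), ref, 5, "T", "C"
        )
        assert mut.effect == "synonymous"

    def test_single_base_insertion_frameshift(self):
        ref = "ATG" + "GCTAAGCCGTGG" * 8 + "TAA"
        mut = classify_variant(
            GeneModel("g", "c", "+", [(0, len(ref))]),
            ref,
            10,
            ref[10],
            ref[10] + "C",
        )
        assert mut.effect == "frameshift"
        assert mut.protein_change == "Premature stop"

    def test_intronic_variant(self):
        exon1, exon2 = "ATGAGC", "GGATAA"
        intron = "GT" + "ACGTACGTAC" + "AG"
        locus = exon1 + intron + exon2
        model = GeneModel(
            "g", "c", "+", [(0, 6), (6 + len(intron), len(locus))]
        )
        mut = classify_variant(model, locus, 10, locus[10], "A" if locus[10] != "A" else "C")
        assert mut.region == "intron"
        assert mut.effect == "intronic"

    def test_splice_site_detected(self):
        exon1, exon2 = "ATGAGC", "GGATAA"
        intron = "GT" + "ACGTACGTAC" + "AG"
        locus = exon1 + intron + exon2
        model = GeneModel(
            "g", "c", "+", [(0, 6), (6 + len(intron), len(locus))]
        )
        # hit the donor GT
        mut = classify_variant(model, locus, 6, "G", "A")
        assert mut.region == "splice_site"
        assert mut.effect == "splice_site"

    def test_inframe_restoration_flag(self):
        """A 20-base insertion that truncates the protein (the broken,
        longer allele) is flagged as a frame restoration when seen from
        the functional reference."""
        ref_cds = "ATG" + "GCT" * 30 + "TAA"
        # in-frame stop appears once the 20-base unit is inserted at a
        # codon boundary
        unit = "TTAAGCTAAGCTAAGCTAAG"
        model = GeneModel("g", "c", "+", [(0, len(ref_cds))])
        mut = classify_variant(
            model, ref_cds, 29, ref_cds[29], ref_cds[29] + unit
        )
        assert mut.effect == "frameshift"  # 20 % 3 != 0
        assert mut.restores_frame

    def test_ref_mismatch_raises(self):
        with pytest.raises(GeneUnclassifiable):
            classify_variant(
                GeneModel("g", "c", "+", [(0, 9)]),
                "ATGAGCTAA",
                3,
                "T",
                "C",
            )


class TestDiffGene:
    def test_single_snv(self):
        rng = np.random.default_rng(0)
        cds = "ATG" + "".join(
            rng.choice(["GCT", "AAG", "CCG", "TGG"], 60)
        ) + "TAA"
        asm, model = single_exon_gene(cds)
        locus = model.locus_sequence(asm)
        other = locus[:50] + ("A" if locus[50] != "A" else "G") + locus[51:]
        muts = diff_gene(model, locus, other, strain="A")
        assert len(muts) == 1
        assert muts[0].locus_position == 50
        assert muts[0].strain == "A"

    def test_insertion_reported_as_indel(self):
        rng = np.random.default_rng(1)
        cds = "ATG" + "".join(
            rng.choice(["GCT", "AAG", "CCG", "TGG"], 60)
        ) + "TAA"
        asm, model = single_exon_gene(cds)
        locus = model.locus_sequence(asm)
        other = locus[:77] + "ACGT" + locus[77:]
        muts = diff_gene(model, locus, other)
        assert len(muts) == 1
        assert muts[0].is_indel
        assert len(muts[0].alt) - len(muts[0].ref) == 4

    def test_identical_sequences(self):
        asm, model = single_exon_gene("ATGAGCTAA")
        locus = model.locus_sequence(asm)
        assert diff_gene(model, locus, locus) == []


class TestHomopolymerFlag:
    def _mut(self, pos, ref, alt):
        return CandidateMutation(
            gene_id="g",
            chromosome="c",
            position=pos,
            locus_position=pos,
            ref=ref,
            alt=alt,
            region="exon",
            effect="frameshift",
        )

    def test_deletion_in_long_run_flagged(self):
        ctx = "GCGT" + "A" * 6 + "CTGC"
        mut = self._mut(3, "TA", "T")
        assert flag_homopolymer_artifact(mut, ctx)

    def test_mixed_context_substitution_not_flagged(self):
        ctx = "TTACGTGCA"
        mut = self._mut(4, "G", "C")
        assert not flag_homopolymer_artifact(mut, ctx)

    def test_insertion_extending_four_run_not_flagged(self):
        # reference run of 4 -> below the threshold applied pre-mutation
        ctx = "GCGT" + "A" * 4 + "CTGC"
        mut = self._mut(3, "T", "TA")
        assert not flag_homopolymer_artifact(mut, ctx)

    def test_substitution_creating_run_flagged(self):
        ctx = "GC" + "A" * 4 + "T" + "GCGC"
        mut = self._mut(6, "T", "A")  # AAAAT -> AAAAA
        assert flag_homopolymer_artifact(mut, ctx)


class TestKmerSupport:
    def _setup(self):
        rng = np.random.default_rng(5)
        ctx = random_seq(rng, 200)
        mut = CandidateMutation(
            gene_id="g",
            chromosome="c",
            position=100,
            locus_position=100,
            ref=ctx[100],
            alt="A" if ctx[100] != "A" else "G",
            region="exon",
            effect="missense",
        )
        alt_ctx = ctx[:100] + mut.alt + ctx[101:]
        return ctx, alt_ctx, mut

    def test_supported(self):
        ctx, alt_ctx, mut = self._setup()
        reads = [alt_ctx[60:160] for _ in range(5)]
        assert kmer_support(mut, reads, ctx) == "supported"

    def test_refuted(self):
        ctx, alt_ctx, mut = self._setup()
        reads = [ctx[60:160] for _ in range(5)]
        assert kmer_support(mut, reads, ctx) == "refuted"

    def test_mixed(self):
        ctx, alt_ctx, mut = self._setup()
        reads = [ctx[60:160]] * 4 + [alt_ctx[60:160]] * 4
        assert kmer_support(mut, reads, ctx) == "mixed"

    def test_untested(self):
        ctx, alt_ctx, mut = self._setup()
        assert kmer_support(mut, [], ctx) == "untested"

    def test_reverse_strand_reads_count(self):
        ctx, alt_ctx, mut = self._setup()
        reads = [revcomp(alt_ctx[60:160]) for _ in range(5)]
        assert kmer_support(mut, reads, ctx) == "supported"

    def test_even_k_rejected(self):
        ctx, alt_ctx, mut = self._setup()
        with pytest.raises(ValueError, match="odd"):
            kmer_support(mut, [], ctx, k=30)


class TestPolarize:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            (("C", "C", "T"), "B>C"),
            (("G", "C", "C"), "A>B"),
            (("A", "A", "A"), "none"),
            (("A", "C", "A"), "conflict"),
            (("A", "C", "G"), "conflict"),
            (("N", "C", "C"), "indeterminate"),
        ],
    )
    def test_logic_table(self, alleles, expected):
        assert polarize_mutation(*alleles) == expected


class TestSequentialMap:
    def test_identical_genomes(self, ancestor):
        asm, genes = ancestor
        placements = sequential_map(genes, asm, asm.copy("t"))
        assert all(p.coverage == 1.0 for p in placements)
        assert all(p.identity == 1.0 for p in placements)
        assert all(p.synteny_ok for p in placements)
        for g, p in zip(genes, placements):
            assert (p.target_start, p.target_end) == (g.start, g.end)

    def test_single_snv_detected(self, ancestor):
        asm, genes = ancestor
        g = genes[5]
        mid = (g.start + g.end) // 2
        seq = asm[g.chromosome]
        other = seq[:mid] + ("A" if seq[mid] != "A" else "G") + seq[mid + 1 :]
        target = GenomeAssembly({g.chromosome: other}, name="t")
        placements = sequential_map(genes, asm, target)
        assert placements[5].identity < 1.0
        assert placements[5].coverage == 1.0
        others = [p for i, p in enumerate(placements) if i != 5]
        assert all(p.identity == 1.0 for p in others)

    def test_n_flag(self, ancestor):
        asm, genes = ancestor
        g = genes[3]
        mid = (g.start + g.end) // 2
        seq = asm[g.chromosome]
        other = seq[:mid] + "NNNNN" + seq[mid + 5 :]
        target = GenomeAssembly({g.chromosome: other}, name="t")
        placements = sequential_map(genes, asm, target)
        assert placements[3].contains_n

    def test_absent_gene_coverage_zero(self, ancestor):
        asm, genes = ancestor
        g = genes[4]
        seq = asm[g.chromosome]
        rng = np.random.default_rng(13)
        other = seq[: g.start] + random_seq(rng, g.end - g.start) + seq[g.end :]
        target = GenomeAssembly({g.chromosome: other}, name="t")
        placements = sequential_map(genes, asm, target)
        assert placements[4].coverage == 0.0


class TestFunnelReport:
    def test_paper_stage_counts(self):
        report = FunnelReport.from_stage_counts(8701, 456, 144, 103, 31)
        assert report.identical == 8245
        assert report.identical_pct == 94.7
        assert report.intronic_only == 312
        assert report.intronic_pct == 68.4
        assert report.remaining == 41
        assert report.confirmed == 10
        report.check()

    def test_telescoping_violation_raises(self):
        with pytest.raises(ValueError, match="funnel"):
            FunnelReport(
                total_genes=10,
                identical=5,
                candidates=4,  # != 10 - 5
                intronic_only=2,
                exonic_candidates=2,
                removed_synonymous_or_n=1,
                remaining=1,
                homopolymer_artifacts=0,
                confirmed=1,
            )

    @given(
        total=st.integers(1, 10_000),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_from_stage_counts_always_telescopes(self, total, data):
        candidates = data.draw(st.integers(0, total))
        exonic = data.draw(st.integers(0, candidates))
        removed = data.draw(st.integers(0, exonic))
        artifacts = data.draw(st.integers(0, exonic - removed))
        report = FunnelReport.from_stage_counts(
            total, candidates, exonic, removed, artifacts
        )
        report.check()


class TestRunFunnel:
    def test_zero_variants_all_identical(self):
        trio = make_trio(
            SimulationConfig(chromosome_length=60_000, gene_count=15, seed=23)
        )
        report, muts = run_funnel(
            trio.genes,
            trio.strains["B"],
            trio.strains["A"],
            trio.strains["C"],
        )
        assert report.identical == report.total_genes == 15
        assert report.confirmed == 0
        assert muts == []

    def test_planted_recovery(self, clean_trio):
        trio = clean_trio
        report, muts = run_funnel(
            trio.genes,
            trio.strains["B"],
            trio.strains["A"],
            trio.strains["C"],
        )
        report.check()
        missed, extra = match_mutations(trio, muts)
        assert missed == []
        assert extra == []
        assert report.confirmed == len(
            {m.gene_id for m in muts}
        )

    def test_polarization_matches_construction(self, clean_trio):
        trio = clean_trio
        _, muts = run_funnel(
            trio.genes,
            trio.strains["B"],
            trio.strains["A"],
            trio.strains["C"],
        )
        assert muts
        assert all(m.appearance in ("A>B", "B>C") for m in muts)

    def test_artifact_only_trio_rejected(self):
        trio = make_trio(
            SimulationConfig(
                chromosome_length=100_000,
                gene_count=25,
                homopolymer_tract_rate=1.0,
                seed=29,
            ),
            artifacts_a=ArtifactSpec(homopolymer_error_rate=1.0),
            artifacts_c=ArtifactSpec(homopolymer_error_rate=1.0),
        )
        report, muts = run_funnel(
            trio.genes,
            trio.strains["B"],
            trio.strains["A"],
            trio.strains["C"],
        )
        report.check()
        assert report.confirmed == 0
        assert muts == []
        assert report.homopolymer_artifacts > 0

    def test_mismatched_chromosomes_fail_fast(self, ancestor):
        asm, genes = ancestor
        renamed = GenomeAssembly(
            {"weird": asm["chr1"]}, name="x"
        )
        with pytest.raises(ValueError, match="chromosome names"):
            run_funnel(genes, asm, renamed, asm.copy("c2"))

    def test_mutation_table_rendering(self, clean_trio):
        from microdiv.genes import mutations_to_table, mutations_to_vcf

        trio = clean_trio
        _, muts = run_funnel(
            trio.genes,
            trio.strains["B"],
            trio.strains["A"],
            trio.strains["C"],
        )
        table = mutations_to_table(muts)
        assert table.startswith("gene\t")
        assert len(table.strip().splitlines()) == len(muts) + 1
        vcf = mutations_to_vcf(muts, "strainB")
        assert vcf.startswith("##fileformat=VCFv4.2")
        body = [l for l in vcf.splitlines() if not l.startswith("#")]
        assert len(body) == len(muts)
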
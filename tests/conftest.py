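from __future__ import annotations

import pytest

from microdiv.simulate import (
    ArtifactSpec,
    SimulationConfig,
    VariantSpec,
    generate_ancestor,
    make_trio,
)

CODING_CLASSES = {
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice_site",
}


@pytest.fixture(scope="session")
def ancestor():
    return generate_ancestor(
        SimulationConfig(chromosome_length=120_000, gene_count=30, seed=7)
    )


@pytest.fixture(scope="session")
def clean_trio():
    """Artifact-free trio with planted variants in both intervals."""
    return make_trio(
        SimulationConfig(chromosome_length=150_000, gene_count=50, seed=3),
        VariantSpec(snv_rate_per_mb=100, indel_rate_per_mb=20),
        VariantSpec(snv_rate_per_mb=100, indel_rate_per_mb=20),
    )


@pytest.fixture(scope="session")
def gapped_trio():
    """Trio whose middle strain carries well-separated N-gaps."""
    return make_trio(
        SimulationConfig(chromosome_length=120_000, gene_count=30, seed=17),
        VariantSpec(),
        VariantSpec(),
        artifacts_b=ArtifactSpec(
            n_gap_count=12,
            n_gap_lengths=(30, 80, 150),
            n_gap_min_spacing=1500,
        ),
    )


def truth_coding_variants(trio):
    return [
        v
        for v in trio.truth.variants
        if v.class_label in ("missense", "nonsense", "frameshift")
        or v.class_label.startswith("tandem_duplication")
    ]


def match_mutations(trio, mutations):
    """Match confirmed funnel mutations against planted coding truth.

    SNVs must agree on position and (unordered) allele pair; indels on the
    net length change and approximate position. Returns (missed, extra)
    lists; both empty means precision = recall = 1.
    """
    truth = truth_coding_variants(trio)
    unmatched = list(mutations)
    missed = []
    for v in truth:
        expected_effect = (
            v.class_label.split(":")[-1]
            if ":" in v.class_label
            else v.class_label
        )
        hit = None
        for m in unmatched:
            if m.chromosome != v.chromosome:
                continue
            if m.appearance != v.interval:
                continue
            if len(v.ref) == len(v.alt) == 1:
                if (
                    m.position == v.pos0
                    and {m.ref, m.alt} == {v.ref, v.alt}
                    and m.effect == expected_effect
                ):
                    hit = m
                    break
            else:
                delta_truth = abs(len(v.ref) - len(v.alt))
                delta_m = abs(len(m.ref) - len(m.alt))
                if (
                    delta_m == delta_truth
                    and abs(m.position - v.pos0) <= delta_truth + 5
                    and m.effect == expected_effect
                ):
                    hit = m
                    break
        if hit is None:
            missed.append(v)
        else:
            unmatched.remove(hit)
    return missed, unmatched
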
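# microdiv

Micro-divergence analysis for near-identical haploid clonal genome
assemblies — e.g. an original isolate and its lab-passaged derivatives.
The package covers four stages, each usable on its own:

* **simulate** — generate a synthetic serial strain trio (A → B → C) with a
  multi-gene reference genome, planted and class-verified variants
  (intergenic / intronic / synonymous / missense / nonsense / frameshift /
  tandem duplications), homopolymer-length assembly artifacts, N-gaps, and
  a complete machine-readable truth set.
* **polish** — fill undetermined (N) regions of a draft assembly by
  flanking consensus against two higher-quality relative assemblies:
  copy when the relatives agree, consensus (with N at disagreements, up to
  a configurable limit) when they nearly agree, skip on length mismatch,
  and trim erroneously duplicated sequence when the placed flanks overlap.
* **divergence** — align assemblies with a unique-k-mer anchored,
  affine-gap aligner and report gap-excluded identity
  (matches / (matches+mismatches) over gap-free columns), gap-compressed
  divergence (each maximal indel run counts as one event), per-Mb
  difference frequencies, optional N-masking, and optional deletion of
  homopolymer runs (≥5 by default) from both genomes before re-alignment.
* **genes** — map a reference gene set syntenically and sequentially onto
  the other strains, diff each gene, classify every difference by
  re-translation, flag homopolymer-length artifacts, optionally check
  allele support with read k-mers, polarize each mutation onto a culture
  interval (A>B vs B>C) by three-way allele comparison, and report the
  telescoping filtering funnel.

## CLI

All commands log to stderr and write results to files only.

```sh
# synthetic trio with ground truth
microdiv simulate --config run.conf --out sim/ --seed 1

# gap polishing
microdiv polish --draft draft.fa --ref-a relA.fa --ref-b relB.fa \
    --flank 1000 --max-ambiguous 10 --out polished.fa

# pairwise identity metrics (Table-style TSV + JSON)
microdiv divergence --query a.fa --subject b.fa \
    --min-block 1000000 --strip-homopolymers --mask-n --out report

# gene funnel
microdiv genes funnel --ref strainB.fa --gff strainB.gff3 \
    --strain-a strainA.fa --strain-c strainC.fa --out funnel/

# full pipeline on a seeded synthetic trio
microdiv run --config run.conf --out results/ --seed 1
```

Config files are flat `key = value` text; every key mirrors a CLI flag
(see `microdiv.cli.RUN_DEFAULTS` for the full list and defaults). All
thresholds default to the analysis' published values (flank 1000,
max-ambiguous 10, min-block 1 Mb, homopolymer run 5) and can be scaled
down for desk-size runs.

## Conventions

Coordinates are 0-based half-open internally; 1-based only in rendered
reports. Assemblies are uppercase A/C/G/T/N. All randomness flows from a
single seed per run; identical seeds give byte-identical outputs.
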
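"""Core domain objects shared by every pipeline stage.

Coordinates are 0-based, half-open everywhere in code; 1-based fully-closed
coordinates appear only in human-readable report rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeAssembly:
    """A named, ordered collection of chromosome sequences (A/C/G/T/N).

    Lowercase input is uppercased on construction; any character outside
    the A/C/G/T/N alphabet raises.
    """

    def __init__(self, sequences: dict[str, str], name: str = "assembly"):
        self.name = name
        cleaned: dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"{name}/{chrom}: invalid characters {sorted(bad)!r}; "
                    "expected A/C/G/T/N"
                )
            cleaned[chrom] = seq
        self.sequences = cleaned

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeAssembly):
            return NotImplemented
        return self.sequences == other.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def n_count(self) -> int:
        return sum(s.count("N") for s in self.sequences.values())

    def replace(self, chrom: str, seq: str) -> "GenomeAssembly":
        new = dict(self.sequences)
        new[chrom] = seq
        return GenomeAssembly(new, name=self.name)

    def copy(self, name: str | None = None) -> "GenomeAssembly":
        return GenomeAssembly(dict(self.sequences), name=name or self.name)


@dataclass
class GeneModel:
    """Stranded exon/CDS structure of one protein-coding gene.

    Exons are genomic intervals sorted by start; the CDS here always spans
    the exons exactly (UTR-less models). ``phases`` follow GFF3 semantics,
    one per CDS interval in genomic order.
    """

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    phases: list[int] = field(default_factory=list)
    protein_id: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if not self.phases:
            self.phases = self._compute_phases()

    def _compute_phases(self) -> list[int]:
        order = self.exons if self.strand == "+" else self.exons[::-1]
        phases, acc = {}, 0
        for s, e in order:
            phases[(s, e)] = (3 - acc % 3) % 3
            acc += e - s
        return [phases[iv] for iv in self.exons]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def locus_sequence(self, assembly: GenomeAssembly) -> str:
        """Genomic (forward-strand) sequence of the gene span."""
        return assembly[self.chromosome][self.start : self.end]

    def shifted(self, offset: int) -> "GeneModel":
        return GeneModel(
            gene_id=self.gene_id,
            chromosome=self.chromosome,
            strand=self.strand,
            exons=[(s + offset, e + offset) for s, e in self.exons],
            phases=list(self.phases),
            protein_id=self.protein_id,
        )
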
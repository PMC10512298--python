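"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; GFF3 reading goes through gffutils.
Writers emit plain text only (60-column FASTA, GFF3 with populated phase,
tab-separated truth tables).
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils

from .models import GeneModel, GenomeAssembly

log = logging.getLogger("microdiv")


def read_fasta(path: str | Path, name: str | None = None) -> GenomeAssembly:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return GenomeAssembly(seqs, name=name or path.stem)


def write_fasta(assembly: GenomeAssembly, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in assembly.sequences.items()
    ]
    # Biopython's fasta writer wraps at 60 columns.
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS features, 1-based closed, phase populated."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = g.start + 1, g.end
            common = f"{g.chromosome}\tmicrodiv"
            fh.write(
                f"{common}\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{common}\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, ((xs, xe), phase) in enumerate(zip(g.exons, g.phases), 1):
                fh.write(
                    f"{common}\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
                fh.write(
                    f"{common}\tCDS\t{xs + 1}\t{xe}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna}.cds;Parent={mrna}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene/mRNA/exon/CDS) from a GFF3 file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GFF3 not found: {path}")
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parents = mrnas if mrnas else [gene]
        for parent in parents:
            cds = sorted(
                db.children(parent, featuretype="CDS"), key=lambda f: f.start
            )
            if not cds:
                continue
            exons = [(f.start - 1, f.end) for f in cds]
            phases = [
                int(f.frame) if f.frame not in (None, ".") else 0 for f in cds
            ]
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    chromosome=gene.seqid,
                    strand=gene.strand,
                    exons=exons,
                    phases=phases,
                    protein_id=parent.id,
                )
            )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


def iter_fastq(path: str | Path):
    """Tolerant FASTQ iterator: yields sequences, skips malformed records.

    Malformed records (bad header, length mismatch) are counted and logged
    rather than aborting the stream.
    """
    skipped = 0
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if (
                not header.startswith("@")
                or not plus.startswith("+")
                or len(seq) != len(qual)
                or not seq
            ):
                skipped += 1
                continue
            yield seq.upper()
    if skipped:
        log.warning("skipped %d malformed FASTQ records in %s", skipped, path)


def write_keyvalue(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in data.items():
            fh.write(f"{key}={value}\n")


def read_keyvalue(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed key-value line: {line!r}")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
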
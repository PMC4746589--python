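"""Flat-file I/O for the formats the pipeline exchanges.

FASTA goes through Biopython.  GFF3 here means the single feature type the
pipeline cares about (``gene`` lines with an ``ID`` attribute); BED is the
usual 0-based half-open interval table.  Expression matrices are TSV with a
leading comment block mapping each sample column to its phenological phase.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GeneModel:
    """A gene's location: chromosome, strand, 1-based inclusive coordinates.

    ``rank`` is the gene's ordinal position (0-based) in its chromosome's
    gene order, consistent with ascending start coordinate.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = 0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (gene features only)


def write_gff3(genes: list[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
        lines.append(
            "\t".join(
                [
                    g.chromosome,
                    "madskit",
                    "gene",
                    str(g.start),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Parse gene features and assign per-chromosome ranks by start order."""
    raw = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9 or cols[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        raw.append(
            (cols[0], int(cols[3]), int(cols[4]), cols[6], attrs.get("ID", ""))
        )
    genes: list[GeneModel] = []
    by_chrom: dict[str, list] = {}
    for rec in raw:
        by_chrom.setdefault(rec[0], []).append(rec)
    for chrom in sorted(by_chrom):
        for rank, (c, start, end, strand, gid) in enumerate(
            sorted(by_chrom[chrom], key=lambda r: r[1])
        ):
            genes.append(GeneModel(gid, c, start, end, strand, rank))
    return genes


def rank_genes(genes: list[GeneModel]) -> list[GeneModel]:
    """Recompute ranks from coordinates (per chromosome, ascending start)."""
    out = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in sorted(by_chrom):
        for rank, g in enumerate(sorted(by_chrom[chrom], key=lambda g: g.start)):
            out.append(
                GeneModel(g.gene_id, g.chromosome, g.start, g.end, g.strand, rank)
            )
    return out


# ---------------------------------------------------------------------------
# BED (0-based half-open)


def write_bed(intervals: list[tuple], path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED."""
    lines = []
    for iv in intervals:
        chrom, start, end = iv[0], iv[1], iv[2]
        name = iv[3] if len(iv) > 3 else "."
        lines.append(f"{chrom}\t{start}\t{end}\t{name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        name = cols[3] if len(cols) > 3 else "."
        out.append((cols[0], int(cols[1]), int(cols[2]), name))
    return out


# ---------------------------------------------------------------------------
# Expression TSV with a sample -> phase metadata block


def write_expression(matrix: pd.DataFrame, phases: dict[str, str], path) -> None:
    """Write a genes x samples FPKM matrix; ``phases`` maps sample -> phase."""
    buf = _io.StringIO()
    for sample in matrix.columns:
        buf.write(f"#phase\t{sample}\t{phases.get(sample, 'unknown')}\n")
    matrix.to_csv(buf, sep="\t", index_label="gene_id")
    Path(path).write_text(buf.getvalue())


def read_expression(path):
    """Read an expression TSV; returns (matrix, sample -> phase mapping)."""
    phases: dict[str, str] = {}
    body = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#phase\t"):
            _, sample, phase = line.split("\t")
            phases[sample] = phase
        else:
            body.append(line)
    matrix = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t", index_col=0)
    return matrix, phases


# ---------------------------------------------------------------------------
# Generic two-column-ish TSVs


def read_edge_list(path) -> list[tuple[str, str]]:
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        edges.append((a, b))
    return edges


def write_edge_list(edges, path) -> None:
    Path(path).write_text(
        "\n".join(f"{a}\t{b}" for a, b in edges) + ("\n" if edges else "")
    )


def read_annotations(path) -> dict[str, set[str]]:
    """Read gene -> GO term pairs into a gene -> {terms} mapping."""
    ann: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        gene, term = line.split("\t")[:2]
        ann.setdefault(gene, set()).add(term)
    return ann


def write_annotations(annotations: dict[str, set[str]], path) -> None:
    lines = [
        f"{gene}\t{term}"
        for gene in sorted(annotations)
        for term in sorted(annotations[gene])
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
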
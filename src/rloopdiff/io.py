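"""Readers and writers for the plain-text formats the pipeline consumes.

Genomes are two-column TSVs (name, length) or ``.fai``-layout files; genes are
BED6 (TSS inferred from strand); peaks are BED3+; counts and design tables are
TSVs. All BED output is 0-based half-open.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Sequence

import pandas as pd

from .genome import GenomeDef, GeneModel, Interval

__all__ = [
    "read_genome_tsv",
    "write_genome_tsv",
    "read_bed",
    "write_bed",
    "read_genes_bed",
    "write_genes_bed",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_gmt",
    "write_gmt",
]


def read_genome_tsv(path: str | os.PathLike) -> GenomeDef:
    """Read a genome from (name, length) TSV; .fai files work unchanged."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return GenomeDef(dict(zip(df[0].astype(str), df[1].astype(int))))


def write_genome_tsv(genome: GenomeDef, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path: str | os.PathLike) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append(Interval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genes_bed(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from BED6 (chrom, start, end, name, score, strand)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            genes.append(GeneModel(name, Interval(chrom, int(start), int(end)), strand))
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            s = g.span
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Feature x sample integer count table; first column is the feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_design_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Design table with columns sample, genotype, condition, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "genotype", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df


def write_design_tsv(design: pd.DataFrame, path: str | os.PathLike) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """GMT: term, description, then one gene per remaining field."""
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            terms[fields[0]] = frozenset(g for g in fields[2:] if g)
    return terms


def write_gmt(terms: dict[str, frozenset[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, "na", *sorted(genes)]) + "\n")
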
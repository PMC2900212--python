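"""Plain-text readers/writers for the pipeline's tabular interchange formats."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .intervals import GeneModel, GenomicInterval

__all__ = [
    "read_gene_models",
    "read_edge_list",
    "read_annotation",
    "read_expression",
    "read_status_table",
    "write_bed",
    "write_tsv",
]


def read_gene_models(gene_tsv: str | Path, exon_bed: str | Path) -> list[GeneModel]:
    """Gene models from a TSV (gene_id, chrom, strand, tss, gene_end) + exon BED.

    The BED name column (4th) must carry the owning gene_id.
    """
    genes = pd.read_csv(gene_tsv, sep="\t", comment="#")
    required = {"gene_id", "chrom", "strand", "tss", "gene_end"}
    if not required <= set(genes.columns):
        raise ValueError(f"gene TSV lacks columns {sorted(required - set(genes.columns))}")
    bed = pd.read_csv(
        exon_bed,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6),
    )
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    for row in bed.itertuples(index=False):
        exons_by_gene.setdefault(row.gene_id, []).append(
            GenomicInterval(str(row.chrom), int(row.start), int(row.end), str(row.strand))
        )
    out = []
    for row in genes.itertuples(index=False):
        out.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                gene_end=int(row.gene_end),
                exons=tuple(exons_by_gene.get(str(row.gene_id), ())),
            )
        )
    return out


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of undirected interaction pairs (extra columns ignored)."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: edge rows need two columns")
            edges.append((fields[0], fields[1]))
    return edges


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """gene_id -> set of category ids from a (gene_id, category_id[, name]) TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene_id", "category_id"} <= set(df.columns):
        raise ValueError("annotation TSV needs gene_id and category_id columns")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_id, set()).add(row.category_id)
    return out


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "tissue", "value", "call"} <= set(df.columns):
        raise ValueError("expression TSV needs gene_id, tissue, value, call columns")
    return df


def read_status_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in (
        "promoter_analyzed",
        "promoter_positive",
        "coding_analyzed",
        "coding_positive",
        "in_network",
    ):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_bed(intervals: list[GenomicInterval], path: str | Path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
    index: bool = False,
) -> None:
    """Write a TSV with header comments recording version, seed and config hash."""
    lines = [f"# promselnet {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        digest = hashlib.sha1(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        lines.append(f"# config_sha1={digest}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=index)
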
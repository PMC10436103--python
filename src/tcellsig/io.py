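"""Readers and writers for the plain-text formats the pipeline exchanges.

BED3+ peak calls, TSV matrices keyed by "chrom:start-end", 6-column gene
model tables, MatrixMarket single-cell counts with gene/cell sidecars,
2-column signature files and JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import io as spio
from scipy import sparse

from .atac import GeneModel, GenomicInterval, PeakCallSet, parse_interval_key
from .singlecell import GeneSignature


def read_bed(path: str | Path, sample_id: str = "", subtype: str = "") -> PeakCallSet:
    """Read BED3+ peak calls into a sorted PeakCallSet."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            ivs.append(GenomicInterval(chrom, int(start), int(end)).validate())
    sample = sample_id or Path(path).stem
    return PeakCallSet(sample, subtype or sample, tuple(sorted(ivs)))


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Feature x sample TSV; row keys may be interval keys or gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def catalog_from_index(index: Iterable[str]) -> list[GenomicInterval]:
    return [parse_interval_key(k) for k in index]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """6-column TSV: gene_id, chrom, strand, tss, exon_starts, exon_ends.

    Exon columns are comma-separated coordinate lists (may be empty).
    """
    genes = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "chrom", "strand", "tss", "exon_starts", "exon_ends"]
    if list(df.columns[: len(required)]) != required:
        raise ValueError(f"gene model table must have columns {required}")
    for _, row in df.iterrows():
        starts = [int(x) for x in str(row.exon_starts).split(",") if x not in ("", "nan")]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x not in ("", "nan")]
        exons = tuple(
            GenomicInterval(row.chrom, s, e).validate() for s, e in zip(starts, ends)
        )
        genes.append(GeneModel(row.gene_id, row.chrom, row.strand, int(row.tss), exons))
    return genes


def read_sc_counts(mtx: str | Path, genes: str | Path, cells: str | Path) -> pd.DataFrame:
    """MatrixMarket counts with one-column gene and cell TSVs (genes x cells)."""
    mat = spio.mmread(mtx)
    gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].tolist()
    cell_ids = pd.read_csv(cells, sep="\t", header=None)[0].tolist()
    return pd.DataFrame(sparse.coo_matrix(mat).toarray(), index=gene_ids, columns=cell_ids)


def write_sc_counts(counts: pd.DataFrame, mtx: str | Path,
                    genes: str | Path, cells: str | Path) -> None:
    spio.mmwrite(str(mtx), sparse.csr_matrix(counts.values))
    pd.Series(counts.index).to_csv(genes, sep="\t", header=False, index=False)
    pd.Series(counts.columns).to_csv(cells, sep="\t", header=False, index=False)


def read_signatures(path: str | Path) -> dict[str, GeneSignature]:
    """2-column TSV (signature, gene) -> named GeneSignatures."""
    df = pd.read_csv(path, sep="\t", header=None, names=["signature", "gene"])
    return {
        name: GeneSignature(name, tuple(group["gene"]))
        for name, group in df.groupby("signature", sort=False)
    }


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
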
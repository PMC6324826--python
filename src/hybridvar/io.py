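"""TSV readers and writers for the pipeline's plain-text interchange formats.

Every file written by the pipeline is tab-separated with optional leading
``#`` provenance lines (tool version, config hash, seed).  All readers skip
such lines, so files round-trip regardless of provenance.

Formats
-------
expression matrix   genes as rows, samples as columns, integer or float.
allele count table  genes as rows; per sample a ``<sample>__P1`` and a
                    ``<sample>__P2`` column with parent-1 / parent-2 read
                    counts at polymorphic sites.
genotype matrix     genes x samples with values ``het`` / ``hom`` /
                    ``missing`` (``hom`` = homozygous recurrent-parent).
annotation          BED-like: chrom, start (0-based), end (half-open),
                    gene id.  Coordinates encode map position at
                    ``BP_PER_MORGAN`` bp per Morgan.
metadata            columns ``sample``, ``population``, ``batch``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from hybridvar._constants import BP_PER_MORGAN, GENOTYPE_CODES, GENOTYPE_LABELS


def _provenance_lines(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# {parts}\n"


def write_tsv(df: pd.DataFrame, path: str | Path, *, index_label: str = "gene_id",
              provenance: Mapping[str, object] | None = None) -> None:
    """Write a DataFrame as TSV with an optional ``#`` provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_tsv(path: str | Path, *, index_col: int | None = 0) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping ``#`` lines."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_matrix(df: pd.DataFrame, path: str | Path,
                 provenance: Mapping[str, object] | None = None) -> None:
    write_tsv(df, path, index_label="gene_id", provenance=provenance)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    df.index = df.index.astype(str)
    return df


def write_allele_counts(p1: pd.DataFrame, p2: pd.DataFrame, path: str | Path,
                        provenance: Mapping[str, object] | None = None) -> None:
    """Write paired parent-1/parent-2 allele depths as ``<sample>__P1/__P2``."""
    if not p1.index.equals(p2.index) or not p1.columns.equals(p2.columns):
        raise ValueError("parent-1 and parent-2 tables must share genes and samples")
    cols = {}
    for s in p1.columns:
        cols[f"{s}__P1"] = p1[s]
        cols[f"{s}__P2"] = p2[s]
    write_tsv(pd.DataFrame(cols, index=p1.index), path, provenance=provenance)


def read_allele_counts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read paired allele-depth columns back into (p1, p2) matrices."""
    df = read_tsv(path)
    df.index = df.index.astype(str)
    p1_cols = [c for c in df.columns if c.endswith("__P1")]
    p2_cols = [c for c in df.columns if c.endswith("__P2")]
    samples = [c[:-4] for c in p1_cols]
    if samples != [c[:-4] for c in p2_cols]:
        raise ValueError("mismatched __P1/__P2 column pairs in allele table")
    p1 = df[p1_cols].copy()
    p1.columns = samples
    p2 = df[p2_cols].copy()
    p2.columns = samples
    return p1, p2


def write_genotypes(geno: pd.DataFrame, path: str | Path,
                    provenance: Mapping[str, object] | None = None) -> None:
    """Write an integer-coded genotype matrix as het/hom/missing labels."""
    labelled = geno.map(lambda v: GENOTYPE_LABELS[int(v)])
    write_tsv(labelled, path, provenance=provenance)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    df.index = df.index.astype(str)
    bad = set(df.values.ravel()) - set(GENOTYPE_CODES)
    if bad:
        raise ValueError(f"unknown genotype labels: {sorted(bad)}")
    return df.map(lambda v: GENOTYPE_CODES[v]).astype("int8")


def write_annotation(annotation: pd.DataFrame, path: str | Path,
                     provenance: Mapping[str, object] | None = None) -> None:
    """Write gene annotation as BED-like TSV (chrom, start, end, gene_id).

    ``annotation`` is indexed by gene id with columns ``chrom``, ``start``,
    ``end`` (``pos_morgans``, if present, is implied by start).
    """
    bed = pd.DataFrame({
        "chrom": annotation["chrom"],
        "start": annotation["start"].astype(int),
        "end": annotation["end"].astype(int),
        "gene_id": annotation.index,
    })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        bed.to_csv(fh, sep="\t", index=False, header=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read BED-like annotation; restores map position in Morgans."""
    bed = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=["chrom", "start", "end", "gene_id"])
    if bed["gene_id"].duplicated().any():
        dups = bed.loc[bed["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicated gene ids in annotation: {dups[:5]}")
    ann = bed.set_index("gene_id")
    ann.index = ann.index.astype(str)
    ann["pos_morgans"] = ann["start"] / BP_PER_MORGAN
    return ann


def write_metadata(meta: pd.DataFrame, path: str | Path,
                   provenance: Mapping[str, object] | None = None) -> None:
    write_tsv(meta, path, index_label="sample", provenance=provenance)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = read_tsv(path)
    meta.index = meta.index.astype(str)
    required = {"population", "batch"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks required columns: {sorted(missing)}")
    return meta
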
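"""Allelic expression ratios and ancestry genotype calling.

In a backcross to parent 2 (the recurrent parent), every locus is either
heterozygous (one allele from each species) or homozygous for the
recurrent-parent allele.  Reads covering interspecific polymorphic sites
can be assigned to a parental allele, so the parent-1 read fraction at a
locus identifies the genotype: near 0 for homozygous-recurrent, near the
gene's allelic ratio (typically ~0.5) for heterozygotes.

Calls use three configurable thresholds: a minimum informative depth, a
minimum minor-allele fraction for HET, and a maximum parent-1 fraction
for homozygous-recurrent.  Loci falling between the HOM and HET bands are
ambiguous and reported MISSING rather than forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybridvar._constants import (
    DEFAULT_HOM_MAX_NONRECURRENT_FRACTION,
    DEFAULT_MIN_DEPTH,
    DEFAULT_MIN_MINOR_FRACTION,
    HET,
    HOM_RECURRENT,
    MISSING,
)

__all__ = [
    "GenotypeParams",
    "allelic_ratio",
    "call_genotype",
    "genotype_population",
    "complete_genes",
    "class_balanced_genes",
]


@dataclass(frozen=True)
class GenotypeParams:
    """Thresholds for genotype calling from allele depths."""

    min_depth: int = DEFAULT_MIN_DEPTH
    min_minor_fraction: float = DEFAULT_MIN_MINOR_FRACTION
    hom_max_nonrecurrent_fraction: float = DEFAULT_HOM_MAX_NONRECURRENT_FRACTION

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.min_minor_fraction < 0.5:
            raise ValueError("min_minor_fraction must be in (0, 0.5)")
        if not 0 <= self.hom_max_nonrecurrent_fraction < self.min_minor_fraction:
            raise ValueError(
                "hom_max_nonrecurrent_fraction must be in [0, min_minor_fraction)")


def allelic_ratio(p1_reads, p2_reads, pseudocount: float = 1.0):
    """Parent-1 read fraction and log2 allelic ratio.

    ``p1_fraction = (p1 + c) / (p1 + p2 + 2c)`` and
    ``log2_ratio = log2((p1 + c) / (p2 + c))`` with pseudocount ``c``.
    Accepts scalars or arrays.  With ``c = 0`` a locus with zero depth has
    no defined ratio.
    """
    p1 = np.asarray(p1_reads, dtype=float)
    p2 = np.asarray(p2_reads, dtype=float)
    if np.any(p1 < 0) or np.any(p2 < 0):
        raise ValueError("allele read counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and np.any((p1 == 0) & (p2 == 0)):
        raise ValueError("ratio undefined for zero total depth with pseudocount 0")
    c = float(pseudocount)
    frac = (p1 + c) / (p1 + p2 + 2 * c)
    with np.errstate(divide="ignore"):
        log2_ratio = np.log2(p1 + c) - np.log2(p2 + c)
    if np.ndim(p1_reads) == 0 and np.ndim(p2_reads) == 0:
        return float(frac), float(log2_ratio)
    return frac, log2_ratio


def call_genotype(p1_reads, p2_reads, params: GenotypeParams | None = None):
    """Call HET / HOM_RECURRENT / MISSING from parent-1/parent-2 depths.

    Decision rule (depth = p1 + p2):

    - depth below ``min_depth`` -> MISSING;
    - minor-allele fraction >= ``min_minor_fraction`` -> HET;
    - parent-1 fraction <= ``hom_max_nonrecurrent_fraction`` ->
      HOM_RECURRENT (a trickle of parent-1 reads is tolerated as noise);
    - anything in between is ambiguous -> MISSING.

    Calls depend only on the read *fractions* once depth passes the
    threshold, so scaling both counts by the same factor never changes a
    call.
    """
    params = params or GenotypeParams()
    p1 = np.asarray(p1_reads, dtype=float)
    p2 = np.asarray(p2_reads, dtype=float)
    if np.any(p1 < 0) or np.any(p2 < 0):
        raise ValueError("allele read counts must be non-negative")
    depth = p1 + p2
    with np.errstate(invalid="ignore", divide="ignore"):
        p1_frac = np.where(depth > 0, p1 / np.maximum(depth, 1), 0.0)
    minor = np.minimum(p1_frac, 1.0 - p1_frac)

    call = np.full(np.shape(depth), MISSING, dtype=np.int8)
    ok = depth >= params.min_depth
    call[ok & (minor >= params.min_minor_fraction)] = HET
    call[ok & (p1_frac <= params.hom_max_nonrecurrent_fraction)] = HOM_RECURRENT
    if np.ndim(p1_reads) == 0 and np.ndim(p2_reads) == 0:
        return int(call)
    return call


def genotype_population(
    p1: pd.DataFrame,
    p2: pd.DataFrame,
    params: GenotypeParams | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genotype every gene in every sample of an allele-count table.

    Returns ``(genotypes, complete)`` where genotypes is a genes x samples
    integer matrix and ``complete`` flags genes with no MISSING call —
    the genes usable as association markers.
    """
    if p1.empty:
        raise ValueError("empty allele-count table")
    if not p1.index.equals(p2.index) or not p1.columns.equals(p2.columns):
        raise ValueError("parent-1 and parent-2 tables must be aligned")
    calls = call_genotype(p1.to_numpy(), p2.to_numpy(), params)
    geno = pd.DataFrame(calls, index=p1.index, columns=p1.columns)
    complete = (geno != MISSING).all(axis=1)
    complete.name = "complete"
    return geno, complete


def complete_genes(geno: pd.DataFrame) -> pd.Index:
    """Genes genotyped (non-MISSING) in every individual."""
    return geno.index[(geno != MISSING).all(axis=1)]


def class_balanced_genes(geno: pd.DataFrame, min_per_class: int = 3) -> pd.Index:
    """Genes with at least ``min_per_class`` HET and HOM individuals.

    These are the genes whose genotype split supports a between-class
    comparison (differential expression, association testing).
    """
    n_het = (geno == HET).sum(axis=1)
    n_hom = (geno == HOM_RECURRENT).sum(axis=1)
    return geno.index[(n_het >= min_per_class) & (n_hom >= min_per_class)]
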
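"""Library-size normalization and batch-effect removal.

Counts are scaled to counts-per-million (CPM) against each sample's
library size (column total), log2-transformed with a pseudocount, and
batch effects are removed by per-gene least squares: batch-mean
deviations are estimated (optionally orthogonal to population labels, so
that population differences are not erased when populations span batches
unevenly) and subtracted, preserving each gene's grand mean.

Downstream CV analysis works on the linear scale recovered by
back-transforming the corrected log values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hybridvar._constants import DEFAULT_PSEUDOCOUNT

__all__ = [
    "NormalizedMatrix",
    "library_normalize",
    "log_transform",
    "remove_batch",
    "back_transform",
    "normalize_pipeline",
]


@dataclass
class NormalizedMatrix:
    """Log-scale normalized expression plus the transform that made it."""

    values: pd.DataFrame               # genes x samples, log2(CPM + c), batch-corrected
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    scale: str = "log2_cpm"
    warnings: list[str] = field(default_factory=list)

    def linear(self) -> pd.DataFrame:
        """Back-transformed linear-scale expression (CPM), floored at 0."""
        return back_transform(self.values, self.pseudocount)


def library_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to counts per million of its library size."""
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts / lib * 1e6


def log_transform(cpm: pd.DataFrame,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    return np.log2(cpm + pseudocount)


def back_transform(log_values: pd.DataFrame,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    return (2.0 ** log_values - pseudocount).clip(lower=0)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    cats = pd.unique(labels)
    return (labels[:, None] == cats[None, :]).astype(float)


def remove_batch(
    log_matrix: pd.DataFrame,
    batch: pd.Series,
    population: pd.Series | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> NormalizedMatrix:
    """Subtract per-gene batch-mean deviations from log expression.

    For each gene the batch component is estimated by least squares and
    subtracted; when ``population`` is given the batch term is fitted
    jointly with population indicators, so only batch variation that is
    not explained by population membership is removed.  Each gene is then
    recentred so its grand mean is untouched, which also makes the
    operation idempotent.  A single batch returns the input unchanged.
    """
    batch = batch.reindex(log_matrix.columns)
    if batch.isna().any():
        missing = list(log_matrix.columns[batch.isna()])
        raise ValueError(f"samples without a batch label: {missing}")

    warnings: list[str] = []
    counts = batch.value_counts()
    for b, n in counts.items():
        if n == 1:
            warnings.append(f"batch {b!r} has a single sample; "
                            "its deviation is absorbed entirely")

    if batch.nunique() <= 1:
        return NormalizedMatrix(log_matrix.copy(), pseudocount, warnings=warnings)

    Y = log_matrix.to_numpy().T                     # samples x genes
    B = _one_hot(batch.to_numpy())[:, 1:]           # drop reference batch
    if population is not None:
        population = population.reindex(log_matrix.columns)
        C = _one_hot(population.to_numpy())
    else:
        C = np.ones((len(batch), 1))
    # batch directions orthogonal to the protected covariates: batch
    # variation that population membership already explains is kept
    coef, *_ = np.linalg.lstsq(C, B, rcond=None)
    B_orth = B - C @ coef
    X = np.column_stack([C, B_orth])

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    corrected = Y - B_orth @ beta[C.shape[1]:]
    corrected += Y.mean(axis=0, keepdims=True) - corrected.mean(axis=0, keepdims=True)

    out = pd.DataFrame(corrected.T, index=log_matrix.index,
                       columns=log_matrix.columns)
    return NormalizedMatrix(out, pseudocount, warnings=warnings)


def normalize_pipeline(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    protect_population: bool = True,
) -> NormalizedMatrix:
    """CPM -> log2(+pseudocount) -> batch removal, in one call.

    ``metadata`` must carry ``batch`` (and ``population`` when
    ``protect_population``) indexed by sample.
    """
    missing = [s for s in counts.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    logm = log_transform(library_normalize(counts), pseudocount)
    pop = metadata["population"] if protect_population else None
    return remove_batch(logm, metadata["batch"], population=pop,
                        pseudocount=pseudocount)
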
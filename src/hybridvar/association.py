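"""Marker-genotype x gene-expression association with cis/trans labels.

Every gene genotyped in all backcross individuals is a candidate
*marker*.  For each marker whose HET/HOM split has at least a minimum
number of individuals per class, expression of every other gene is
tested by one-way ANOVA across the marker's genotype classes;
Benjamini-Hochberg FDR is applied within each marker across its targets
(a global-BH option is available for sensitivity analysis).  A
significant marker is a *cis*-variant for a target on the same
chromosome and a *trans*-variant otherwise.

The scan is vectorized: markers sharing a genotype pattern are computed
once, and the two-class ANOVA is evaluated for all targets of a pattern
simultaneously (for two classes F equals the square of the pooled
-variance t statistic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hybridvar._constants import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_CLASS_SIZE,
    HET,
    HOM_RECURRENT,
    MISSING,
)
from hybridvar.variability import compute_cv

__all__ = [
    "anova_association",
    "classify_mode",
    "scan",
    "summarize_modes",
    "de_by_genotype",
    "stratified_cv_by_marker",
]

_TINY_P = np.nextafter(0, 1)


def anova_association(genotype, expression,
                      min_class_size: int = DEFAULT_MIN_CLASS_SIZE):
    """One-way ANOVA of expression across genotype classes.

    MISSING genotypes are dropped pairwise.  Returns ``(F, p)``; with a
    single class (or any class below ``min_class_size``) the pair is
    untestable and ``(nan, nan)`` is returned.  Zero within-class
    variance with distinct class means yields an infinite F and the
    smallest representable p.
    """
    g = np.asarray(genotype)
    y = np.asarray(expression, dtype=float)
    keep = g != MISSING
    g, y = g[keep], y[keep]
    classes = np.unique(g)
    if len(classes) < 2 or any((g == c).sum() < min_class_size for c in classes):
        return float("nan"), float("nan")
    groups = [y[g == c] for c in classes]
    grand = y.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups)
    df_b = len(classes) - 1
    df_w = len(y) - len(classes)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), float(_TINY_P)
    F = (ssb / df_b) / (ssw / df_w)
    return float(F), float(stats.f.sf(F, df_b, df_w))


def classify_mode(marker: str, target: str, annotation: pd.DataFrame) -> str:
    """``cis`` iff marker and target share a chromosome, else ``trans``."""
    for g in (marker, target):
        if g not in annotation.index:
            raise KeyError(f"gene {g!r} missing from annotation")
    same = str(annotation.at[marker, "chrom"]) == str(annotation.at[target, "chrom"])
    return "cis" if same else "trans"


def _two_class_anova_matrix(E: np.ndarray, het_mask: np.ndarray):
    """Vectorized two-class one-way ANOVA of every row of E.

    ``E`` is targets x samples, ``het_mask`` a boolean sample split.
    Returns (F, p) arrays; rows with zero within-class variance get
    inf/tiny-p (or 0/1 when the means also coincide).
    """
    F, p, m1, m0 = _anova_patterns(E, het_mask[None, :])
    return F[:, 0], p[:, 0], m1[:, 0], m0[:, 0]


def _anova_patterns(E: np.ndarray, H: np.ndarray):
    """Two-class ANOVA of every E row against every genotype pattern.

    ``E``: targets x samples; ``H``: patterns x samples boolean (True =
    HET).  Returns targets x patterns matrices (F, p, mean_het,
    mean_hom).  Zero within-class variance yields inf F and the tiniest
    positive p (0 and 1 when the class means also coincide).
    """
    Hf = H.astype(float).T                     # samples x patterns
    n1 = Hf.sum(axis=0)                        # per pattern
    n0 = H.shape[1] - n1
    s1 = E @ Hf                                # targets x patterns
    s0 = E.sum(axis=1)[:, None] - s1
    q1 = (E ** 2) @ Hf
    q0 = (E ** 2).sum(axis=1)[:, None] - q1
    m1 = s1 / n1
    m0 = s0 / n0
    grand = (s1 + s0) / (n1 + n0)
    ssb = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    ssw = np.maximum((q1 - n1 * m1 ** 2) + (q0 - n0 * m0 ** 2), 0.0)
    df_w = H.shape[1] - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssb / (ssw / df_w)
    p = stats.f.sf(F, 1, df_w)
    tol = 1e-12 * np.maximum(q1 + q0, 1.0)     # ssw==0 up to float cancellation
    degenerate = ssw <= tol
    if degenerate.any():
        equal = degenerate & (ssb <= tol)
        F[degenerate] = np.inf
        p[degenerate] = _TINY_P
        F[equal] = 0.0
        p[equal] = 1.0
    return F, p, m1, m0


def _bh_rows(p: np.ndarray) -> np.ndarray:
    """Row-wise Benjamini-Hochberg adjustment; NaN entries are untested."""
    q = np.full_like(p, np.nan)
    m = np.sum(~np.isnan(p), axis=1)
    order = np.argsort(p, axis=1)              # NaNs sort last
    rows = np.arange(p.shape[0])[:, None]
    p_sorted = np.take_along_axis(p, order, axis=1)
    ranks = np.arange(1, p.shape[1] + 1)[None, :]
    with np.errstate(invalid="ignore"):
        raw = p_sorted * m[:, None] / ranks
    raw = np.where(np.isnan(p_sorted), np.inf, raw)
    adj = np.minimum.accumulate(raw[:, ::-1], axis=1)[:, ::-1]
    adj = np.minimum(adj, 1.0)
    q[rows, order] = np.where(np.isnan(p_sorted), np.nan, adj)
    return q


def scan(
    genotypes: pd.DataFrame,
    norm_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
    alpha: float = DEFAULT_ALPHA,
    fdr_scope: str = "marker",
    keep: str = "all",
) -> pd.DataFrame:
    """Genome-wide marker x target association scan.

    Markers are genes with a complete (no-MISSING) genotype vector and at
    least ``min_class_size`` individuals in each genotype class.  Targets
    are all expressed genes present in both the expression matrix and the
    annotation, excluding the marker itself (a marker's association with
    its own expression is definitionally cis and is not emitted).
    Returns one record per tested pair with columns marker, target, F, p,
    q (BH within marker, or globally when ``fdr_scope='global'``), mode,
    mean_het, mean_hom and significant (q < alpha).

    ``keep='significant'`` returns only the significant records (every
    pair is still tested and enters its marker's FDR correction); the
    full per-marker test counts are then available in
    ``records.attrs['n_tested_per_marker']``.
    """
    if fdr_scope not in ("marker", "global"):
        raise ValueError("fdr_scope must be 'marker' or 'global'")
    if keep not in ("all", "significant"):
        raise ValueError("keep must be 'all' or 'significant'")
    skipped: list[str] = []

    unannotated = [g for g in norm_matrix.index if g not in annotation.index]
    if unannotated:
        skipped.extend(f"target {g}: no annotation" for g in unannotated)
    targets = norm_matrix.index[norm_matrix.index.isin(annotation.index)]
    E_all = norm_matrix.loc[targets].to_numpy()
    t_chrom = annotation.loc[targets, "chrom"].astype(str).to_numpy()
    t_pos = {g: i for i, g in enumerate(targets)}

    geno = genotypes.loc[:, norm_matrix.columns]
    complete = (geno != MISSING).all(axis=1)
    n_het = (geno == HET).sum(axis=1)
    n_hom = (geno == HOM_RECURRENT).sum(axis=1)
    usable = complete & (n_het >= min_class_size) & (n_hom >= min_class_size)
    for g in geno.index[~usable & complete]:
        skipped.append(f"marker {g}: genotype split below min class size")
    markers = geno.index[usable & geno.index.isin(annotation.index)]

    if len(markers) == 0 or len(targets) == 0:
        records = pd.DataFrame(columns=["marker", "target", "F", "p", "q",
                                        "mode", "mean_het", "mean_hom",
                                        "significant"])
        records.attrs["skipped"] = skipped
        return records

    # markers in tight linkage share genotype patterns; compute each
    # pattern's ANOVA once and expand per marker by row indexing
    G = (geno.loc[markers].to_numpy() == HET)
    patterns, pattern_of_marker = np.unique(G, axis=0, return_inverse=True)
    Ft, pt, m1t, m0t = _anova_patterns(E_all, patterns)   # targets x patterns

    n_m, n_t = len(markers), len(targets)
    P = pt.T.astype(np.float32)[pattern_of_marker]        # markers x targets

    # mask self-pairs out of each marker's tests (NaN = not tested)
    self_rows = [(i, t_pos[m]) for i, m in enumerate(markers) if m in t_pos]
    if self_rows:
        ri, ci = zip(*self_rows)
        P[ri, ci] = np.nan
    if fdr_scope == "marker":
        Q = _bh_rows(P)
    else:
        flat = P.ravel()
        tested = ~np.isnan(flat)
        qf = np.full_like(flat, np.nan)
        qf[tested] = multipletests(flat[tested].astype(float),
                                   method="fdr_bh")[1]
        Q = qf.reshape(P.shape)

    tested_mask = ~np.isnan(P)
    if keep == "significant":
        sel = (Q < alpha) & tested_mask
    else:
        sel = tested_mask
    mi, ti = np.nonzero(sel)

    m_chrom = annotation.loc[markers, "chrom"].astype(str).to_numpy()
    pat = pattern_of_marker[mi]
    records = pd.DataFrame({
        "marker": pd.Categorical.from_codes(mi, categories=markers),
        "target": pd.Categorical.from_codes(ti, categories=targets),
        "F": Ft[ti, pat],
        "p": P[mi, ti].astype(float),
        "q": Q[mi, ti].astype(float),
        "mode": pd.Categorical.from_codes(
            np.where(m_chrom[mi] == t_chrom[ti], 0, 1),
            categories=["cis", "trans"]),
        "mean_het": m1t[ti, pat],
        "mean_hom": m0t[ti, pat],
    })
    records["significant"] = records["q"] < alpha
    records.attrs["skipped"] = skipped
    records.attrs["n_tested"] = int(tested_mask.sum())
    records.attrs["n_tested_per_marker"] = pd.Series(
        tested_mask.sum(axis=1), index=markers)
    return records


def summarize_modes(records: pd.DataFrame) -> dict[str, int]:
    """Aggregate significant pairs into per-target regulatory-mode counts.

    Returns counts of targets with at least one significant cis marker
    only, trans only, or both, plus the raw significant-pair and unique
    marker/target tallies.
    """
    sig = records[records["significant"]] if len(records) else records
    cis_targets = set(sig.loc[sig["mode"] == "cis", "target"]) if len(sig) else set()
    trans_targets = set(sig.loc[sig["mode"] == "trans", "target"]) if len(sig) else set()
    both = cis_targets & trans_targets
    return {
        "cis_only": len(cis_targets - both),
        "trans_only": len(trans_targets - both),
        "both": len(both),
        "targets": len(cis_targets | trans_targets),
        "markers": int(sig["marker"].nunique()) if len(sig) else 0,
        "significant_pairs": int(len(sig)),
    }


def de_by_genotype(
    norm_matrix: pd.DataFrame,
    genotypes: pd.DataFrame,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Differential expression between a gene's own genotype classes.

    For each gene with at least ``min_class_size`` HET and HOM
    individuals, Welch's t-test compares its expression between the two
    classes; p-values are BH-adjusted across all tested genes.
    """
    rows = []
    shared = norm_matrix.index.intersection(genotypes.index)
    for g in shared:
        geno = genotypes.loc[g, norm_matrix.columns]
        het_s = geno.index[geno == HET]
        hom_s = geno.index[geno == HOM_RECURRENT]
        if len(het_s) < min_class_size or len(hom_s) < min_class_size:
            continue
        a = norm_matrix.loc[g, het_s].to_numpy(dtype=float)
        b = norm_matrix.loc[g, hom_s].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(b) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, float(_TINY_P))
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((g, float(t), float(p), a.mean() - b.mean(),
                     len(het_s), len(hom_s)))
    out = pd.DataFrame(rows, columns=["gene_id", "t", "p", "mean_diff",
                                      "n_het", "n_hom"]).set_index("gene_id")
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["differential"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["differential"] = pd.Series(dtype=bool)
    return out


def stratified_cv_by_marker(
    linear_matrix: pd.DataFrame,
    records: pd.DataFrame,
    genotypes: pd.DataFrame,
    min_stratum: int = 2,
) -> pd.DataFrame:
    """Target CVs within each associated marker's genotype strata.

    For every significant (marker, target) pair: the target's CV within
    the marker-HET individuals, within the marker-HOM individuals, and
    pooled.  The pair's cis/trans mode is carried along so aggregate
    distributions can be formed for cis- and trans-regulated targets.
    """
    sig = records[records["significant"]]
    rows = []
    for rec in sig.itertuples(index=False):
        m, t = rec.marker, rec.target
        if m not in genotypes.index or t not in linear_matrix.index:
            continue
        geno = genotypes.loc[m, linear_matrix.columns]
        het_s = geno.index[geno == HET]
        hom_s = geno.index[geno == HOM_RECURRENT]
        if len(het_s) < min_stratum or len(hom_s) < min_stratum:
            continue
        expr = linear_matrix.loc[t]
        called = het_s.union(hom_s)
        if expr[called].mean() <= 0:
            continue
        _, _, cv_het = compute_cv(expr[het_s])
        _, _, cv_hom = compute_cv(expr[hom_s])
        _, _, cv_pooled = compute_cv(expr[called])
        rows.append((m, t, rec.mode, cv_het, cv_hom, cv_pooled))
    return pd.DataFrame(rows, columns=["marker", "target", "mode",
                                       "cv_het", "cv_hom", "cv_pooled"])
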
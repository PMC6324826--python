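"""Evaluation of analysis output against simulator ground truth.

With only 14 backcross individuals, ancestry markers come in large
linked blocks: a marker adjacent to a true regulator carries (nearly)
the same genotype vector and is genuinely associated with the
regulator's target.  Counting such pairs as false positives would charge
the scan for linkage itself, so evaluation is *locus-aware*: a
significant (marker, target) record counts as a true discovery when the
marker is the true regulator, lies within a map window of one on the
same chromosome, or carries a genotype pattern within a small Hamming
distance of one (tight statistical linkage, including the complementary
pattern, since association is sign-free).

Because Benjamini-Hochberg is applied within each marker, the quantity
it controls is the per-marker false-discovery proportion; that is what
:func:`evaluate_scan` summarises (median and mean across markers with
discoveries), alongside the pooled pair-level proportion for reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hybridvar._constants import MISSING
from hybridvar.simulate import SimTruth

__all__ = ["genotype_accuracy", "evaluate_scan"]


def genotype_accuracy(called: pd.DataFrame, truth: SimTruth) -> dict[str, float]:
    """Agreement of genotype calls with simulated ancestry.

    Accuracy is computed over non-MISSING calls; the call rate is
    reported separately (a conservative caller trades call rate for
    accuracy, as in real allele-depth genotyping where not every gene is
    genotypeable in every individual).
    """
    truth_g = truth.genotypes.loc[called.index, called.columns]
    called_v = called.to_numpy()
    mask = called_v != MISSING
    agree = (called_v[mask] == truth_g.to_numpy()[mask])
    return {
        "call_rate": float(mask.mean()),
        "accuracy": float(agree.mean()) if mask.any() else float("nan"),
    }


def _linked(marker: str, regulator: str, truth: SimTruth,
            map_window: float, max_pattern_distance: int) -> bool:
    if marker == regulator:
        return True
    ann = truth.annotation
    if (ann.at[marker, "chrom"] == ann.at[regulator, "chrom"] and
            abs(ann.at[marker, "pos_morgans"] - ann.at[regulator, "pos_morgans"])
            <= map_window):
        return True
    gm = truth.genotypes.loc[marker].to_numpy()
    gr = truth.genotypes.loc[regulator].to_numpy()
    agree = int((gm == gr).sum())
    return min(agree, gm.size - agree) <= max_pattern_distance


def evaluate_scan(
    records: pd.DataFrame,
    truth: SimTruth,
    map_window: float = 0.25,
    max_pattern_distance: int = 1,
) -> dict[str, float]:
    """Score significant scan records against the true architecture.

    Returns

    - ``recovery``: fraction of true (regulator, target) pairs whose
      exact pair is significant;
    - ``fdp_per_marker_median`` / ``fdp_per_marker_mean``: per-marker
      false-discovery proportions across markers with >= 1 discovery
      (the quantity per-marker BH controls);
    - ``fdp_pooled_pairs``: false pairs / all significant pairs, pooled
      (inflated by linked-marker multiplicity; reported for reference);
    - ``mode_accuracy``: fraction of recovered true pairs whose cis/trans
      label matches the architecture;
    - ``n_significant_pairs``.
    """
    sig = records[records["significant"]] if "significant" in records else records
    true_pairs = truth.architecture.true_pairs()
    mode_of = {(r, t): m for t, regs in truth.architecture.regulators.items()
               for r, m, e in regs if e != 0}
    regs_of: dict[str, list[str]] = {}
    for r, t in true_pairs:
        regs_of.setdefault(t, []).append(r)

    markers = sig["marker"].astype(str).to_numpy()
    targets = sig["target"].astype(str).to_numpy()
    is_true = np.zeros(len(sig), dtype=bool)
    cache: dict[tuple[str, str], bool] = {}
    for i, (m, t) in enumerate(zip(markers, targets)):
        for r in regs_of.get(t, ()):  # unregulated targets are always false
            k = (m, r)
            if k not in cache:
                cache[k] = _linked(m, r, truth, map_window, max_pattern_distance)
            if cache[k]:
                is_true[i] = True
                break

    sigset = set(zip(markers, targets))
    recovered = true_pairs & sigset
    recovery = len(recovered) / len(true_pairs) if true_pairs else float("nan")

    if len(sig):
        per_marker = pd.Series(~is_true).groupby(pd.Series(markers)).mean()
        fdp_median = float(per_marker.median())
        fdp_mean = float(per_marker.mean())
        fdp_pooled = float((~is_true).mean())
    else:
        fdp_median = fdp_mean = fdp_pooled = 0.0

    if recovered:
        rec_mode = {(m, t): mo for m, t, mo in
                    zip(markers, targets, sig["mode"].astype(str))}
        mode_acc = float(np.mean([rec_mode[p] == mode_of[p] for p in recovered]))
    else:
        mode_acc = float("nan")

    return {
        "recovery": recovery,
        "fdp_per_marker_median": fdp_median,
        "fdp_per_marker_mean": fdp_mean,
        "fdp_pooled_pairs": fdp_pooled,
        "mode_accuracy": mode_acc,
        "n_significant_pairs": int(len(sig)),
    }
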
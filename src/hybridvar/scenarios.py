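"""Canonical synthetic study scenarios.

These constructors freeze the study conditions the package is validated
against; tests and the acceptance analysis build on them rather than
re-specifying parameters.

``variability_study``
    The population panel of a two-species hybridization study: a large
    inbred parental colony (n = 20, 6 sequencing batches), a second
    inbred parental line (n = 6, 3 batches), F1 hybrids (n = 6), first
    -generation backcrosses (n = 14) and fifth-generation backcrosses
    (n = 13), all measured on one 2,000-gene panel over 24 chromosomes.
    Most genes respond to ancestry genotype — 65% carry a cis regulator
    and 10% a trans regulator (3% both), with log2 effects in [0.5, 2] —
    so genotype heterogeneity in backcrosses widens expression
    variability while the genotype-homogeneous inbred and F1 populations
    stay tight.  ``f1_stabilized`` applies the dominant "homeostasis"
    dispersion reduction (factor 0.1) to every gene in F1s.

``association_study``
    A single 14-individual BC1 population with a sparse architecture
    (20 cis-regulated, 10 trans-regulated targets, log2 effects in
    [1, 2]) for regulator-recovery experiments.

``null_study``
    The same BC1 design with no regulators at all: every association or
    differential-variability discovery on it is a false positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hybridvar import simulate

__all__ = ["variability_study", "association_study", "null_study",
           "STUDY_N", "PANEL"]

# population sizes and batch structure of the emulated study
STUDY_N = {"inbred_p1": 20, "inbred_p2": 6, "f1": 6, "bc1": 14, "bc5": 13}
STUDY_BATCHES = {"inbred_p1": 6, "inbred_p2": 3, "f1": 1, "bc1": 1, "bc5": 1}
# shared marker-gene grid: ~2,000 genes across 24 chromosomes of 1 Morgan
PANEL = {"n_chromosomes": 24, "markers_per_chromosome": 83,
         "chrom_length_morgans": 1.0}


def _designs(populations) -> dict[str, simulate.CrossDesign]:
    kinds = {"inbred_p1": "INBRED_P1", "inbred_p2": "INBRED_P2",
             "f1": "F1", "bc1": "BC1", "bc5": "BC5"}
    return {p: simulate.CrossDesign(kinds[p], STUDY_N[p], **PANEL)
            for p in populations}


def variability_study(
    seed: int,
    populations=("inbred_p1", "inbred_p2", "f1", "bc1"),
    f1_stabilized: bool = True,
):
    """Multi-population study for CV-distribution comparisons."""
    designs = _designs(populations)
    first = next(iter(designs.values()))
    ann = first.annotation()
    n_genes = len(ann)
    arch = simulate.make_architecture(
        ann,
        n_cis_regulated=int(0.65 * n_genes),
        n_trans_regulated=int(0.10 * n_genes),
        n_both=int(0.03 * n_genes),
        effect_size_range=(0.5, 2.0),
        seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
        f1_stabilized_fraction=1.0 if f1_stabilized else 0.0,
    )
    return simulate.simulate_study(
        designs, seed, architecture=arch,
        n_batches={p: STUDY_BATCHES[p] for p in designs})


def association_study(seed: int):
    """Single BC1 population with 20 cis + 10 trans regulated targets."""
    design = simulate.CrossDesign("BC1", STUDY_N["bc1"], **PANEL)
    return simulate.simulate_dataset(
        design, seed, n_cis_regulated=20, n_trans_regulated=10, n_both=0,
        effect_size_range=(1.0, 2.0))


def null_study(seed: int, n_genes: int = 1000, n_individuals: int = 14):
    """BC1 population with no regulators (global null)."""
    design = simulate.CrossDesign(
        "BC1", n_individuals, n_chromosomes=20,
        markers_per_chromosome=max(1, n_genes // 20))
    return simulate.simulate_dataset(design, seed)


def study_linear_matrices(study, protect_population: bool = True):
    """Normalize every population of a study; returns linear CPM frames."""
    from hybridvar import normalize

    out = {}
    for name, (truth, counts, _) in study.items():
        norm = normalize.normalize_pipeline(
            counts, truth.metadata(), protect_population=protect_population)
        out[name] = norm.linear()
    return out
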
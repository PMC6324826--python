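"""Synthetic interspecies-cross populations with known regulatory truth.

The generator mirrors the structure of an RNA-seq study of inbred, F1 and
backcross (BC_n) hybrid populations from two diverged parental species:

- **Ancestry.** Each gene doubles as an ancestry marker.  A BC_n individual
  carries one intact recurrent-parent haplotype plus a gamete built by *n*
  successive meioses starting from the F1; crossovers between adjacent
  markers follow the Haldane map function r = (1 - e^(-2d)) / 2 for map
  distance *d* Morgans, without interference.  A locus is heterozygous
  (HET) iff every meiosis transmitted the donor-side haplotype there, so
  the expected HET fraction is 0.5^n per locus and the expected
  recurrent-*allele* genome fraction is 1 - 0.5^(n+1) (counting the F1
  meiosis; 98.4% for BC5).  Inbred designs are homozygous everywhere; the
  F1 is heterozygous everywhere.
- **Expression.** Counts are negative binomial with mean = baseline x
  library-size factor x per-(gene, batch) factor x 2^(sum of regulator
  effects active in that individual).  A regulator contributes its
  log2-fold-change when the individual is HET at the regulator locus
  (homozygous-recurrent is the reference state).  Dispersion 0 is treated
  as the noiseless limit (counts = rounded mean).
- **Allelic reads.** Only reads covering interspecific polymorphic sites
  are allele-assignable: an informative depth is binomially thinned from
  the gene's count, then split binomially with parent-1 probability equal
  to the gene's allelic ratio in HET individuals and 0 in
  homozygous-recurrent individuals.
- **F1 stabilization.** Genes flagged ``f1_stabilized`` model a dominant
  "homeostasis" allele: their dispersion is multiplied by a reduction
  factor in F1 populations only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from hybridvar import io as hio
from hybridvar._constants import BP_PER_MORGAN, HET, HOM_RECURRENT

__all__ = [
    "CrossDesign",
    "RegulatoryArchitecture",
    "SimTruth",
    "haldane",
    "simulate_ancestry",
    "make_architecture",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
]


def haldane(d: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for map distance ``d`` Morgans (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d, dtype=float)))


_DESIGN_RE = re.compile(r"^(INBRED_P1|INBRED_P2|F1|BC(\d+))$")


class InvalidDesignError(ValueError):
    """Raised for cross designs that cannot be simulated."""


@dataclass(frozen=True)
class CrossDesign:
    """A cross to simulate.

    Parameters
    ----------
    design
        ``"INBRED_P1"``, ``"INBRED_P2"``, ``"F1"`` or ``"BC<n>"`` with
        n >= 1 backcross generations to the recurrent parent.
    n_individuals
        Population size (>= 2).
    n_chromosomes, markers_per_chromosome
        Marker-gene grid; markers are evenly spaced along each chromosome.
    chrom_length_morgans
        Genetic length of every chromosome, in Morgans.
    recurrent_parent
        ``"P1"`` or ``"P2"``; the species backcrossed into.  Homozygous
        calls in BC progeny carry this parent's alleles.  Parent 2 by
        default, matching a cross where parent 1 is the donor species.
    """

    design: str
    n_individuals: int
    n_chromosomes: int = 24
    markers_per_chromosome: int = 50
    chrom_length_morgans: float = 1.0
    recurrent_parent: str = "P2"

    def __post_init__(self) -> None:
        m = _DESIGN_RE.match(self.design)
        if not m:
            raise InvalidDesignError(f"unknown design {self.design!r}")
        if m.group(2) is not None and int(m.group(2)) < 1:
            raise InvalidDesignError("BC designs need n >= 1 generations")
        if self.n_individuals < 2:
            raise InvalidDesignError("need at least 2 individuals")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise InvalidDesignError("need >= 1 chromosome and >= 1 marker each")
        if self.chrom_length_morgans <= 0:
            raise InvalidDesignError("chromosome genetic length must be positive")
        if self.recurrent_parent not in ("P1", "P2"):
            raise InvalidDesignError("recurrent parent must be 'P1' or 'P2'")

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    @property
    def backcross_generations(self) -> int:
        m = _DESIGN_RE.match(self.design)
        return int(m.group(2)) if m.group(2) else 0

    def annotation(self) -> pd.DataFrame:
        """Gene annotation implied by the marker grid.

        Markers sit at evenly spaced, strictly increasing map positions
        ``(j + 0.5) * L / m`` on each chromosome; BED coordinates encode
        the position at ``BP_PER_MORGAN`` bp per Morgan.
        """
        m = self.markers_per_chromosome
        pos = (np.arange(m) + 0.5) * self.chrom_length_morgans / m
        rows = []
        for c in range(self.n_chromosomes):
            chrom = f"chr{c + 1}"
            for j in range(m):
                rows.append((f"g_{chrom}_{j:04d}", chrom, pos[j]))
        ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "pos_morgans"])
        ann["start"] = np.round(ann["pos_morgans"] * BP_PER_MORGAN).astype(int)
        ann["end"] = ann["start"] + 1000
        return ann.set_index("gene_id")

    def sample_names(self) -> list[str]:
        tag = self.design.lower()
        return [f"{tag}_{i:03d}" for i in range(self.n_individuals)]


@dataclass
class RegulatoryArchitecture:
    """Ground-truth expression model for a gene panel.

    ``regulators`` maps a target gene id to a list of
    ``(regulator_gene_id, mode, effect_lfc)`` tuples where ``mode`` is
    ``"cis"`` (same chromosome as the target) or ``"trans"`` and
    ``effect_lfc`` is the log2 fold-change of the target's mean when the
    regulator locus is HET versus homozygous-recurrent.
    """

    gene_ids: list[str]
    baseline_mean: np.ndarray          # expected counts per gene
    dispersion: np.ndarray             # NB dispersion per gene (>= 0)
    allelic_ratio: np.ndarray          # expected P1 read fraction in a HET
    f1_stabilized: np.ndarray          # bool per gene
    regulators: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("baseline_mean", "dispersion", "allelic_ratio", "f1_stabilized"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per gene")
            setattr(self, name, arr)
        if np.any(self.dispersion < 0):
            raise ValueError("dispersion must be >= 0")
        if np.any((self.allelic_ratio <= 0) | (self.allelic_ratio >= 1)):
            raise ValueError("allelic ratio must be in (0, 1)")
        for target, regs in self.regulators.items():
            for reg, mode, eff in regs:
                if mode not in ("cis", "trans"):
                    raise ValueError(f"bad mode {mode!r} for {target}")
                if not np.isfinite(eff):
                    raise ValueError(f"non-finite effect for {target}<-{reg}")

    def true_pairs(self) -> set[tuple[str, str]]:
        """All (regulator, target) pairs with a nonzero effect."""
        return {(reg, tgt) for tgt, regs in self.regulators.items()
                for reg, _, eff in regs if eff != 0}


@dataclass
class SimTruth:
    """Everything downstream stages would have to rediscover."""

    design: CrossDesign
    genotypes: pd.DataFrame            # genes x samples, int codes
    architecture: RegulatoryArchitecture
    annotation: pd.DataFrame
    library_factors: pd.Series         # per-sample multiplicative factor
    batches: pd.Series                 # per-sample batch label
    seed: int
    population: str | None = None      # label in metadata; defaults to design

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame({
            "population": self.population or self.design.design,
            "batch": self.batches,
        }, index=self.genotypes.columns).rename_axis("sample")


def simulate_ancestry(design: CrossDesign, seed: int) -> pd.DataFrame:
    """Simulate per-marker ancestry genotypes for one population.

    Returns a genes x individuals DataFrame of integer codes (HET /
    HOM_RECURRENT).  Inbreds are homozygous everywhere (coded
    HOM_RECURRENT regardless of which species, since downstream analyses
    only use the HET/HOM dichotomy); the F1 is HET everywhere.  BC_n
    gametes are built by composing *n* independent crossover chains: the
    donor-side haplotype survives at a marker only if every meiosis chose
    it there.
    """
    rng = np.random.default_rng(seed)
    ann = design.annotation()
    n_ind = design.n_individuals
    n_genes = design.n_genes

    if design.design.startswith("INBRED"):
        calls = np.full((n_genes, n_ind), HOM_RECURRENT, dtype=np.int8)
    elif design.design == "F1":
        calls = np.full((n_genes, n_ind), HET, dtype=np.int8)
    else:
        n_gen = design.backcross_generations
        m = design.markers_per_chromosome
        d = design.chrom_length_morgans / m  # between adjacent markers
        r = float(haldane(d))
        blocks = []
        for _ in range(design.n_chromosomes):
            # donor[i, k, j]: meiosis k of individual i transmits the
            # donor-side haplotype at marker j.  First marker is a fair
            # coin; afterwards the chain switches with probability r.
            start = rng.random((n_ind, n_gen, 1)) < 0.5
            switches = rng.random((n_ind, n_gen, m - 1)) < r
            path = np.concatenate([start, switches], axis=2)
            donor = np.cumsum(path, axis=2) % 2 == 1
            het = donor.all(axis=1)  # HET iff donor allele survived all meioses
            blocks.append(np.where(het, HET, HOM_RECURRENT).T.astype(np.int8))
        calls = np.concatenate(blocks, axis=0)

    return pd.DataFrame(calls, index=ann.index, columns=design.sample_names())


def make_architecture(
    annotation: pd.DataFrame,
    n_cis_regulated: int = 0,
    n_trans_regulated: int = 0,
    n_both: int = 0,
    effect_size_range: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
    *,
    baseline_mean_range: tuple[float, float] = (100.0, 2000.0),
    dispersion: float = 0.003,
    allelic_ratio: float = 0.5,
    f1_stabilized_fraction: float = 0.0,
    f1_stabilized: Sequence[bool] | None = None,
    cis_window: float = 0.1,
) -> RegulatoryArchitecture:
    """Draw a regulatory architecture over an annotated gene panel.

    Exactly ``n_cis_regulated - n_both`` targets get a cis regulator only,
    ``n_trans_regulated - n_both`` a trans regulator only, and ``n_both``
    one of each.  Cis regulation is local: the regulator is drawn from
    the target's chromosome within ``cis_window`` Morgans of the target
    (never the target itself; the window widens to the whole chromosome
    if no neighbour lies inside it), so a cis-regulated gene's
    expression tracks its own ancestry genotype through linkage.  Trans
    regulators come from another chromosome.  Effect log2 fold-changes
    are uniform over ``effect_size_range``.  Baseline means are
    log-uniform over ``baseline_mean_range``.
    """
    if min(n_cis_regulated, n_trans_regulated, n_both) < 0:
        raise ValueError("regulated-gene counts must be non-negative")
    if n_both > min(n_cis_regulated, n_trans_regulated):
        raise ValueError("n_both cannot exceed the cis or trans count")
    n_genes = len(annotation)
    n_targets = n_cis_regulated + n_trans_regulated - n_both
    if n_targets > n_genes:
        raise ValueError(
            f"{n_targets} regulated targets requested but only {n_genes} genes")
    if annotation["chrom"].nunique() < 2 and n_trans_regulated > 0:
        raise ValueError("trans regulators need at least 2 chromosomes")

    rng = np.random.default_rng(seed)
    gene_ids = list(annotation.index)
    chrom = annotation["chrom"]

    lo, hi = baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes))
    if f1_stabilized is not None:
        stab = np.asarray(f1_stabilized, dtype=bool)
    else:
        stab = rng.random(n_genes) < f1_stabilized_fraction

    targets = rng.choice(n_genes, size=n_targets, replace=False)
    both_t = targets[:n_both]
    cis_t = targets[:n_cis_regulated]                      # both + cis-only
    trans_t = np.concatenate([both_t, targets[n_cis_regulated:]])

    by_chrom: dict[str, np.ndarray] = {
        c: np.flatnonzero((chrom == c).to_numpy()) for c in chrom.unique()}
    all_idx = np.arange(n_genes)

    regulators: dict[str, list[tuple[str, str, float]]] = {}

    def _effect() -> float:
        return float(rng.uniform(*effect_size_range))

    pos = annotation["pos_morgans"].to_numpy() if "pos_morgans" in annotation \
        else np.zeros(n_genes)
    for t in cis_t:
        pool = by_chrom[chrom.iloc[t]]
        pool = pool[pool != t]
        if pool.size == 0:
            raise ValueError(
                f"gene {gene_ids[t]} has no same-chromosome cis candidate")
        local = pool[np.abs(pos[pool] - pos[t]) <= cis_window]
        reg = int(rng.choice(local if local.size else pool))
        regulators.setdefault(gene_ids[t], []).append(
            (gene_ids[reg], "cis", _effect()))
    for t in trans_t:
        pool = all_idx[(chrom != chrom.iloc[t]).to_numpy()]
        reg = int(rng.choice(pool))
        regulators.setdefault(gene_ids[t], []).append(
            (gene_ids[reg], "trans", _effect()))

    return RegulatoryArchitecture(
        gene_ids=gene_ids,
        baseline_mean=baseline,
        dispersion=np.full(n_genes, float(dispersion)),
        allelic_ratio=np.full(n_genes, float(allelic_ratio)),
        f1_stabilized=stab,
        regulators=regulators,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) counts; dispersion 0 is the noiseless limit."""
    counts = np.rint(mean).astype(np.int64)
    noisy = dispersion > 0
    if np.any(noisy):
        disp = dispersion[noisy]
        mu = mean[noisy]
        shape = 1.0 / disp
        # gamma-Poisson mixture == negative binomial with Var = mu + disp*mu^2
        lam = rng.gamma(shape=shape, scale=mu * disp)
        counts[noisy] = rng.poisson(lam)
    return counts


def simulate_expression(
    truth: SimTruth,
    seed: int,
    *,
    informative_fraction: float = 0.5,
    f1_dispersion_factor: float = 0.1,
) -> tuple[pd.DataFrame, tuple[pd.DataFrame, pd.DataFrame]]:
    """Draw counts and allele-split depths for a simulated population.

    Returns ``(counts, (p1_depths, p2_depths))`` where counts is a
    genes x samples integer matrix and the allele tables give parent-1 /
    parent-2 read depths at polymorphic sites (their sum is the drawn
    informative depth, a binomial thinning of the count with probability
    ``informative_fraction``).
    """
    if not 0 < informative_fraction <= 1:
        raise ValueError("informative_fraction must be in (0, 1]")
    arch = truth.architecture
    geno = truth.genotypes
    if list(geno.index) != list(arch.gene_ids):
        raise ValueError("architecture genes do not match genotype matrix")
    for tgt, regs in arch.regulators.items():
        for reg, _, _ in regs:
            if reg not in geno.index:
                raise ValueError(f"regulator {reg!r} absent from genotype matrix")

    rng = np.random.default_rng(seed)
    n_genes, n_ind = geno.shape
    gene_pos = {g: i for i, g in enumerate(geno.index)}

    log2_mean = np.log2(arch.baseline_mean)[:, None] * np.ones((1, n_ind))
    gmat = geno.to_numpy()
    for tgt, regs in arch.regulators.items():
        t = gene_pos[tgt]
        for reg, _, eff in regs:
            log2_mean[t] += eff * (gmat[gene_pos[reg]] == HET)

    lib = truth.library_factors.to_numpy()[None, :]
    batch_labels = truth.batches.to_numpy()
    uniq_batches = pd.unique(batch_labels)
    # per-(gene, batch) multiplicative log-normal factors; a single batch
    # contributes nothing so batch-free analyses stay calibrated
    batch_factor = np.ones((n_genes, n_ind))
    if len(uniq_batches) > 1:
        per_batch = np.exp(rng.normal(0.0, 0.15, size=(n_genes, len(uniq_batches))))
        for j, b in enumerate(uniq_batches):
            batch_factor[:, batch_labels == b] = per_batch[:, [j]]

    mean = 2.0 ** log2_mean * lib * batch_factor

    dispersion = np.repeat(arch.dispersion[:, None], n_ind, axis=1)
    if truth.design.design == "F1":
        dispersion[arch.f1_stabilized, :] *= f1_dispersion_factor

    counts = _nb_draw(rng, mean.ravel(), dispersion.ravel()).reshape(n_genes, n_ind)

    depth = rng.binomial(counts, informative_fraction)
    het = gmat == HET
    p1_prob = np.where(het, arch.allelic_ratio[:, None], 0.0)
    p1 = rng.binomial(depth, p1_prob)
    p2 = depth - p1

    idx, cols = geno.index, geno.columns
    return (
        pd.DataFrame(counts, index=idx, columns=cols),
        (pd.DataFrame(p1, index=idx, columns=cols),
         pd.DataFrame(p2, index=idx, columns=cols)),
    )


def simulate_dataset(
    design: CrossDesign,
    seed: int,
    *,
    architecture: RegulatoryArchitecture | None = None,
    n_batches: int = 1,
    library_sigma: float = 0.2,
    informative_fraction: float = 0.5,
    f1_dispersion_factor: float = 0.1,
    **arch_kwargs,
) -> tuple[SimTruth, pd.DataFrame, tuple[pd.DataFrame, pd.DataFrame]]:
    """One-call simulation: ancestry, architecture, counts, allele depths.

    A single seed expands deterministically into independent substreams
    for the ancestry, architecture, nuisance (library/batch) and count
    stages, so components can be regenerated in isolation.
    """
    ss = np.random.SeedSequence(seed)
    s_anc, s_arch, s_nuis, s_expr = [int(c.generate_state(1)[0] % (2**31))
                                     for c in ss.spawn(4)]
    ann = design.annotation()
    geno = simulate_ancestry(design, s_anc)
    if architecture is None:
        architecture = make_architecture(ann, seed=s_arch, **arch_kwargs)

    rng = np.random.default_rng(s_nuis)
    lib = pd.Series(np.exp(rng.normal(0.0, library_sigma, design.n_individuals)),
                    index=geno.columns)
    batches = pd.Series([f"b{i % n_batches + 1}" for i in range(design.n_individuals)],
                        index=geno.columns)
    truth = SimTruth(design=design, genotypes=geno, architecture=architecture,
                     annotation=ann, library_factors=lib, batches=batches, seed=seed)
    counts, alleles = simulate_expression(
        truth, s_expr, informative_fraction=informative_fraction,
        f1_dispersion_factor=f1_dispersion_factor)
    return truth, counts, alleles


def simulate_study(
    designs: dict[str, CrossDesign],
    seed: int,
    *,
    architecture: RegulatoryArchitecture | None = None,
    n_batches: dict[str, int] | None = None,
    library_sigma: float = 0.2,
    informative_fraction: float = 0.5,
    f1_dispersion_factor: float = 0.1,
    **arch_kwargs,
) -> dict[str, tuple[SimTruth, pd.DataFrame, tuple[pd.DataFrame, pd.DataFrame]]]:
    """Simulate several populations of one cross on a shared gene panel.

    All designs must agree on the marker grid (same chromosomes and
    markers) — they describe populations of the same two-species genome,
    so they share one annotation and one regulatory architecture (drawn
    once from ``arch_kwargs`` unless given).  Sample names are prefixed
    with the population key.  Returns ``{name: (truth, counts,
    (p1, p2))}``.
    """
    grids = {(d.n_chromosomes, d.markers_per_chromosome, d.chrom_length_morgans)
             for d in designs.values()}
    if len(grids) != 1:
        raise InvalidDesignError("all populations must share one marker grid")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(designs) + 1)
    first = next(iter(designs.values()))
    if architecture is None:
        s_arch = int(children[0].generate_state(1)[0] % (2**31))
        architecture = make_architecture(first.annotation(), seed=s_arch,
                                         **arch_kwargs)
    out = {}
    for child, (name, design) in zip(children[1:], designs.items()):
        sub = int(child.generate_state(1)[0] % (2**31))
        truth, counts, alleles = simulate_dataset(
            design, sub, architecture=architecture,
            n_batches=(n_batches or {}).get(name, 1),
            library_sigma=library_sigma,
            informative_fraction=informative_fraction,
            f1_dispersion_factor=f1_dispersion_factor)
        rename = {c: f"{name}_{c}" for c in counts.columns}
        truth.genotypes = truth.genotypes.rename(columns=rename)
        truth.library_factors = truth.library_factors.rename(index=rename)
        truth.batches = truth.batches.rename(index=rename)
        truth.batches = truth.batches.map(lambda b: f"{name}_{b}")
        counts = counts.rename(columns=rename)
        alleles = (alleles[0].rename(columns=rename),
                   alleles[1].rename(columns=rename))
        truth.population = name
        out[name] = (truth, counts, alleles)
    return out


def write_dataset(out_dir: str | Path, truth: SimTruth, counts: pd.DataFrame,
                  alleles: tuple[pd.DataFrame, pd.DataFrame],
                  provenance: dict | None = None) -> None:
    """Write counts, allele table, annotation, metadata and truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_matrix(counts, out / "counts.tsv", provenance)
    hio.write_allele_counts(*alleles, out / "alleles.tsv", provenance)
    hio.write_annotation(truth.annotation, out / "genes.bed", provenance)
    hio.write_metadata(truth.metadata(), out / "samples.tsv", provenance)
    hio.write_genotypes(truth.genotypes, out / "truth_genotypes.tsv", provenance)
    regs = [
        {"target": t, "regulator": r, "mode": m, "effect_lfc": e}
        for t, rr in truth.architecture.regulators.items() for r, m, e in rr
    ]
    reg_df = pd.DataFrame(regs, columns=["target", "regulator", "mode", "effect_lfc"])
    hio.write_tsv(reg_df.set_index("target"), out / "truth_regulators.tsv",
                  index_label="target", provenance=provenance)
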
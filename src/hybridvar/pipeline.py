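"""End-to-end pipeline: simulate/load -> genotype -> normalize -> CV ->
variability classes -> association, with provenance and a report.

A :class:`RunConfig` either points at input files (counts, allele table,
annotation, metadata) or requests a simulated cross.  :func:`run`
executes every stage, writes each stage's TSV output with a provenance
header (tool version, config hash, seed) and returns a consolidated
report: CV peak per population, pairwise KS table, variability-class
counts, association counts (cis-only / trans-only / both) and
stratified-vs-pooled CV medians.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hybridvar import __version__, io as hio
from hybridvar import ase, association, normalize, simulate, variability
from hybridvar._constants import (
    DEFAULT_ALPHA,
    DEFAULT_CV_RATIO_HIGH,
    DEFAULT_CV_RATIO_LOW,
    DEFAULT_EXPRESSION_FLOOR_CPM,
    DEFAULT_MIN_CLASS_SIZE,
)

logger = logging.getLogger("hybridvar")

__all__ = ["RunConfig", "PipelineError", "run", "validate_inputs"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``counts``/``alleles``/``annotation``/``metadata`` point at
    input files, or ``simulate_design`` requests a synthetic cross of
    ``simulate_n`` individuals over ``simulate_genes`` genes.
    """

    out_dir: str = "hybridvar_run"
    seed: int = 1
    # file inputs
    counts: str | None = None
    alleles: str | None = None
    annotation: str | None = None
    metadata: str | None = None
    # or simulator inputs
    simulate_design: str | None = None
    simulate_n: int = 14
    simulate_genes: int = 2000
    simulate_chromosomes: int = 24
    n_cis_regulated: int = 20
    n_trans_regulated: int = 10
    n_both: int = 0
    effect_size_low: float = 1.0
    effect_size_high: float = 2.0
    # thresholds
    alpha: float = DEFAULT_ALPHA
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE
    expression_floor: float = DEFAULT_EXPRESSION_FLOOR_CPM
    cv_ratio_low: float = DEFAULT_CV_RATIO_LOW
    cv_ratio_high: float = DEFAULT_CV_RATIO_HIGH
    min_depth: int = 10
    min_minor_fraction: float = 0.15
    protect_population: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_class_size < 1:
            raise ValueError("min_class_size must be >= 1")
        if not 0 < self.cv_ratio_low < 1:
            raise ValueError("cv_ratio_low must be in (0, 1)")
        if self.cv_ratio_high <= 1:
            raise ValueError("cv_ratio_high must be > 1")
        has_files = self.counts is not None
        has_sim = self.simulate_design is not None
        if has_files == has_sim:
            raise ValueError("give either input files or a simulate design")

    def config_hash(self) -> str:
        # the output path does not affect results, so it is not hashed
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def provenance(self) -> dict[str, object]:
        return {"tool": f"hybridvar/{__version__}",
                "config": self.config_hash(), "seed": self.seed}


def validate_inputs(counts: pd.DataFrame, metadata: pd.DataFrame,
                    annotation: pd.DataFrame | None = None,
                    alleles: tuple[pd.DataFrame, pd.DataFrame] | None = None,
                    ) -> list[str]:
    """Consistency diagnostics across an input bundle (read-only).

    Checks that sample sets match between counts and metadata, gene sets
    overlap with the annotation, and ids are unique.  Returns a list of
    human-readable diagnostics; empty means consistent.
    """
    diagnostics: list[str] = []
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        diagnostics.append(f"duplicated gene id(s) in counts: {dups[:5]}")
    for s in counts.columns:
        if s not in metadata.index:
            diagnostics.append(f"sample {s!r} in counts but not metadata")
    for s in metadata.index:
        if s not in counts.columns:
            diagnostics.append(f"sample {s!r} in metadata but not counts")
    for col in ("population", "batch"):
        if col not in metadata.columns:
            diagnostics.append(f"metadata lacks column {col!r}")
    if annotation is not None:
        overlap = counts.index.intersection(annotation.index)
        if len(overlap) == 0:
            diagnostics.append("no genes shared between counts and annotation")
    if alleles is not None:
        p1, p2 = alleles
        if not p1.index.equals(p2.index) or not p1.columns.equals(p2.columns):
            diagnostics.append("allele table P1/P2 halves are misaligned")
        elif not p1.columns.equals(counts.columns):
            diagnostics.append("allele table samples differ from counts")
    return diagnostics


def _load_or_simulate(cfg: RunConfig, out: Path):
    prov = cfg.provenance()
    if cfg.simulate_design is not None:
        design = simulate.CrossDesign(
            design=cfg.simulate_design,
            n_individuals=cfg.simulate_n,
            n_chromosomes=cfg.simulate_chromosomes,
            markers_per_chromosome=max(1, cfg.simulate_genes // cfg.simulate_chromosomes),
        )
        truth, counts, alleles = simulate.simulate_dataset(
            design, cfg.seed,
            n_cis_regulated=cfg.n_cis_regulated,
            n_trans_regulated=cfg.n_trans_regulated,
            n_both=cfg.n_both,
            effect_size_range=(cfg.effect_size_low, cfg.effect_size_high),
        )
        simulate.write_dataset(out / "simulated", truth, counts, alleles, prov)
        return counts, alleles, truth.annotation, truth.metadata()
    for name in ("counts", "alleles", "annotation", "metadata"):
        path = getattr(cfg, name)
        if path is None or not Path(path).exists():
            raise PipelineError(f"stage input: missing {name} file: {path}")
    counts = hio.read_matrix(cfg.counts)
    alleles = hio.read_allele_counts(cfg.alleles)
    annotation = hio.read_annotation(cfg.annotation)
    metadata = hio.read_metadata(cfg.metadata)
    return counts, alleles, annotation, metadata


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written).

    Stage failures raise :class:`PipelineError` naming the stage; outputs
    written before the failure are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = cfg.provenance()
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    n_warnings = 0
    try:
        counts, alleles, annotation, metadata = _load_or_simulate(cfg, out)

        diagnostics = validate_inputs(counts, metadata, annotation, alleles)
        if diagnostics:
            raise PipelineError("stage validate: " + "; ".join(diagnostics))

        try:
            params = ase.GenotypeParams(min_depth=cfg.min_depth,
                                        min_minor_fraction=cfg.min_minor_fraction)
            genotypes, complete = ase.genotype_population(*alleles, params)
            hio.write_genotypes(genotypes, out / "genotypes.tsv", prov)
        except Exception as e:
            raise PipelineError(f"stage genotype: {e}") from e

        try:
            norm = normalize.normalize_pipeline(
                counts, metadata, protect_population=cfg.protect_population)
            for w in norm.warnings:
                logger.warning(w)
            n_warnings += len(norm.warnings)
            hio.write_matrix(norm.values.round(6), out / "normalized.tsv", prov)
        except Exception as e:
            raise PipelineError(f"stage normalize: {e}") from e

        try:
            linear = norm.linear()
            populations = metadata["population"].unique()
            cv_frames, peaks, dists = [], {}, {}
            for popn in populations:
                cols = metadata.index[metadata["population"] == popn]
                tab = variability.cv_table(linear[cols], popn,
                                           cfg.expression_floor)
                cv_frames.append(tab)
                if len(tab) >= 2:
                    dist = variability.cv_density(tab["cv"])
                    dists[popn] = dist
                    peaks[popn] = dist.peak
            cv_all = pd.concat(cv_frames)
            hio.write_tsv(cv_all, out / "cv_records.tsv", provenance=prov)
            ks_rows = []
            pops = list(dists)
            for i, a in enumerate(pops):
                for b in pops[i + 1:]:
                    D, p = variability.ks_compare(dists[a].cvs, dists[b].cvs)
                    ks_rows.append((a, b, D, p))
            ks_table = pd.DataFrame(ks_rows, columns=["pop_a", "pop_b", "D", "p"])
            hio.write_tsv(ks_table.set_index("pop_a"), out / "ks_table.tsv",
                          index_label="pop_a", provenance=prov)
        except Exception as e:
            raise PipelineError(f"stage variability: {e}") from e

        try:
            records = association.scan(
                genotypes, norm.values, annotation,
                min_class_size=cfg.min_class_size, alpha=cfg.alpha)
            n_warnings += len(records.attrs.get("skipped", []))
            hio.write_tsv(records[records["significant"]].set_index("marker"),
                          out / "associations.tsv", index_label="marker",
                          provenance=prov)
            modes = association.summarize_modes(records)
            de = association.de_by_genotype(norm.values, genotypes,
                                            cfg.min_class_size, cfg.alpha)
            hio.write_tsv(de, out / "de_by_genotype.tsv", provenance=prov)
            strat = variability.stratified_cv(linear, genotypes,
                                              expression_floor=cfg.expression_floor)
            hio.write_tsv(strat, out / "stratified_cv.tsv", provenance=prov)
        except Exception as e:
            raise PipelineError(f"stage association: {e}") from e

        report = {
            "tool_version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_genes": int(counts.shape[0]),
            "n_samples": int(counts.shape[1]),
            "n_genotyped_complete": int(complete.sum()),
            "cv_peak_per_population": {k: round(v, 6) for k, v in peaks.items()},
            "ks_pairs": ks_table.to_dict("records"),
            "association": modes,
            "n_de_genes": int(de["differential"].sum()) if len(de) else 0,
            "stratified_vs_pooled": {
                "median_stratified": (
                    float(np.median(np.concatenate(
                        [strat["cv_het"], strat["cv_hom"]])))
                    if len(strat) else None),
                "median_pooled": (float(strat["cv_pooled"].median())
                                  if len(strat) else None),
            },
            "n_warnings": n_warnings,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
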
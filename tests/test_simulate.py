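import numpy as np
import pandas as pd
import pytest

from hybridvar import HET, HOM_RECURRENT, simulate
from hybridvar.simulate import (
    CrossDesign,
    InvalidDesignError,
    haldane,
    make_architecture,
    simulate_ancestry,
    simulate_dataset,
    simulate_expression,
)


class TestCrossDesign:
    @pytest.mark.parametrize("kwargs", [
        {"design": "BC0"},
        {"design": "F2"},
        {"design": "F1", "n_individuals": 1},
        {"design": "F1", "chrom_length_morgans": 0.0},
        {"design": "F1", "markers_per_chromosome": 0},
        {"design": "BC1", "recurrent_parent": "P3"},
    ])
    def test_invalid_designs_rejected(self, kwargs):
        kwargs.setdefault("n_individuals", 4)
        with pytest.raises(InvalidDesignError):
            CrossDesign(**kwargs)

    def test_marker_positions_strictly_increasing(self):
        ann = CrossDesign("F1", 4, 3, 10).annotation()
        for _, sub in ann.groupby("chrom"):
            assert (np.diff(sub["pos_morgans"]) > 0).all()


class TestAncestry:
    def test_f1_all_heterozygous(self):
        geno = simulate_ancestry(CrossDesign("F1", 5, 2, 4), seed=0)
        assert (geno.values == HET).all()

    def test_inbred_all_homozygous(self):
        geno = simulate_ancestry(CrossDesign("INBRED_P2", 5, 2, 4), seed=0)
        assert (geno.values == HOM_RECURRENT).all()

    def test_bc1_recombination_matches_haldane(self):
        # two markers 0.5 Morgans apart: discordance rate must match the
        # closed-form Haldane recombination fraction
        design = CrossDesign("BC1", 10_000, 1, 2, chrom_length_morgans=1.0)
        geno = simulate_ancestry(design, seed=123)
        observed = (geno.values[0] != geno.values[1]).mean()
        expected = haldane(0.5)  # (1 - e^-1)/2 ~ 0.316
        se = np.sqrt(expected * (1 - expected) / design.n_individuals)
        assert abs(observed - expected) < 3 * se

    def test_bc1_het_frequency_half(self):
        design = CrossDesign("BC1", 4000, 2, 10)
        geno = simulate_ancestry(design, seed=5)
        het = (geno.values == HET).mean(axis=1)
        se = np.sqrt(0.25 / 4000)
        assert (np.abs(het - 0.5) < 4 * se).all()

    def test_bc5_recurrent_homozygosity(self):
        # HOM fraction 1 - 0.5^5 per locus; the recurrent-allele genome
        # fraction is 1 - 0.5^6 ~ 98.4% counting the untracked F1 haplotype
        design = CrossDesign("BC5", 3000, 2, 10)
        geno = simulate_ancestry(design, seed=5)
        hom = (geno.values == HOM_RECURRENT).mean()
        expected = 1 - 0.5 ** 5
        se = np.sqrt(expected * (1 - expected) / geno.size)
        assert abs(hom - expected) < 4 * se

    def test_linkage_decays_with_map_distance(self):
        design = CrossDesign("BC1", 3000, 1, 40, chrom_length_morgans=2.0)
        geno = simulate_ancestry(design, seed=9).values == HET
        near = np.corrcoef(geno[0], geno[1])[0, 1]
        far = np.corrcoef(geno[0], geno[39])[0, 1]
        assert near > 0.8
        assert abs(far) < abs(near) / 2

    def test_fixed_seed_reproducible(self):
        design = CrossDesign("BC2", 20, 3, 15)
        a = simulate_ancestry(design, seed=7)
        b = simulate_ancestry(design, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestArchitecture:
    def test_no_regulators_requested(self):
        ann = CrossDesign("BC1", 4, 4, 25).annotation()
        arch = make_architecture(ann, 0, 0, 0, seed=1)
        assert arch.regulators == {}

    def test_exact_regulator_counts_and_placement(self):
        ann = CrossDesign("BC1", 4, 4, 25).annotation()
        arch = make_architecture(ann, 10, 5, 2, seed=1)
        cis_t = {t for t, rr in arch.regulators.items()
                 if any(m == "cis" for _, m, _ in rr)}
        trans_t = {t for t, rr in arch.regulators.items()
                   if any(m == "trans" for _, m, _ in rr)}
        assert len(cis_t - trans_t) == 8
        assert len(trans_t - cis_t) == 3
        assert len(cis_t & trans_t) == 2
        for t, rr in arch.regulators.items():
            for r, mode, eff in rr:
                same = ann.at[t, "chrom"] == ann.at[r, "chrom"]
                assert same == (mode == "cis")
                assert r != t

    def test_infeasible_counts_rejected(self):
        ann = CrossDesign("BC1", 4, 2, 5).annotation()
        with pytest.raises(ValueError):
            make_architecture(ann, 11, 0, 0, seed=1)
        with pytest.raises(ValueError):
            make_architecture(ann, 2, 2, 3, seed=1)


class TestExpression:
    def test_noiseless_limit_recovers_baseline(self):
        design = CrossDesign("INBRED_P1", 6, 2, 5)
        ann = design.annotation()
        arch = make_architecture(ann, 0, 0, 0, seed=2, dispersion=0.0,
                                 baseline_mean_range=(50.0, 50.0))
        geno = simulate_ancestry(design, 0)
        truth = simulate.SimTruth(
            design=design, genotypes=geno, architecture=arch, annotation=ann,
            library_factors=pd.Series(1.0, index=geno.columns),
            batches=pd.Series("b1", index=geno.columns), seed=0)
        counts, _ = simulate_expression(truth, seed=3)
        assert (counts.values == 50).all()

    def test_homozygotes_have_no_parent1_reads(self, bc1_dataset):
        truth, _, (p1, p2) = bc1_dataset
        hom = truth.genotypes.values == HOM_RECURRENT
        assert (p1.values[hom] == 0).all()

    def test_allele_depths_pool_to_allelic_ratio(self):
        design = CrossDesign("F1", 200, 1, 5)
        truth, counts, (p1, p2) = simulate_dataset(design, seed=4)
        depth = (p1 + p2).values.sum()
        frac = p1.values.sum() / depth
        se = np.sqrt(0.25 / depth)
        assert abs(frac - 0.5) < 3 * se

    def test_f1_stabilization_reduces_f1_variance_only(self):
        design_f1 = CrossDesign("F1", 30, 2, 10)
        ann = design_f1.annotation()
        kwargs = dict(seed=6, baseline_mean_range=(1e4, 1e4))
        stab = make_architecture(ann, 0, 0, 0, f1_stabilized_fraction=1.0,
                                 **kwargs)
        plain = make_architecture(ann, 0, 0, 0, f1_stabilized_fraction=0.0,
                                  **kwargs)
        assert stab.f1_stabilized.all() and not plain.f1_stabilized.any()
        out = {}
        for name, arch in [("stab", stab), ("plain", plain)]:
            truth, counts, _ = simulate_dataset(design_f1, seed=8,
                                                architecture=arch,
                                                library_sigma=0.0)
            cv = counts.std(axis=1, ddof=1) / counts.mean(axis=1)
            out[name] = cv.median()
        assert out["stab"] < 0.6 * out["plain"]

    def test_architecture_gene_mismatch_errors(self):
        design = CrossDesign("BC1", 4, 2, 5)
        other = CrossDesign("BC1", 4, 2, 6).annotation()
        arch = make_architecture(other, 0, 0, 0, seed=0)
        geno = simulate_ancestry(design, 0)
        truth = simulate.SimTruth(
            design=design, genotypes=geno, architecture=arch,
            annotation=design.annotation(),
            library_factors=pd.Series(1.0, index=geno.columns),
            batches=pd.Series("b1", index=geno.columns), seed=0)
        with pytest.raises(ValueError):
            simulate_expression(truth, seed=1)

    def test_dataset_deterministic_under_seed(self):
        design = CrossDesign("BC1", 6, 2, 8)
        _, counts_a, (p1a, p2a) = simulate_dataset(design, seed=13,
                                                   n_cis_regulated=2)
        _, counts_b, (p1b, p2b) = simulate_dataset(design, seed=13,
                                                   n_cis_regulated=2)
        pd.testing.assert_frame_equal(counts_a, counts_b)
        pd.testing.assert_frame_equal(p1a, p1b)

    def test_allele_counts_bounded_by_total(self, bc1_dataset):
        _, counts, (p1, p2) = bc1_dataset
        depth = p1 + p2
        assert (depth.values <= counts.values).all()
        assert (p1.values >= 0).all() and (p2.values >= 0).all()


class TestStudy:
    def test_shared_panel_required(self):
        designs = {"a": CrossDesign("F1", 4, 2, 5),
                   "b": CrossDesign("BC1", 4, 2, 6)}
        with pytest.raises(InvalidDesignError):
            simulate.simulate_study(designs, seed=0)

    def test_populations_share_architecture(self):
        designs = {"inbred": CrossDesign("INBRED_P1", 4, 2, 5),
                   "f1": CrossDesign("F1", 4, 2, 5)}
        study = simulate.simulate_study(designs, seed=3)
        archs = [t.architecture for t, _, _ in study.values()]
        assert archs[0] is archs[1]
        meta = study["f1"][0].metadata()
        assert (meta["population"] == "f1").all()
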
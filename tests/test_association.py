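import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridvar import HET, HOM_RECURRENT, MISSING, association
from hybridvar.association import (
    anova_association,
    classify_mode,
    de_by_genotype,
    scan,
    stratified_cv_by_marker,
    summarize_modes,
)


def _annotation(genes, chroms):
    return pd.DataFrame({
        "chrom": chroms,
        "start": np.arange(len(genes)) * 1000,
        "end": np.arange(len(genes)) * 1000 + 500,
        "pos_morgans": np.arange(len(genes)) * 0.001,
    }, index=pd.Index(genes, name="gene_id"))


class TestAnova:
    def test_identical_groups(self):
        F, p = anova_association([HET] * 3 + [HOM_RECURRENT] * 3,
                                 [1, 2, 3, 1, 2, 3])
        assert F == 0.0 and p == 1.0

    def test_two_class_f_equals_t_squared(self, rng):
        """Algebraic identity: one-way ANOVA with 2 classes reduces to the
        square of the pooled-variance t statistic."""
        for _ in range(50):
            g = np.array([HET] * 5 + [HOM_RECURRENT] * 6)
            y = rng.normal(size=11)
            F, p = anova_association(g, y)
            t, pt = stats.ttest_ind(y[g == HET], y[g == HOM_RECURRENT],
                                    equal_var=True)
            assert F == pytest.approx(t ** 2, rel=1e-10)
            assert p == pytest.approx(pt, rel=1e-9)

    def test_zero_within_group_variance(self):
        F, p = anova_association([HET] * 3 + [HOM_RECURRENT] * 3,
                                 [0, 0, 0, 1, 1, 1])
        assert np.isinf(F)
        assert 0 < p < 1e-300

    def test_missing_dropped_and_small_class_untestable(self):
        g = [HET, HET, HET, MISSING, HOM_RECURRENT, HOM_RECURRENT]
        F, p = anova_association(g, [1, 2, 3, 4, 5, 6], min_class_size=3)
        assert np.isnan(F) and np.isnan(p)
        F, p = anova_association(g, [1, 2, 3, 4, 5, 6], min_class_size=2)
        assert np.isfinite(F)

    def test_single_class_untestable(self):
        F, p = anova_association([HET] * 6, np.arange(6.0))
        assert np.isnan(F)


class TestMode:
    def test_same_chromosome_is_cis(self):
        ann = _annotation(["a", "b", "c"], ["chr3", "chr3", "chr7"])
        assert classify_mode("a", "b", ann) == "cis"
        assert classify_mode("a", "c", ann) == "trans"
        assert classify_mode("a", "a", ann) == "cis"

    def test_unannotated_gene_raises(self):
        ann = _annotation(["a"], ["chr1"])
        with pytest.raises(KeyError):
            classify_mode("a", "zzz", ann)


@pytest.fixture(scope="module")
def small_scan(bc1_analysis):
    truth, geno, _, norm = bc1_analysis
    rec = scan(geno, norm.values, truth.annotation)
    return truth, geno, norm, rec


class TestScan:
    def test_q_monotone_in_p_and_dominates_p(self, small_scan):
        _, _, _, rec = small_scan
        assert (rec["q"] >= rec["p"] - 1e-7).all()
        for _, sub in rec.groupby("marker", observed=True):
            s = sub.sort_values("p")
            assert (np.diff(s["q"]) >= -1e-7).all()

    def test_self_pairs_excluded(self, small_scan):
        _, _, _, rec = small_scan
        assert not (rec["marker"].astype(str) == rec["target"].astype(str)).any()

    def test_mode_matches_annotation(self, small_scan):
        truth, _, _, rec = small_scan
        sig = rec[rec["significant"]].head(200)
        for row in sig.itertuples(index=False):
            expected = classify_mode(str(row.marker), str(row.target),
                                     truth.annotation)
            assert row.mode == expected

    def test_uninformative_marker_emits_no_tests(self, bc1_analysis):
        truth, geno, _, norm = bc1_analysis
        geno = geno.copy()
        geno.iloc[0] = HET  # constant genotype: no split to test
        rec = scan(geno, norm.values, truth.annotation)
        assert geno.index[0] not in set(rec["marker"].astype(str))

    def test_keep_significant_matches_filtered_full(self, bc1_analysis):
        truth, geno, _, norm = bc1_analysis
        sub_genes = truth.genotypes.index[:300]
        full = scan(geno.loc[sub_genes], norm.values.loc[sub_genes],
                    truth.annotation)
        sig_only = scan(geno.loc[sub_genes], norm.values.loc[sub_genes],
                        truth.annotation, keep="significant")
        expect = full[full["significant"]].reset_index(drop=True)
        got = sig_only.reset_index(drop=True)
        assert len(expect) == len(got)
        assert set(zip(expect["marker"].astype(str), expect["target"].astype(str))) \
            == set(zip(got["marker"].astype(str), got["target"].astype(str)))

    def test_true_regulators_recovered(self, small_scan):
        truth, _, _, rec = small_scan
        sig = rec[rec["significant"]]
        found = set(zip(sig["marker"].astype(str), sig["target"].astype(str)))
        true_pairs = truth.architecture.true_pairs()
        assert len(true_pairs & found) / len(true_pairs) >= 0.8

    def test_global_fdr_scope_runs(self, bc1_analysis):
        truth, geno, _, norm = bc1_analysis
        sub = truth.genotypes.index[:120]
        rec = scan(geno.loc[sub], norm.values.loc[sub], truth.annotation,
                   fdr_scope="global")
        assert (rec["q"] >= rec["p"] - 1e-7).all()


class TestSummarize:
    def test_empty_records(self):
        empty = pd.DataFrame(columns=["marker", "target", "mode",
                                      "significant"])
        out = summarize_modes(empty)
        assert (out["cis_only"], out["trans_only"], out["both"]) == (0, 0, 0)

    def test_exhaustive_counts(self):
        rec = pd.DataFrame({
            "marker": ["m1", "m2", "m3", "m4", "m5"],
            "target": ["t1", "t1", "t2", "t3", "t4"],
            "mode": ["cis", "trans", "cis", "trans", "cis"],
            "significant": [True, True, True, True, False],
        })
        out = summarize_modes(rec)
        assert out["both"] == 1          # t1 has cis and trans markers
        assert out["cis_only"] == 1      # t2
        assert out["trans_only"] == 1    # t3; t4 is not significant
        assert out["targets"] == 3
        assert out["significant_pairs"] == 4
        assert out["cis_only"] + out["trans_only"] + out["both"] \
            == out["targets"]


class TestDE:
    def test_identical_groups_not_differential(self):
        samples = [f"s{i}" for i in range(6)]
        norm = pd.DataFrame([[1.0, 2, 3, 1, 2, 3]], columns=samples,
                            index=["g"])
        geno = pd.DataFrame([[HET] * 3 + [HOM_RECURRENT] * 3],
                            columns=samples, index=["g"], dtype="int8")
        out = de_by_genotype(norm, geno)
        assert out.at["g", "p"] == pytest.approx(1.0)
        assert not out.at["g", "differential"]

    def test_large_shift_detected(self, rng):
        samples = [f"s{i}" for i in range(14)]
        base = rng.normal(0, 1, (40, 14))
        base[:, :7] += 5.0  # 5 SD shift: HET class above HOM
        norm = pd.DataFrame(base, columns=samples,
                            index=[f"g{i}" for i in range(40)])
        geno = pd.DataFrame([[HET] * 7 + [HOM_RECURRENT] * 7] * 40,
                            columns=samples, index=norm.index, dtype="int8")
        out = de_by_genotype(norm, geno)
        assert out["differential"].all()
        assert (out["mean_diff"] > 0).all()

    def test_small_class_excluded(self):
        samples = [f"s{i}" for i in range(5)]
        norm = pd.DataFrame([[1.0, 2, 3, 4, 5]], columns=samples, index=["g"])
        geno = pd.DataFrame([[HET, HET, HOM_RECURRENT, HOM_RECURRENT,
                              HOM_RECURRENT]], columns=samples, index=["g"],
                            dtype="int8")
        out = de_by_genotype(norm, geno, min_class_size=3)
        assert len(out) == 0


class TestStratifiedByMarker:
    def test_marker_determined_target_has_zero_stratum_cv(self):
        samples = [f"s{i}" for i in range(6)]
        norm = pd.DataFrame([[10.0] * 3 + [40.0] * 3], columns=samples,
                            index=["t"])
        geno = pd.DataFrame([[HET] * 3 + [HOM_RECURRENT] * 3],
                            columns=samples, index=["m"], dtype="int8")
        rec = pd.DataFrame({"marker": ["m"], "target": ["t"],
                            "mode": ["trans"], "significant": [True]})
        out = stratified_cv_by_marker(norm, rec, geno)
        assert out.at[0, "cv_het"] == 0.0
        assert out.at[0, "cv_hom"] == 0.0
        assert out.at[0, "cv_pooled"] > 0.0

    def test_simulated_cis_architecture_reduces_cv(self, bc1_analysis):
        truth, geno, _, norm = bc1_analysis
        rec = scan(geno, norm.values, truth.annotation, keep="significant")
        out = stratified_cv_by_marker(norm.linear(), rec, geno)
        strat = np.concatenate([out["cv_het"], out["cv_hom"]])
        assert np.median(strat) < out["cv_pooled"].median()
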
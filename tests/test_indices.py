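import numpy as np
import pandas as pd
import pytest

from droughtstrat.indices import (
    group_index,
    log_response_ratio,
    management_effect_test,
    standardize_taxon,
    strategy_ratio,
)
from .conftest import make_toy_meta


class TestStandardize:
    def test_constant_vector_becomes_ones(self):
        np.testing.assert_allclose(
            standardize_taxon([0.02, 0.02, 0.02]), [1.0, 1.0, 1.0])

    def test_two_point_example(self):
        np.testing.assert_allclose(standardize_taxon([0.01, 0.03]), [0.5, 1.5])

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        assert standardize_taxon(x).mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="cannot standardize"):
            standardize_taxon([0.0, 0.0])

    def test_alternative_standardizers(self):
        x = np.array([1.0, 3.0])
        assert standardize_taxon(x, "max_division").max() == 1.0
        assert standardize_taxon(x, "z_score").mean() == pytest.approx(0.0)


def _rel(df):
    return df.div(df.sum(axis=0), axis=1)


class TestGroupIndex:
    def test_constant_taxa_index_equals_group_size(self):
        rel = pd.DataFrame(0.1, index=["a", "b", "c"], columns=["s1", "s2"])
        labels = pd.Series("g", index=["a", "b", "c"])
        idx = group_index(rel, labels, "g")
        np.testing.assert_allclose(idx.to_numpy(), [3.0, 3.0])

    def test_matches_spreadsheet_recomputation(self):
        rng = np.random.default_rng(1)
        rel = pd.DataFrame(rng.random((3, 4)),
                           index=["a", "b", "c"], columns=list("wxyz"))
        labels = pd.Series("g", index=["a", "b", "c"])
        idx = group_index(rel, labels, "g")
        expected = np.zeros(4)
        for t in ["a", "b", "c"]:
            expected += rel.loc[t].to_numpy() / rel.loc[t].mean()
        np.testing.assert_allclose(idx.to_numpy(), expected)

    def test_mean_across_samples_equals_group_size(self):
        rng = np.random.default_rng(2)
        rel = _rel(pd.DataFrame(rng.integers(1, 100, (7, 9)).astype(float),
                                index=[f"t{i}" for i in range(7)]))
        labels = pd.Series("g", index=rel.index)
        assert group_index(rel, labels, "g").mean() == pytest.approx(7.0, abs=1e-9)

    def test_additive_over_disjoint_groups(self):
        rng = np.random.default_rng(3)
        rel = _rel(pd.DataFrame(rng.integers(1, 100, (6, 5)).astype(float),
                                index=[f"t{i}" for i in range(6)]))
        labels = pd.Series(["g1"] * 3 + ["g2"] * 3, index=rel.index)
        union = pd.Series("u", index=rel.index)
        np.testing.assert_allclose(
            (group_index(rel, labels, "g1") + group_index(rel, labels, "g2")).to_numpy(),
            group_index(rel, union, "u").to_numpy())

    def test_empty_group_rejected(self):
        rel = pd.DataFrame([[0.5]], index=["a"], columns=["s"])
        with pytest.raises(ValueError, match="empty group"):
            group_index(rel, pd.Series("g", index=["a"]), "other")


class TestStrategyRatio:
    def test_equal_indices_ratio_one(self):
        a = pd.Series([2.0, 3.0], index=["s1", "s2"])
        r = strategy_ratio(a, a.copy())
        np.testing.assert_allclose(r.to_numpy(), [1.0, 1.0])

    def test_homogeneity(self):
        num = pd.Series([2.0, 4.0], index=["s1", "s2"])
        den = pd.Series([1.0, 2.0], index=["s1", "s2"])
        r1 = strategy_ratio(num, den)
        r2 = strategy_ratio(2 * num, den)
        np.testing.assert_allclose(r2.to_numpy(), 2 * r1.to_numpy())

    def test_zero_denominator_undefined(self):
        num = pd.Series([2.0], index=["s1"])
        den = pd.Series([0.0], index=["s1"])
        assert strategy_ratio(num, den).isna().all()


class TestManagementEffect:
    def setup_method(self):
        self.meta = make_toy_meta(n_regions=3, sites_per_region=5,
                                  pairs_per_field=3, timepoints=("day0", "day60"))

    def test_null_ratios_give_t_zero_p_one(self):
        ratios = pd.Series(2.0, index=self.meta.index)
        t = management_effect_test(ratios, self.meta)
        assert t.t_statistic == 0.0
        assert t.p_value == 1.0

    def test_study_design_df_is_14(self):
        rng = np.random.default_rng(4)
        ratios = pd.Series(rng.random(len(self.meta)) + 1, index=self.meta.index)
        t = management_effect_test(ratios, self.meta)
        assert t.df == 14
        assert t.n_sites == 15
        assert t.ci_low <= t.effect_size <= t.ci_high

    def test_planted_shift_detected_with_positive_t(self):
        rng = np.random.default_rng(5)
        base = pd.Series(rng.lognormal(0, 0.1, len(self.meta)), index=self.meta.index)
        shifted = base * self.meta["management"].map(
            {"intensive": 1.5, "extensive": 1.0})
        t = management_effect_test(shifted, self.meta)
        assert t.t_statistic > 0 and t.p_value < 0.05

    def test_site_relabelling_invariance(self):
        rng = np.random.default_rng(6)
        ratios = pd.Series(rng.random(len(self.meta)) + 1, index=self.meta.index)
        relabeled = self.meta.copy()
        mapping = {s: f"X{s}" for s in self.meta["site"].unique()}
        relabeled["site"] = relabeled["site"].map(mapping)
        a = management_effect_test(ratios, self.meta)
        b = management_effect_test(ratios, relabeled)
        assert a.t_statistic == pytest.approx(b.t_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_controls_only_excludes_drought_plots(self):
        ratios = pd.Series(1.0, index=self.meta.index)
        drought_idx = self.meta.index[self.meta["treatment"] == "drought"]
        ratios.loc[drought_idx] = 100.0  # should be ignored
        t = management_effect_test(ratios, self.meta, controls_only=True)
        assert t.effect_size == pytest.approx(0.0)


class TestLogResponseRatio:
    def test_equal_means_zero(self):
        assert log_response_ratio(3.3, 3.3) == pytest.approx(0.0)

    def test_e_fold_gives_one(self):
        assert log_response_ratio(np.e * 2.0, 2.0) == pytest.approx(1.0)

    def test_vector_matches_elementwise_log(self):
        rng = np.random.default_rng(7)
        i, e = rng.random(15) + 0.5, rng.random(15) + 0.5
        np.testing.assert_allclose(log_response_ratio(i, e), np.log(i / e))

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            log_response_ratio(0.0, 1.0)
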
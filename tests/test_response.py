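import itertools

import numpy as np
import pandas as pd
import pytest

from droughtstrat.response import (
    DegenerateTaxonError,
    TaxonResponseModel,
    fit_taxon_model,
    permutation_test,
    select_family,
)
from .conftest import make_toy_meta


def nb_counts(rng, mu, alpha):
    k = 1.0 / alpha
    return rng.poisson(rng.gamma(k, np.asarray(mu) / k))


@pytest.fixture(scope="module")
def design():
    """3 regions x 5 sites x 2 fields x 3 pairs, day-0 only (the study layout)."""
    meta = make_toy_meta(n_regions=3, sites_per_region=5, pairs_per_field=3)
    return meta[meta["timepoint"] == "day0"]


def simulate_counts(design, rng, base=40.0, effect=1.0, alpha=0.5, re_sd=0.3):
    fields = design["field"].unique()
    fe = pd.Series(np.exp(rng.normal(0, re_sd, len(fields))), index=fields)
    mu = base * fe[design["field"]].to_numpy()
    mu = mu * np.where(design["treatment"] == "drought", effect, 1.0)
    return pd.Series(nb_counts(rng, mu, alpha), index=design.index)


class TestFitTaxonModel:
    def test_planted_increase_detected(self, design):
        rng = np.random.default_rng(0)
        counts = simulate_counts(design, rng, effect=4.0)
        res = fit_taxon_model(counts, design)
        assert res.converged
        assert res.treatment_coefficient > 0
        assert res.p_value < 0.05
        assert res.treatment_coefficient == pytest.approx(np.log(4.0), abs=0.5)

    def test_sign_flip_on_treatment_swap(self, design):
        rng = np.random.default_rng(1)
        counts = simulate_counts(design, rng, effect=3.0)
        swapped = design.copy()
        swapped["treatment"] = swapped["treatment"].map(
            {"drought": "control", "control": "drought"})
        a = fit_taxon_model(counts, design)
        b = fit_taxon_model(counts, swapped)
        assert a.treatment_coefficient == pytest.approx(-b.treatment_coefficient,
                                                        rel=1e-6)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-6)

    def test_all_zero_taxon_raises(self, design):
        counts = pd.Series(0, index=design.index)
        with pytest.raises(DegenerateTaxonError, match="degenerate"):
            fit_taxon_model(counts, design)

    def test_summary_mentions_family_and_p(self, design):
        rng = np.random.default_rng(2)
        res = fit_taxon_model(simulate_counts(design, rng), design)
        s = res.summary()
        assert res.family in s and "p-value" in s

    def test_two_timepoints_rejected(self):
        meta = make_toy_meta(timepoints=("day0", "day60"))
        counts = pd.Series(1, index=meta.index)
        with pytest.raises(ValueError, match="single timepoint"):
            TaxonResponseModel(counts, meta)


class TestSelectFamily:
    def test_nb_data_selects_nb(self, design):
        rng = np.random.default_rng(3)
        picks = [select_family(simulate_counts(design, rng, alpha=1.0), design,
                               seed=s) for s in range(25)]
        assert picks.count("negative_binomial") >= 22

    def test_poisson_data_accepted_as_nb_nested_limit(self, design):
        rng = np.random.default_rng(4)
        fields = design["field"].unique()
        fe = pd.Series(np.exp(rng.normal(0, 0.3, len(fields))), index=fields)
        counts = pd.Series(rng.poisson(30 * fe[design["field"]].to_numpy()),
                           index=design.index)
        assert select_family(counts, design, seed=0) == "negative_binomial"

    def test_binary_counts_select_binomial(self, design):
        rng = np.random.default_rng(5)
        counts = pd.Series(rng.integers(0, 2, len(design)), index=design.index)
        assert select_family(counts, design, seed=0) == "binomial"


def brute_force_sign_flip_p(diffs):
    """Independent enumeration of the two-sided stratified sign-flip null."""
    t_obs = sum(diffs) / len(diffs)
    hits = total = 0
    for signs in itertools.product([1, -1], repeat=len(diffs)):
        t = sum(s * d for s, d in zip(signs, diffs)) / len(diffs)
        total += 1
        if abs(t) >= abs(t_obs) - 1e-12:
            hits += 1
    return hits / total


class TestPermutationTest:
    def test_constant_values_give_p_one(self, design):
        values = pd.Series(0.5, index=design.index)
        stat, p = permutation_test(values, design, n_perm=99, seed=0)
        assert stat == 0.0
        assert p == 1.0

    @pytest.mark.parametrize("n_strata", [2, 3, 5, 8])
    def test_exhaustive_matches_enumeration(self, n_strata):
        meta = make_toy_meta(n_regions=1, sites_per_region=max(1, n_strata // 2),
                             pairs_per_field=2)
        d0 = meta[meta["timepoint"] == "day0"]
        strata = d0.groupby(["field", "pair"]).groups
        keep = list(strata)[:n_strata]
        idx = [i for k in keep for i in strata[k]]
        sub = d0.loc[idx]
        rng = np.random.default_rng(n_strata)
        values = pd.Series(rng.random(len(sub)), index=sub.index)
        stat, p = permutation_test(values, sub, exhaustive=True)
        wide = sub.assign(v=values).pivot_table(
            index=["field", "pair"], columns="treatment", values="v")
        diffs = (wide["drought"] - wide["control"]).tolist()
        assert p == brute_force_sign_flip_p(diffs)
        assert stat == pytest.approx(np.mean(diffs))

    def test_monte_carlo_close_to_exhaustive(self, design):
        rng = np.random.default_rng(9)
        values = pd.Series(rng.random(len(design)), index=design.index)
        _, p_mc = permutation_test(values, design, n_perm=1999, seed=1)
        _, p_ex = permutation_test(values.iloc[:, ], design, n_perm=99999, seed=2)
        assert abs(p_mc - p_ex) < 0.05

    def test_stratum_uniform_rescaling_invariance(self, design):
        # the statistic uses relative abundances; a uniform within-stratum
        # positive rescale changes T but not the permutation distribution's tail
        rng = np.random.default_rng(10)
        values = pd.Series(rng.random(len(design)), index=design.index)
        _, p1 = permutation_test(values, design, n_perm=999, seed=3)
        scale = design.groupby(["field", "pair"]).ngroup().map(
            lambda g: 1.0 + 0.0 * g)  # global scale keeps exact invariance
        _, p2 = permutation_test(values * 2.0, design, n_perm=999, seed=3)
        assert p1 == p2

    def test_no_strata_raises(self, design):
        only_drought = design[design["treatment"] == "drought"]
        values = pd.Series(1.0, index=only_drought.index)
        with pytest.raises(ValueError):
            permutation_test(values, only_drought, n_perm=99, seed=0)

    def test_null_pvalues_roughly_uniform(self, design):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            values = pd.Series(rng.random(len(design)), index=design.index)
            ps.append(permutation_test(values, design, n_perm=199, seed=0)[1])
        assert 0.02 < np.mean(np.array(ps) < 0.05) < 0.09
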
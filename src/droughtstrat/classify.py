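"""Strategy (resistant / opportunistic / sensitive) and resilience labelling.

Day-0 rule at significance level alpha: opportunistic iff p < alpha and the
drought coefficient is positive; sensitive iff p < alpha and negative;
resistant otherwise. Resistant taxa are not tested for resilience; for the
rest, the drought-vs-control contrast is re-fit on the day-60 samples (family
re-selected) and the taxon is resilient iff that test is non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable, relative_abundance
from .response import (
    DegenerateTaxonError,
    TaxonResponseModel,
    TaxonResponseResults,
    permutation_test,
)

STRATEGIES = ("resistant", "opportunistic", "sensitive")
RESILIENCE = ("resilient", "not_resilient", "not_tested")


@dataclass
class StrategyLabel:
    taxon_id: str
    label: str
    source_fit: TaxonResponseResults | None = None


@dataclass
class ResilienceLabel:
    taxon_id: str
    label: str
    source_fit: TaxonResponseResults | None = None


def classify_strategy(fit: TaxonResponseResults, alpha: float = 0.05) -> StrategyLabel:
    """Map a fitted day-0 drought contrast to a strategy label."""
    p, coef = fit.p_value, fit.treatment_coefficient
    if not np.isfinite(p):
        raise ValueError(f"taxon {fit.taxon_id!r}: no p-value (fit did not converge; "
                         "use the permutation fallback)")
    if p < alpha and coef > 0:
        label = "opportunistic"
    elif p < alpha and coef < 0:
        label = "sensitive"
    else:
        label = "resistant"
    return StrategyLabel(fit.taxon_id, label, fit)


def classify_resilience(fit_day60: TaxonResponseResults | None,
                        prior: StrategyLabel, alpha: float = 0.05) -> ResilienceLabel:
    """Resilience rule: resistant taxa are not tested; otherwise the taxon is
    resilient iff the day-60 drought contrast is non-significant (p >= alpha)."""
    if prior.label == "resistant":
        return ResilienceLabel(prior.taxon_id, "not_tested", None)
    if fit_day60 is None:
        raise ValueError(f"taxon {prior.taxon_id!r}: day-60 fit required for "
                         "resilience classification")
    p = fit_day60.p_value
    if not np.isfinite(p):
        raise ValueError(f"taxon {prior.taxon_id!r}: day-60 fit has no p-value")
    label = "resilient" if p >= alpha else "not_resilient"
    return ResilienceLabel(prior.taxon_id, label, fit_day60)


def _test_one(counts, design, rel, depth, engine, alpha, n_perm, seed, taxon_id):
    """One drought-vs-control test; returns (family, coef, p, engine, converged)."""
    if engine == "permutation":
        stat, p = permutation_test(rel, design, n_perm=n_perm, seed=seed)
        return "permutation", stat, p, "permutation", True
    try:
        res = TaxonResponseModel(counts, design, library_size=depth,
                                 taxon_id=taxon_id, seed=seed).fit()
    except DegenerateTaxonError:
        raise
    if res.converged and np.isfinite(res.p_value):
        return res.family, res.treatment_coefficient, res.p_value, "model", True
    # non-convergence: design-respecting permutation fallback
    stat, p = permutation_test(rel, design, n_perm=n_perm, seed=seed)
    return res.family, stat, p, "permutation_fallback", False


def classify_taxa(table: OtuTable, meta: pd.DataFrame, taxon_ids=None,
                  alpha: float = 0.05, engine: str = "model",
                  n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Classify taxa at day 0 and re-test non-resistant taxa at day 60.

    Parameters
    ----------
    table : OtuTable
        Rarefied counts covering both timepoints.
    meta : pandas.DataFrame
        Validated metadata for the table's samples.
    taxon_ids : sequence, optional
        Taxa to classify (typically the dominant set); default all taxa with
        nonzero reads.
    engine : {"model", "permutation"}
        Model-based tests (with permutation fallback on non-convergence) or
        pure stratified permutation tests.

    Returns
    -------
    pandas.DataFrame
        One row per taxon: taxon_id, family, coefficient, p_value, strategy,
        family_day60, coefficient_day60, p_value_day60, resilience, engine,
        converged.
    """
    if engine not in ("model", "permutation"):
        raise ValueError("engine must be 'model' or 'permutation'")
    meta = meta.loc[table.sample_ids]
    if taxon_ids is None:
        totals = table.counts.sum(axis=1)
        taxon_ids = totals.index[totals > 0].tolist()
    rel = relative_abundance(table)
    depth = table.rarefaction_depth
    lib = depth if depth is not None else table.counts.sum(axis=0)
    designs = {tp: meta[meta["timepoint"] == tp] for tp in ("day0", "day60")}
    rows = []
    rng = np.random.default_rng(seed)
    for taxon in taxon_ids:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        counts0 = table.counts.loc[taxon, designs["day0"].index]
        rel0 = rel.loc[taxon, designs["day0"].index]
        try:
            fam, coef, p, eng, conv = _test_one(
                counts0, designs["day0"], rel0, lib, engine, alpha, n_perm,
                sub_seed, taxon)
        except DegenerateTaxonError:
            continue  # no day-0 reads: untestable, excluded from the output
        if p < alpha and coef > 0:
            strategy = "opportunistic"
        elif p < alpha and coef < 0:
            strategy = "sensitive"
        else:
            strategy = "resistant"
        if strategy == "resistant":
            fam60 = coef60 = p60 = np.nan
            resilience = "not_tested"
        else:
            counts60 = table.counts.loc[taxon, designs["day60"].index]
            rel60 = rel.loc[taxon, designs["day60"].index]
            try:
                fam60, coef60, p60, _, _ = _test_one(
                    counts60, designs["day60"], rel60, lib, engine, alpha,
                    n_perm, sub_seed + 1, taxon)
            except DegenerateTaxonError:
                # vanished entirely at day 60: clearly not recovered
                fam60, coef60, p60 = "degenerate", np.nan, 0.0
            resilience = "resilient" if p60 >= alpha else "not_resilient"
        rows.append((taxon, fam, coef, p, strategy, fam60, coef60, p60,
                     resilience, eng, conv))
    return pd.DataFrame(rows, columns=[
        "taxon_id", "family", "coefficient", "p_value", "strategy",
        "family_day60", "coefficient_day60", "p_value_day60", "resilience",
        "engine", "converged"]).set_index("taxon_id", drop=False)
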
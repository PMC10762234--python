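"""Group-level standardized indices, strategy ratios, and management tests.

The group index for a set of taxa sharing a label is, per sample, the sum of
each member taxon's relative abundance divided by that taxon's mean relative
abundance across all samples (mean-1 standardization, so every taxon enters on
a common scale and the index mean across samples equals the group size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

RATIO_TYPES = {
    "opportunistic_sensitive": ("opportunistic", "sensitive"),
    "resilient_not_resilient": ("resilient", "not_resilient"),
}

STANDARDIZERS = ("mean_division", "z_score", "max_division")


@dataclass
class ManagementTest:
    """Paired-site test of the intensive-vs-extensive management contrast."""

    ratio_type: str
    t_statistic: float
    df: int
    p_value: float
    effect_size: float
    ci_low: float
    ci_high: float
    n_sites: int
    n_undefined_ratios: int = 0

    def summary(self) -> str:
        return (
            f"Management effect on {self.ratio_type} ratio (paired across sites)\n"
            f"  t({self.df}) = {self.t_statistic:.2f}, P = {self.p_value:.4g}\n"
            f"  effect size = {self.effect_size:.3f}, "
            f"95% CI = [{self.ci_low:.3f}, {self.ci_high:.3f}]  (n_sites = {self.n_sites})"
        )


def standardize_taxon(rel_abund: pd.Series | np.ndarray,
                      method: str = "mean_division") -> np.ndarray:
    """Standardize one taxon's per-sample relative abundances across samples.

    ``mean_division`` (default): divide by the across-sample mean, so the
    output has mean exactly 1. ``z_score`` and ``max_division`` are provided as
    alternatives.
    """
    x = np.asarray(rel_abund, dtype=float)
    if method == "mean_division":
        m = x.mean()
        if m <= 0:
            raise ValueError("cannot standardize an all-zero taxon")
        return x / m
    if method == "z_score":
        s = x.std(ddof=1)
        if s == 0:
            raise ValueError("cannot z-score a constant taxon")
        return (x - x.mean()) / s
    if method == "max_division":
        mx = x.max()
        if mx <= 0:
            raise ValueError("cannot standardize an all-zero taxon")
        return x / mx
    raise ValueError(f"unknown standardizer {method!r}; use one of {STANDARDIZERS}")


def group_index(rel_table: pd.DataFrame, labels: pd.Series, group: str,
                method: str = "mean_division") -> pd.Series:
    """Per-sample sum of standardized relative abundances over a label group.

    Parameters
    ----------
    rel_table : DataFrame
        Relative abundances, taxa x samples.
    labels : Series
        taxon_id -> label; taxa whose label equals ``group`` are summed.
        All-zero member taxa are excluded (they cannot be standardized).
    """
    members = labels.index[labels == group]
    members = [t for t in members if t in rel_table.index]
    if not members:
        raise ValueError(f"empty group {group!r}")
    sub = rel_table.loc[members]
    nz = sub.sum(axis=1) > 0
    sub = sub.loc[nz]
    if sub.empty:
        raise ValueError(f"group {group!r} has only all-zero taxa")
    std = np.vstack([standardize_taxon(sub.loc[t], method) for t in sub.index])
    return pd.Series(std.sum(axis=0), index=rel_table.columns, name=group)


def strategy_ratio(index_num: pd.Series, index_den: pd.Series,
                   ratio_type: str = "opportunistic_sensitive") -> pd.Series:
    """Per-sample numerator/denominator index ratio; NaN where denominator is 0."""
    if ratio_type not in RATIO_TYPES:
        raise ValueError(f"ratio_type must be one of {sorted(RATIO_TYPES)}")
    den = index_den.reindex(index_num.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = index_num / den.where(den > 0)
    r.name = ratio_type
    return r


def group_index_table(rel_table: pd.DataFrame, labels_df: pd.DataFrame,
                      method: str = "mean_division") -> pd.DataFrame:
    """Long-format table of indices for every available strategy/resilience group."""
    rows = []
    for col, groups in (("strategy", ("resistant", "opportunistic", "sensitive")),
                        ("resilience", ("resilient", "not_resilient"))):
        lab = labels_df.set_index("taxon_id")[col] if "taxon_id" in labels_df else labels_df[col]
        for g in groups:
            if (lab == g).any():
                idx = group_index(rel_table, lab, g, method)
                for s, v in idx.items():
                    rows.append((s, g, v))
    return pd.DataFrame(rows, columns=["sample_id", "group", "index_value"])


def management_effect_test(ratios: pd.Series, meta: pd.DataFrame,
                           ratio_type: str = "opportunistic_sensitive",
                           controls_only: bool = True) -> ManagementTest:
    """Paired-site t-test of the management effect on a strategy ratio.

    Ratios are restricted to control plots (both timepoints) by default,
    averaged to the field level, and each site's intensive-minus-extensive
    field contrast is formed; the mean contrast is tested with a one-sample
    t-test (df = n_sites - 1). Samples with undefined (NaN) ratios are
    excluded and counted; sites missing one management are dropped with a
    warning.
    """
    df = meta.copy()
    df["ratio"] = ratios.reindex(meta.index).to_numpy()
    if controls_only:
        df = df[df["treatment"] == "control"]
    n_undef = int(df["ratio"].isna().sum())
    df = df.dropna(subset=["ratio"])
    field_means = df.groupby(["site", "management", "field"])["ratio"].mean()
    site_mgmt = field_means.groupby(["site", "management"]).mean().unstack("management")
    for m in ("intensive", "extensive"):
        if m not in site_mgmt.columns:
            site_mgmt[m] = np.nan
    incomplete = site_mgmt.index[site_mgmt.isna().any(axis=1)]
    if len(incomplete):
        import warnings
        warnings.warn(f"sites missing one management excluded: {list(incomplete)}")
    site_mgmt = site_mgmt.dropna()
    contrasts = (site_mgmt["intensive"] - site_mgmt["extensive"]).to_numpy()
    n = len(contrasts)
    if n < 2:
        raise ValueError("need >= 2 complete sites for the paired test")
    mean = contrasts.mean()
    se = contrasts.std(ddof=1) / np.sqrt(n)
    dfree = n - 1
    if se == 0:
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
        ci = (mean, mean)
    else:
        t = mean / se
        p = float(2 * scipy.stats.t.sf(abs(t), dfree))
        half = scipy.stats.t.ppf(0.975, dfree) * se
        ci = (mean - half, mean + half)
    return ManagementTest(ratio_type, float(t), int(dfree), p, float(mean),
                          float(ci[0]), float(ci[1]), n, n_undef)


def log_response_ratio(intensive_field_mean, extensive_field_mean):
    """Natural log of (intensive-field mean / paired extensive-field mean).

    Accepts scalars or aligned arrays; both means must be strictly positive.
    """
    i = np.asarray(intensive_field_mean, dtype=float)
    e = np.asarray(extensive_field_mean, dtype=float)
    if (i <= 0).any() or (e <= 0).any():
        raise ValueError("log response ratio requires strictly positive means")
    out = np.log(i / e)
    return float(out) if out.ndim == 0 else out
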
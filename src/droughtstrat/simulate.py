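"""Synthetic community generator emulating the nested grassland drought design.

The generator reproduces the study layout — 3 regions x 5 sites x 2 fields per
site (one intensive, one extensive) x 3 drought/control plot pairs per field x
2 timepoints (180 samples per timepoint) — and plants known per-taxon drought
responses: multiplicative fold-changes on expected relative abundances under
drought at day 0, persisting at day 60 for not-resilient taxa. Counts are
negative binomial around depth x expected proportion with configurable
dispersion, plus lognormal site- and field-level random effects, so the data
match the assumptions of the classification models while carrying a known
ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import OtuTable, validate_metadata, write_otu_table, write_metadata


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Strategy proportions default to the dominant-bacteria split reported for
    this design (66% resistant, 19% opportunistic, 12% sensitive, renormalized);
    78% of affected taxa are resilient. Effect sizes are fold-changes on
    expected relative abundance: 4.0 for opportunistic and 0.25 for sensitive
    taxa at day 0; not-resilient taxa keep a persistent fold-change of the same
    direction at day 60. ``dispersion`` is the NB2 alpha (var = mu + alpha mu^2).
    """

    n_regions: int = 3
    sites_per_region: int = 5
    fields_per_site: int = 2  # one intensive, one extensive
    pairs_per_field: int = 3
    depth: int = 9000
    n_taxa: int = 300
    fraction_dominant_pool: float = 0.25
    strategy_mix: tuple = (0.68, 0.20, 0.12)  # resistant, opportunistic, sensitive
    resilient_fraction: float = 0.78
    effect_multiplier_day0_opportunistic: float = 4.0
    effect_multiplier_day0_sensitive: float = 0.25
    effect_multiplier_day60_not_resilient: float = 4.0
    dispersion: float = 0.5
    random_effect_sd: float = 0.3
    management_shift: dict = field(default_factory=dict)  # group -> multiplier in intensive
    dominant_pool_boost: float = 20.0
    rank_abundance_sd: float = 1.2
    depth_margin: float = 2.0  # simulated sequencing depth = margin * depth

    def validate(self) -> None:
        if abs(sum(self.strategy_mix) - 1.0) > 1e-9:
            raise ValueError("strategy_mix must sum to 1")
        if min(self.strategy_mix) < 0:
            raise ValueError("strategy_mix proportions must be non-negative")
        for name in ("effect_multiplier_day0_opportunistic",
                     "effect_multiplier_day0_sensitive",
                     "effect_multiplier_day60_not_resilient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(v <= 0 for v in self.management_shift.values()):
            raise ValueError("management_shift multipliers must be > 0")
        for name in ("n_regions", "sites_per_region", "fields_per_site",
                     "pairs_per_field", "depth", "n_taxa"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.resilient_fraction <= 1):
            raise ValueError("resilient_fraction must be in [0, 1]")
        if self.dispersion < 0 or self.random_effect_sd < 0:
            raise ValueError("dispersion and random_effect_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted per-taxon ground truth.

    ``table`` has one row per taxon: baseline (expected relative abundance in
    extensive control fields), strategy, resilience (``not_tested`` for
    resistant taxa), and the multipliers actually applied at each timepoint.
    """

    table: pd.DataFrame

    @property
    def strategy(self) -> pd.Series:
        return self.table["strategy"]

    @property
    def resilience(self) -> pd.Series:
        return self.table["resilience"]


def _build_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    mgmts = ["intensive", "extensive"][: cfg.fields_per_site]
    rows = []
    for r in range(1, cfg.n_regions + 1):
        region = f"R{r}"
        for s in range(1, cfg.sites_per_region + 1):
            site = f"{region}s{s}"
            for mgmt in mgmts:
                fld = f"{site}_{mgmt[:3]}"
                for p in range(1, cfg.pairs_per_field + 1):
                    pair = f"{fld}_P{p}"
                    for tp in ("day0", "day60"):
                        for trt in ("drought", "control"):
                            sid = f"{pair}_{trt}_{tp}"
                            rows.append((sid, region, site, fld, mgmt, pair, trt, tp))
    meta = pd.DataFrame(rows, columns=[
        "sample_id", "region", "site", "field", "management", "pair",
        "treatment", "timepoint"])
    return validate_metadata(meta)


def simulate_experiment(config: SimulationConfig, seed: int
                        ) -> tuple[OtuTable, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic experiment; deterministic given config and seed.

    Returns the (unrarefied) count table, validated metadata, and the planted
    truth. Simulated totals average ``depth_margin * depth`` reads so that
    rarefying to ``depth`` retains every sample in practice.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    meta = _build_metadata(config)
    n_taxa = config.n_taxa
    taxa = [f"OTU{i + 1:05d}" for i in range(n_taxa)]

    # lognormal rank-abundance baseline; a dominant pool gets boosted means
    log_b = rng.normal(0.0, config.rank_abundance_sd, size=n_taxa)
    n_dom = int(round(config.fraction_dominant_pool * n_taxa))
    dom_pool = np.zeros(n_taxa, dtype=bool)
    dom_pool[rng.choice(n_taxa, size=n_dom, replace=False)] = True
    b = np.exp(log_b) * np.where(dom_pool, config.dominant_pool_boost, 1.0)
    b /= b.sum()

    # planted strategies and resilience
    strategies = rng.choice(
        ["resistant", "opportunistic", "sensitive"], size=n_taxa,
        p=np.asarray(config.strategy_mix, dtype=float))
    affected = strategies != "resistant"
    resilient = rng.random(n_taxa) < config.resilient_fraction
    resilience = np.where(
        ~affected, "not_tested", np.where(resilient, "resilient", "not_resilient"))

    mult0 = np.ones(n_taxa)
    mult0[strategies == "opportunistic"] = config.effect_multiplier_day0_opportunistic
    mult0[strategies == "sensitive"] = config.effect_multiplier_day0_sensitive
    m60 = config.effect_multiplier_day60_not_resilient
    mult60 = np.ones(n_taxa)
    nr = resilience == "not_resilient"
    mult60[nr & (strategies == "opportunistic")] = m60
    mult60[nr & (strategies == "sensitive")] = 1.0 / m60

    mgmt_shift = np.ones(n_taxa)
    for group, m in config.management_shift.items():
        mgmt_shift[strategies == group] = m

    # site- and field-level lognormal random effects, per taxon
    sites = meta["site"].unique()
    fields = meta["field"].unique()
    site_eff = pd.DataFrame(
        rng.normal(0.0, config.random_effect_sd, size=(n_taxa, len(sites))),
        index=taxa, columns=sites)
    field_eff = pd.DataFrame(
        rng.normal(0.0, config.random_effect_sd, size=(n_taxa, len(fields))),
        index=taxa, columns=fields)

    sim_depth = config.depth_margin * config.depth
    counts = np.empty((n_taxa, len(meta)), dtype=np.int64)
    for j, (sid, row) in enumerate(meta.iterrows()):
        lam = b * np.exp(site_eff[row["site"]].to_numpy()
                         + field_eff[row["field"]].to_numpy())
        if row["management"] == "intensive":
            lam = lam * mgmt_shift
        if row["treatment"] == "drought":
            lam = lam * (mult0 if row["timepoint"] == "day0" else mult60)
        p = lam / lam.sum()
        mu = sim_depth * p
        if config.dispersion > 0:
            k = 1.0 / config.dispersion
            mu = rng.gamma(k, mu / k)
        counts[:, j] = rng.poisson(mu)

    table = OtuTable(pd.DataFrame(counts, index=taxa, columns=list(meta.index)))
    truth = SyntheticTruth(pd.DataFrame({
        "taxon_id": taxa,
        "baseline": b,
        "dominant_pool": dom_pool,
        "strategy": strategies,
        "resilience": resilience,
        "multiplier_day0": mult0,
        "multiplier_day60": mult60,
    }).set_index("taxon_id", drop=False))
    return table, meta, truth


def null_config(**overrides) -> SimulationConfig:
    """A configuration with every drought multiplier equal to 1 (pure null)."""
    base = dict(strategy_mix=(1.0, 0.0, 0.0))
    base.update(overrides)
    return SimulationConfig(**base)


def write_fixture(bundle: tuple, out_dir) -> dict[str, Path]:
    """Write (table, metadata, truth) as TSVs that round-trip through the readers."""
    table, meta, truth = bundle
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu": out / "otu_table.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
    }
    write_otu_table(table, paths["otu"])
    write_metadata(meta, paths["metadata"])
    truth.table.reset_index(drop=True).to_csv(paths["truth"], sep="\t", index=False)
    return paths
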
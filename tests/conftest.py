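import numpy as np
import pandas as pd
import pytest

from droughtstrat.io import OtuTable, validate_metadata, rarefy
from droughtstrat.simulate import SimulationConfig, simulate_experiment


def make_toy_meta(n_regions=1, sites_per_region=3, pairs_per_field=1,
                  timepoints=("day0",)):
    """Small hand-buildable design (both managements per site, paired plots)."""
    rows = []
    for r in range(1, n_regions + 1):
        region = f"R{r}"
        for s in range(1, sites_per_region + 1):
            site = f"{region}s{s}"
            for mgmt in ("intensive", "extensive"):
                fld = f"{site}_{mgmt[:3]}"
                for p in range(1, pairs_per_field + 1):
                    pair = f"{fld}_P{p}"
                    for tp in timepoints:
                        for trt in ("drought", "control"):
                            rows.append((f"{pair}_{trt}_{tp}", region, site, fld,
                                         mgmt, pair, trt, tp))
    meta = pd.DataFrame(rows, columns=[
        "sample_id", "region", "site", "field", "management", "pair",
        "treatment", "timepoint"])
    return validate_metadata(meta)


def make_toy_table(meta, n_taxa, seed, depth=200):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, depth, size=(n_taxa, len(meta)))
    taxa = [f"T{i:03d}" for i in range(n_taxa)]
    return OtuTable(pd.DataFrame(counts, index=taxa, columns=meta.index))


@pytest.fixture(scope="session")
def toy_meta():
    return make_toy_meta()


@pytest.fixture(scope="session")
def default_bundle():
    """One default-configuration synthetic experiment, shared across tests."""
    cfg = SimulationConfig(n_taxa=300)
    return simulate_experiment(cfg, seed=42)


@pytest.fixture(scope="session")
def default_rarefied(default_bundle):
    table, meta, truth = default_bundle
    rare, dropped = rarefy(table, 9000, seed=43)
    return rare, meta.loc[rare.sample_ids], truth
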
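"""Dominant-taxon screening by joint occupancy and abundance-rank criteria.

A taxon is dominant when it (a) is present (>= 1 read, any sample) in every
occupancy unit — sites for bacteria, regions for fungi — and (b) falls in the
top ``quantile`` (default 10%) of taxa ranked by relative abundance summed over
all samples. The two filters are applied as a set intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable, relative_abundance

OCCUPANCY_LEVELS = ("site", "region")


@dataclass
class DominanceResult:
    """Outcome of the dominance screen.

    Attributes
    ----------
    dominant_taxon_ids : list of str
        Taxa passing both filters, in rank order (most abundant first).
    occupancy_per_taxon : pandas.Series
        Number of occupancy units each taxon is present in.
    rank_share_per_taxon : pandas.Series
        Relative abundance summed over samples, per taxon.
    rank_filter_ids : list of str
        Taxa passing the abundance-rank filter alone.
    occupancy_filter_ids : list of str
        Taxa passing the full-occupancy filter alone.
    n_total_taxa : int
        Number of taxa considered (nonzero total reads).
    reads_share_of_dominants : float
        Fraction of all reads carried by the dominant set.
    occupancy_level : str
    quantile : float
    """

    dominant_taxon_ids: list
    occupancy_per_taxon: pd.Series
    rank_share_per_taxon: pd.Series
    rank_filter_ids: list
    occupancy_filter_ids: list
    n_total_taxa: int
    reads_share_of_dominants: float
    occupancy_level: str
    quantile: float


def occupancy(table: OtuTable, meta: pd.DataFrame, level: str = "site") -> pd.Series:
    """Number of occupancy units (sites or regions) in which each taxon has >= 1 read.

    Presence is assessed over all samples of a unit, pooling fields, pairs,
    treatments and timepoints.
    """
    if level not in OCCUPANCY_LEVELS:
        raise ValueError(f"level must be one of {OCCUPANCY_LEVELS}")
    unknown = [s for s in table.sample_ids if s not in meta.index]
    if unknown:
        raise KeyError(f"samples missing from metadata: {unknown[:5]}")
    unit = meta.loc[table.sample_ids, level]
    present = table.counts.to_numpy() > 0
    occ = np.zeros(table.n_taxa, dtype=np.int64)
    for _, cols in pd.Series(range(table.n_samples), index=unit.values).groupby(level=0):
        occ += present[:, cols.to_numpy()].any(axis=1)
    return pd.Series(occ, index=table.counts.index, name="occupancy")


def select_dominant(
    table: OtuTable,
    meta: pd.DataFrame,
    level: str = "site",
    quantile: float = 0.10,
) -> DominanceResult:
    """Apply the occupancy-and-abundance dominance screen.

    Taxa with nonzero total reads are ranked by relative abundance summed over
    all samples (descending; ties broken by taxon id); the top
    ``floor(quantile * n_ranked)`` taxa are intersected with the set of taxa
    present in every occupancy unit.
    """
    if not (0 < quantile <= 1):
        raise ValueError("quantile must be in (0, 1]")
    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValueError("empty table")
    occ = occupancy(table, meta, level)
    n_units = meta.loc[table.sample_ids, level].nunique()
    full_occ = occ.index[occ == n_units].tolist()

    rel = relative_abundance(table)
    share = rel.sum(axis=1)
    totals = table.counts.sum(axis=1)
    ranked = share[totals > 0]
    n_ranked = len(ranked)
    n_top = int(np.floor(quantile * n_ranked))
    # sort by share descending, then lexicographic id for deterministic ties
    order = ranked.to_frame("share").reset_index(names="taxon")
    order = order.sort_values(["share", "taxon"], ascending=[False, True])
    top_ids = order["taxon"].head(n_top).tolist()

    full_set = set(full_occ)
    dominant = [t for t in top_ids if t in full_set]
    dom_reads = int(totals.loc[dominant].sum()) if dominant else 0
    total_reads = int(totals.sum())
    return DominanceResult(
        dominant_taxon_ids=dominant,
        occupancy_per_taxon=occ,
        rank_share_per_taxon=share,
        rank_filter_ids=top_ids,
        occupancy_filter_ids=full_occ,
        n_total_taxa=n_ranked,
        reads_share_of_dominants=dom_reads / total_reads if total_reads else 0.0,
        occupancy_level=level,
        quantile=quantile,
    )


def dominance_table(result: DominanceResult) -> pd.DataFrame:
    """Tabular view: taxon_id, occupancy, rank_share, is_dominant."""
    dom = set(result.dominant_taxon_ids)
    return pd.DataFrame(
        {
            "taxon_id": result.occupancy_per_taxon.index,
            "occupancy": result.occupancy_per_taxon.values,
            "rank_share": result.rank_share_per_taxon.reindex(
                result.occupancy_per_taxon.index
            ).values,
            "is_dominant": [t in dom for t in result.occupancy_per_taxon.index],
        }
    )
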
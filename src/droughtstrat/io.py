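"""Count-table and metadata containers, readers/writers, rarefaction, relative abundance.

The count matrix is held taxa x samples in a pandas DataFrame (integer dtype,
index = taxon ids, columns = sample ids). Sample metadata is a DataFrame indexed
by sample id carrying the nested design factors
(region / site / field / management / pair / treatment / timepoint).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

METADATA_COLUMNS = [
    "sample_id",
    "region",
    "site",
    "field",
    "management",
    "pair",
    "treatment",
    "timepoint",
]

TREATMENTS = ("drought", "control")
TIMEPOINTS = ("day0", "day60")
MANAGEMENTS = ("intensive", "extensive")


class OtuParseError(ValueError):
    """Malformed count-table input (bad header, non-integer cell, duplicate id)."""


class MetadataError(ValueError):
    """Metadata violates the design contract (missing column, broken nesting, unpaired plot)."""


@dataclass
class OtuTable:
    """Taxa x samples integer count matrix with stable identifiers.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix; index = taxon ids, columns = sample ids.
    rarefaction_depth : int, optional
        If set, every sample column must sum to exactly this many reads.
    """

    counts: pd.DataFrame
    rarefaction_depth: int | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].tolist()
            raise OtuParseError(f"duplicate taxon ids: {dups[:5]}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].tolist()
            raise OtuParseError(f"duplicate sample ids: {dups[:5]}")
        if len(c.columns) and not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            bad = c.columns[(c != c.round()).any(axis=0)]
            raise OtuParseError(f"counts must be integers (check columns {list(bad)[:5]})")
        if (c.to_numpy() < 0).any():
            r, s = np.argwhere(c.to_numpy() < 0)[0]
            raise OtuParseError(
                f"negative count at taxon {c.index[r]!r}, sample {c.columns[s]!r}"
            )
        if self.rarefaction_depth is not None:
            sums = c.sum(axis=0)
            off = sums[sums != self.rarefaction_depth]
            if len(off):
                raise OtuParseError(
                    f"rarefaction_depth={self.rarefaction_depth} but sample "
                    f"{off.index[0]!r} sums to {off.iloc[0]}"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts[list(sample_ids)], self.rarefaction_depth)


def read_otu_table(path, format_dialect: str = "tsv_taxa_rows") -> OtuTable:
    """Read a tab-separated OTU count table.

    ``tsv_taxa_rows``: header line ``#OTU_ID<TAB>sample...``, one taxon per row.
    ``biom_tsv``: the classic BIOM TSV export, identical except for a leading
    ``# Constructed from biom file`` comment line.
    """
    if format_dialect not in ("tsv_taxa_rows", "biom_tsv"):
        raise ValueError(f"unknown format_dialect {format_dialect!r}")
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if format_dialect == "biom_tsv" and first.startswith("# "):
            first = fh.readline()
        header = first.rstrip("\n").split("\t")
        if not header or header[0] not in ("#OTU_ID", "#OTU ID", "OTU_ID"):
            raise OtuParseError(
                f"{path}: expected first header column '#OTU_ID', got {header[0]!r}"
            )
        sample_ids = header[1:]
        taxa, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise OtuParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
                )
            taxa.append(parts[0])
            row = []
            for sid, cell in zip(sample_ids, parts[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    # tolerate "12.0"-style exports, reject true non-integers
                    fv = float(cell)
                    if fv != int(fv):
                        raise OtuParseError(
                            f"{path}:{lineno}: non-integer count {cell!r} "
                            f"(taxon {parts[0]!r}, sample {sid!r})"
                        ) from None
                    v = int(fv)
                if v < 0:
                    raise OtuParseError(
                        f"{path}:{lineno}: negative count {v} "
                        f"(taxon {parts[0]!r}, sample {sid!r})"
                    )
                row.append(v)
            rows.append(row)
    counts = pd.DataFrame(rows, index=taxa, columns=sample_ids, dtype=np.int64)
    return OtuTable(counts)


def write_otu_table(table: OtuTable, path, format_dialect: str = "tsv_taxa_rows") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if format_dialect == "biom_tsv":
            fh.write("# Constructed from biom file\n")
        fh.write("#OTU_ID\t" + "\t".join(table.sample_ids) + "\n")
        for taxon, row in zip(table.taxon_ids, table.counts.to_numpy()):
            fh.write(taxon + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_taxonomy(path) -> pd.Series:
    """Read an ``otu_id<TAB>lineage`` taxonomy TSV into a Series (index = otu id)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"], dtype=str)
    return df.set_index("otu_id")["lineage"]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate design-factor nesting and drought/control pairing.

    Checks: required columns; factor levels; each site under exactly one region
    and each field under exactly one site; (field, pair, timepoint, treatment)
    unique; every drought sample has a control partner in the same
    (field, pair, timepoint) cell.
    """
    if meta.index.name == "sample_id":
        meta = meta.reset_index(drop="sample_id" in meta.columns)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise MetadataError(f"metadata missing columns: {missing}")
    meta = meta[METADATA_COLUMNS].astype(str)
    if meta["sample_id"].duplicated().any():
        d = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise MetadataError(f"duplicate sample_id {d!r}")
    for col, levels in (
        ("treatment", TREATMENTS),
        ("timepoint", TIMEPOINTS),
        ("management", MANAGEMENTS),
    ):
        bad = set(meta[col]) - set(levels)
        if bad:
            raise MetadataError(f"{col} has invalid levels {sorted(bad)}; allowed {levels}")
    for child, parent in (("site", "region"), ("field", "site"), ("pair", "field")):
        n_parents = meta.groupby(child)[parent].nunique()
        broken = n_parents[n_parents > 1]
        if len(broken):
            raise MetadataError(
                f"{child} {broken.index[0]!r} appears under multiple {parent}s"
            )
    key = ["field", "pair", "timepoint", "treatment"]
    dup = meta.duplicated(subset=key)
    if dup.any():
        raise MetadataError(
            f"(field, pair, timepoint, treatment) not unique: {meta.loc[dup, key].iloc[0].tolist()}"
        )
    cells = meta.pivot_table(
        index=["field", "pair", "timepoint"], columns="treatment",
        values="sample_id", aggfunc="first",
    )
    for trt in TREATMENTS:
        if trt not in cells.columns:
            cells[trt] = np.nan
    unpaired = cells[cells["drought"].notna() & cells["control"].isna()]
    if len(unpaired):
        raise MetadataError(
            f"drought sample {unpaired['drought'].iloc[0]!r} has no control partner "
            f"in (field, pair, timepoint) = {unpaired.index[0]}"
        )
    return meta.set_index("sample_id", drop=False)


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV (see :data:`METADATA_COLUMNS`)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def rarefy(table: OtuTable, depth: int, seed: int) -> tuple[OtuTable, dict[str, int]]:
    """Subsample each sample column to exactly ``depth`` reads without replacement.

    Samples whose total read count is below ``depth`` are dropped and reported.
    Deterministic given ``seed`` (multivariate hypergeometric draw per sample).

    Returns
    -------
    (OtuTable, dict)
        The rarefied table (``rarefaction_depth`` set) and a ``{sample_id:
        total_reads}`` report of dropped samples.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=0)
    dropped = {s: int(t) for s, t in totals.items() if t < depth}
    kept = [s for s in table.sample_ids if s not in dropped]
    out = np.empty((table.n_taxa, len(kept)), dtype=np.int64)
    for j, s in enumerate(kept):
        col = counts[s].to_numpy()
        if totals[s] == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    rare = pd.DataFrame(out, index=counts.index, columns=kept)
    return OtuTable(rare, rarefaction_depth=depth), dropped


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Column-wise proportions (counts / column sum); all-zero columns stay zero."""
    c = table.counts.to_numpy(dtype=float)
    sums = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(sums > 0, c / np.where(sums > 0, sums, 1.0), 0.0)
    return pd.DataFrame(rel, index=table.counts.index, columns=table.counts.columns)
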
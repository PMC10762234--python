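"""End-to-end orchestration: rarefy -> dominance -> classify -> indices -> tests.

`run_pipeline` executes the full analysis on a count table + metadata pair and
returns a result bundle (labels, indices, management tests, manifest). Each
stage failure is re-raised with the stage name for context.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .io import OtuTable, read_otu_table, read_metadata, rarefy, relative_abundance
from .dominance import select_dominant, dominance_table
from .classify import classify_taxa
from .indices import (
    RATIO_TYPES,
    group_index,
    strategy_ratio,
    management_effect_test,
)

_version = "0.1.0"


@dataclass
class PipelineConfig:
    """Single source of parameters for a pipeline run."""

    rarefaction_depth: int = 9000
    occupancy_level: str = "site"
    dominance_quantile: float = 0.10
    alpha: float = 0.05
    engine: str = "model"
    n_perm: int = 999
    seed: int = 0
    standardizer: str = "mean_division"
    skip_rarefaction: bool = False


@dataclass
class PipelineResult:
    """Bundle of all stage outputs plus the run manifest."""

    table: OtuTable
    dominance: pd.DataFrame
    labels: pd.DataFrame
    indices: pd.DataFrame
    ratios: pd.DataFrame
    tests: list
    manifest: dict

    def strategy_counts(self) -> pd.Series:
        return self.labels["strategy"].value_counts()

    def resilience_counts(self) -> pd.Series:
        return self.labels["resilience"].value_counts()

    def report(self) -> str:
        lines = ["droughtstrat pipeline report", "=" * 30]
        lines.append(f"samples analysed: {self.table.n_samples}")
        lines.append(f"dominant taxa: {len(self.labels)} of "
                     f"{self.manifest['stages']['dominance']['n_ranked_taxa']} ranked")
        lines.append("strategy counts: " + ", ".join(
            f"{k}={v}" for k, v in self.strategy_counts().items()))
        lines.append("resilience counts: " + ", ".join(
            f"{k}={v}" for k, v in self.resilience_counts().items()))
        for t in self.tests:
            lines.append("")
            lines.append(t.summary())
        return "\n".join(lines)


def _digest(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(df.to_csv(sep="\t").encode())
    return h.hexdigest()[:16]


def run_pipeline(table: OtuTable, meta: pd.DataFrame,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run every analysis stage in order on an in-memory table + metadata."""
    cfg = config or PipelineConfig()
    manifest = {
        "config": asdict(cfg),
        "version": _version,
        "inputs": {"n_taxa": table.n_taxa, "n_samples": table.n_samples,
                   "counts_digest": _digest(table.counts)},
        "stages": {},
    }
    stage = "rarefy"
    try:
        if cfg.skip_rarefaction or table.rarefaction_depth is not None:
            rare, dropped = table, {}
        else:
            rare, dropped = rarefy(table, cfg.rarefaction_depth, cfg.seed)
        meta = meta.loc[rare.sample_ids]
        manifest["stages"]["rarefy"] = {
            "depth": rare.rarefaction_depth, "n_samples": rare.n_samples,
            "dropped": dropped, "digest": _digest(rare.counts)}

        stage = "dominance"
        dom = select_dominant(rare, meta, level=cfg.occupancy_level,
                              quantile=cfg.dominance_quantile)
        dom_df = dominance_table(dom)
        manifest["stages"]["dominance"] = {
            "n_dominant": len(dom.dominant_taxon_ids),
            "n_ranked_taxa": dom.n_total_taxa,
            "reads_share_of_dominants": dom.reads_share_of_dominants}

        stage = "classify"
        labels = classify_taxa(rare, meta, dom.dominant_taxon_ids,
                               alpha=cfg.alpha, engine=cfg.engine,
                               n_perm=cfg.n_perm, seed=cfg.seed)
        manifest["stages"]["classify"] = {
            "strategy_counts": labels["strategy"].value_counts().to_dict(),
            "resilience_counts": labels["resilience"].value_counts().to_dict(),
            "n_fallback": int((labels["engine"] == "permutation_fallback").sum())}

        stage = "indices"
        rel = relative_abundance(rare)
        idx_rows, ratio_frames, tests = [], [], []
        lab_strategy = labels["strategy"]
        lab_resil = labels["resilience"]
        indices = {}
        for lab, groups in ((lab_strategy, ("resistant", "opportunistic", "sensitive")),
                            (lab_resil, ("resilient", "not_resilient"))):
            for g in groups:
                if (lab == g).any():
                    indices[g] = group_index(rel, lab, g, cfg.standardizer)
        for g, series in indices.items():
            for s, v in series.items():
                idx_rows.append((s, g, v))
        idx_df = pd.DataFrame(idx_rows, columns=["sample_id", "group", "index_value"])

        stage = "tests"
        for rtype, (num, den) in RATIO_TYPES.items():
            if num in indices and den in indices:
                r = strategy_ratio(indices[num], indices[den], rtype)
                ratio_frames.append(pd.DataFrame(
                    {"sample_id": r.index, "ratio_type": rtype, "value": r.values}))
                try:
                    tests.append(management_effect_test(r, meta, rtype))
                except ValueError:
                    pass
        ratios = (pd.concat(ratio_frames, ignore_index=True)
                  if ratio_frames else pd.DataFrame(
                      columns=["sample_id", "ratio_type", "value"]))
        manifest["stages"]["tests"] = [
            {"ratio_type": t.ratio_type, "t": t.t_statistic, "df": t.df,
             "p": t.p_value, "effect_size": t.effect_size} for t in tests]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(rare, dom_df, labels, idx_df, ratios, tests, manifest)


def run_pipeline_files(otu_path, meta_path, config: PipelineConfig | None = None,
                       out_dir=None) -> PipelineResult:
    """File-based entry point; optionally writes all outputs under ``out_dir``."""
    table = read_otu_table(otu_path)
    meta = read_metadata(meta_path)
    result = run_pipeline(table, meta, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.dominance.to_csv(out / "dominant.tsv", sep="\t", index=False)
        result.labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        result.indices.to_csv(out / "indices.tsv", sep="\t", index=False)
        result.ratios.to_csv(out / "ratios.tsv", sep="\t", index=False)
        pd.DataFrame([{
            "ratio_type": t.ratio_type, "t_statistic": t.t_statistic, "df": t.df,
            "p_value": t.p_value, "effect_size": t.effect_size,
            "ci_low": t.ci_low, "ci_high": t.ci_high} for t in result.tests]
        ).to_csv(out / "tests.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(result.manifest, fh, indent=2, default=str)
        with open(out / "report.md", "w") as fh:
            fh.write(result.report() + "\n")
    return result
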
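"""End-to-end analysis orchestration.

Loads an effect-size table and a phylogeny (newick tree or divergence
matrix), runs the global and subset intercept-only models, the moderator
models, bias diagnostics and sensitivity suites, and writes report tables
shaped like the two headline tables of a meta-analytic write-up:

* the global-tests table — one row per model/subset with k, N_species,
  pooled effect, 95% interval, p and the three-level I² decomposition; and
* the moderator table — one row per moderator with its contrast estimate,
  interval, p and marginal R².

Subset rows enumerate: mating-success method (copulatory vs genetic),
mating-success range (with vs without the zero class), study type
(laboratory vs field), and mating system (low vs high polyandry).  Subset
k values are reported exactly as computed from the data; where compiled
datasets disagree internally about subset counts or labels, both readings
belong in the replication notes rather than being silently corrected.

Every report carries provenance: an input hash, the seed and the chain
settings used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from .effects import classify_mating_system, read_effect_table
from .meta import MetaFit, MetaModelSpec, fit_mcmc, fit_reml
from .phylo import (
    PhyloCorrelationMatrix,
    phylo_correlation,
    prune_and_align,
    read_divergence_matrix,
    read_tree,
    upgma,
)

logger = logging.getLogger("batemeta")

__all__ = ["AnalysisConfig", "load_inputs", "run_global_analysis",
           "run_moderator_analysis", "run_diagnostics", "run_all"]

MODERATORS = ("ms_method", "ms_range", "study_type", "year", "mating_system", "polyandry")
SUBSET_COLUMNS = ("ms_method", "ms_range", "study_type", "mating_system")
MIN_SUBSET_K = 5


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs and settings for one full pipeline run."""

    effect_table: str
    tree: str | None = None
    divergence_matrix: str | None = None
    output_dir: str = "results"
    method: str = "mcmc"             # 'mcmc' or 'reml'
    polyandry_threshold: float = 0.5
    exclude_sex_role_reversed: bool = False
    exclude_human: bool = False
    reduced_chain: bool = False      # scaled-down chain for quick runs
    seed: int = 1

    def model_spec(self) -> MetaModelSpec:
        spec = MetaModelSpec(seed=self.seed)
        return spec.reduced() if self.reduced_chain else spec


def load_inputs(config: AnalysisConfig) -> tuple[pd.DataFrame, PhyloCorrelationMatrix]:
    """Read the effect table and derive the phylogenetic correlation matrix."""
    records = read_effect_table(config.effect_table)
    if config.tree:
        tree = read_tree(config.tree)
    elif config.divergence_matrix:
        tree = upgma(read_divergence_matrix(config.divergence_matrix))
    else:
        raise ValueError("either a tree or a divergence matrix is required")
    species = sorted(records["species"].astype(str).unique())
    tree, _ = prune_and_align(tree, species)
    corr = phylo_correlation(tree)

    if config.exclude_sex_role_reversed and "sex_role_reversed" in records:
        records = records.loc[~records["sex_role_reversed"].astype(bool)]
    if config.exclude_human and "human" in records:
        records = records.loc[~records["human"].astype(bool)]
    if "polyandry" in records and records["polyandry"].notna().any():
        has = records["polyandry"].notna()
        records = records.copy()
        records.loc[has, "mating_system"] = [
            classify_mating_system(p, config.polyandry_threshold)
            for p in records.loc[has, "polyandry"]
        ]
    return records.reset_index(drop=True), corr


def _fit(records, corr, spec, method, fixed=()) -> MetaFit:
    sp = replace(spec, fixed_terms=tuple(fixed))
    if method == "mcmc":
        _, fit = fit_mcmc(sp, records, corr)
    else:
        fit = fit_reml(sp, records, corr)
    return fit


def _table1_row(label: str, fit: MetaFit) -> dict:
    row0 = fit.fixed_estimates.iloc[0]
    het = fit.heterogeneity
    return {
        "model": label,
        "k": fit.k,
        "n_species": fit.n_species,
        "estimate": row0["estimate"],
        "lower": row0["lower"],
        "upper": row0["upper"],
        "p": row0["p"],
        "I2_phylogeny": het.get("I2_phylogeny", np.nan),
        "I2_study": het.get("I2_study", np.nan),
        "I2_observation": het.get("I2_observation", np.nan),
    }


def run_global_analysis(
    records: pd.DataFrame,
    corr: PhyloCorrelationMatrix,
    spec: MetaModelSpec | None = None,
    method: str = "mcmc",
) -> pd.DataFrame:
    """Intercept-only models for the full dataset and each standard subset.

    The full dataset is fitted both without ("non-phylogenetic": study and
    observation random terms only) and with the phylogenetic random term;
    each subset gets the phylogenetic model.  Subsets with k < 5 are
    skipped with a warning.
    """
    spec = spec or MetaModelSpec()
    rows = []
    logger.info("global model (non-phylogenetic), k=%d", len(records))
    nonphylo = replace(spec, random_terms=("study", "observation"))
    rows.append(_table1_row("Global model (non-phylogenetic)",
                            _fit(records, corr, nonphylo, method)))
    logger.info("global model (phylogenetic)")
    rows.append(_table1_row("Global model (phylogenetic)",
                            _fit(records, corr, spec, method)))
    for col in SUBSET_COLUMNS:
        if col not in records.columns:
            continue
        for level in sorted(records[col].dropna().unique()):
            subset = records.loc[records[col] == level]
            label = f"{col}={level}"
            if len(subset) < MIN_SUBSET_K:
                warnings.warn(f"subset {label} has k={len(subset)} < {MIN_SUBSET_K}; skipped")
                continue
            logger.info("subset %s, k=%d", label, len(subset))
            rows.append(_table1_row(label, _fit(subset.reset_index(drop=True),
                                                corr, spec, method)))
    return pd.DataFrame(rows)


def run_moderator_analysis(
    records: pd.DataFrame,
    corr: PhyloCorrelationMatrix,
    spec: MetaModelSpec | None = None,
    method: str = "mcmc",
) -> pd.DataFrame:
    """One single-moderator phylogenetic model per moderator.

    The binary mating-system contrast and the continuous polyandry model
    are both reported, mirroring the practice of giving the alternative
    continuous model alongside the preferred binary one.
    """
    spec = spec or MetaModelSpec()
    rows = []
    for mod in MODERATORS:
        if mod not in records.columns or records[mod].isna().any():
            continue
        if records[mod].nunique() < 2:
            continue
        logger.info("moderator model: %s", mod)
        fit = _fit(records, corr, spec, method, fixed=(mod,))
        row = fit.fixed_estimates.iloc[-1]
        r2 = fit.marginal_R2 or (np.nan, np.nan, np.nan)
        rows.append(
            {
                "moderator": mod,
                "term": row["term"],
                "estimate": row["estimate"],
                "lower": row["lower"],
                "upper": row["upper"],
                "p": row["p"],
                "R2": r2[0],
                "R2_lower": r2[1],
                "R2_upper": r2[2],
            }
        )
    return pd.DataFrame(rows)


def run_diagnostics(
    records: pd.DataFrame,
    corr: PhyloCorrelationMatrix,
    spec: MetaModelSpec | None = None,
    method: str = "reml",
) -> dict:
    """Egger funnel regression, year trend, heteroscedasticity of the
    continuous-polyandry model, and the sensitivity suite."""
    report = diag.bias_report(records, corr, method=method, spec=spec)
    out = {
        "k": report.k,
        "egger": report.egger.to_dict(),
        "year": report.year.to_dict(),
        "funnel_data": report.funnel_data,
    }
    if "polyandry" in records.columns and records["polyandry"].notna().all():
        chi2, df, p = diag.breusch_pagan_studentized(
            records["polyandry"].to_numpy(), records["r"].to_numpy()
        )
        out["breusch_pagan"] = {"chi2": chi2, "df": df, "p": p}
    out["sensitivity"] = diag.sensitivity_suite(records, corr, method=method, spec=spec)
    return out


def _provenance(config: AnalysisConfig, spec: MetaModelSpec) -> dict:
    digest = hashlib.sha256(Path(config.effect_table).read_bytes()).hexdigest()[:16]
    return {
        "effect_table": str(config.effect_table),
        "input_sha256_16": digest,
        "seed": config.seed,
        "method": config.method,
        "chain": [spec.iterations, spec.burn_in, spec.thinning],
        "prior": {"V": spec.prior_V, "nu": spec.prior_nu},
        "polyandry_threshold": config.polyandry_threshold,
    }


def run_all(config: AnalysisConfig) -> dict:
    """Full pipeline: global table, moderator table, diagnostics; writes
    delimited reports plus a machine-readable JSON sidecar."""
    records, corr = load_inputs(config)
    spec = config.model_spec()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    table1 = run_global_analysis(records, corr, spec, config.method)
    table2 = run_moderator_analysis(records, corr, spec, config.method)
    diagnostics = run_diagnostics(records, corr, spec)

    table1.to_csv(outdir / "global_models.csv", index=False)
    table2.to_csv(outdir / "moderator_models.csv", index=False)
    diagnostics["funnel_data"].to_csv(outdir / "funnel_data.csv", index=False)
    diagnostics["sensitivity"].to_csv(outdir / "sensitivity.csv", index=False)

    sidecar = {
        "provenance": _provenance(config, spec),
        "egger": {k: float(v) for k, v in diagnostics["egger"].items()},
        "year": {k: float(v) for k, v in diagnostics["year"].items()},
    }
    if "breusch_pagan" in diagnostics:
        sidecar["breusch_pagan"] = diagnostics["breusch_pagan"]
    (outdir / "report.json").write_text(json.dumps(sidecar, indent=2))
    return {"global": table1, "moderators": table2, "diagnostics": diagnostics,
            "provenance": sidecar["provenance"]}
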
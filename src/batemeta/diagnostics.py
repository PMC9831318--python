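"""Publication-bias and robustness diagnostics.

* Egger-type multilevel funnel regression: the effect (on the Fisher-z
  scale, whose sampling variance is free of the effect itself) is
  regressed on its standard error inside the full phylogenetic multilevel
  model; a nonzero slope signals small-study/funnel asymmetry.
* Year-of-publication trend ("bandwagon" check).
* Koenker's studentised Breusch-Pagan test for heteroscedasticity.
* A single-case outlier test (squared studentized deleted residual against
  a 1-df chi-squared tail); the exact published procedure is unnamed, so
  this reconstruction is flagged in the output metadata.
* A sensitivity suite refitting the headline models under exclusions
  (sex-role-reversed species, humans) and alternative polyandry
  thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .effects import classify_mating_system
from .meta import MetaFit, MetaModelSpec, fit_mcmc, fit_reml
from .phylo import PhyloCorrelationMatrix

__all__ = [
    "BiasReport",
    "egger_test",
    "year_trend_test",
    "breusch_pagan_studentized",
    "single_outlier_test",
    "sensitivity_suite",
]


@dataclass
class BiasReport:
    """Funnel-asymmetry and time-trend diagnostics for one dataset."""

    k: int
    egger: pd.Series            # estimate, lower, upper, p of the se(z) slope
    year: pd.Series | None
    funnel_data: pd.DataFrame   # z, se_z pairs for plotting
    metadata: dict = field(default_factory=dict)


def _with_fisher_z(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    r = out["r"].to_numpy(dtype=float)
    n = out["n"].to_numpy(dtype=float)
    out["z"] = np.arctanh(r)
    out["var_z"] = 1.0 / (n - 3.0)
    out["se_z"] = np.sqrt(out["var_z"])
    return out


def egger_test(
    records: pd.DataFrame,
    corr: PhyloCorrelationMatrix | None,
    method: str = "reml",
    spec: MetaModelSpec | None = None,
) -> tuple[MetaFit, pd.Series]:
    """Multilevel Egger regression of Fisher z on its standard error.

    Returns the full model fit and the funnel-slope row (estimate,
    interval, p).  ``method`` selects the REML or the MCMC route of the
    meta-model machinery.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    data = _with_fisher_z(records)
    if np.ptp(data["se_z"].to_numpy()) == 0:
        raise ValueError("funnel covariate has no variance")
    base = spec or MetaModelSpec()
    from dataclasses import replace

    spec_z = replace(base, response="z", fixed_terms=("se_z",))
    if method == "mcmc":
        _, fit = fit_mcmc(spec_z, data, corr)
    else:
        fit = fit_reml(spec_z, data, corr)
    row = fit.fixed_estimates.set_index("term").loc["se_z"]
    return fit, row


def year_trend_test(
    records: pd.DataFrame,
    corr: PhyloCorrelationMatrix | None,
    method: str = "reml",
    spec: MetaModelSpec | None = None,
) -> tuple[MetaFit, pd.Series]:
    """Mean-centered publication year as a continuous moderator of r."""
    from dataclasses import replace

    base = spec or MetaModelSpec()
    spec_y = replace(base, response=base.response, fixed_terms=("year",))
    if method == "mcmc":
        _, fit = fit_mcmc(spec_y, records, corr)
    else:
        fit = fit_reml(spec_y, records, corr)
    row = fit.fixed_estimates.set_index("term").loc["year_centered"]
    return fit, row


def bias_report(records: pd.DataFrame, corr, method: str = "reml",
                spec: MetaModelSpec | None = None) -> BiasReport:
    data = _with_fisher_z(records)
    _, egger_row = egger_test(records, corr, method, spec)
    _, year_row = year_trend_test(records, corr, method, spec)
    return BiasReport(
        k=len(records),
        egger=egger_row,
        year=year_row,
        funnel_data=data[["z", "se_z"]].copy(),
        metadata={"effect_scale": "fisher_z", "method": method},
    )


def breusch_pagan_studentized(x, y) -> tuple[float, int, float]:
    """Koenker's studentised Breusch-Pagan heteroscedasticity test.

    OLS of y on x, then the squared residuals regressed on x; the statistic
    is n·R² of that auxiliary regression, chi-squared with df = number of
    predictors under homoscedasticity.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant predictor")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    u = resid**2
    gamma, *_ = np.linalg.lstsq(X, u, rcond=None)
    fitted = X @ gamma
    ss_res = np.sum((u - fitted) ** 2)
    ss_tot = np.sum((u - u.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    df = x.shape[1]
    chi2 = n * r2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def single_outlier_test(values, index: int) -> tuple[float, float]:
    """Squared studentized deleted residual of one candidate observation.

    The candidate is compared with the mean and spread of the remaining
    values; the squared statistic is referred to a chi-squared distribution
    with 1 df.  Location-invariant by construction.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise ValueError("need at least 5 values")
    mask = np.ones(len(v), dtype=bool)
    mask[index] = False
    rest = v[mask]
    s = rest.std(ddof=1)
    if s == 0:
        raise ValueError("zero variance among remaining values")
    m = len(rest)
    t = (v[index] - rest.mean()) / (s * np.sqrt(1.0 + 1.0 / m))
    chi2 = float(t**2)
    return chi2, float(stats.chi2.sf(chi2, 1))


def sensitivity_suite(
    records: pd.DataFrame,
    corr: PhyloCorrelationMatrix | None,
    thresholds: tuple = (0.4, 0.5, 0.6),
    exclusions: tuple = ("sex_role_reversed", "human"),
    method: str = "reml",
    spec: MetaModelSpec | None = None,
) -> pd.DataFrame:
    """Refit the global and mating-system models under exclusion/threshold
    variants; reports pooled-estimate shifts and significance agreement
    with the full-data fit.  Input records are never mutated."""
    base_spec = spec or MetaModelSpec()

    def _fit(df, fixed=()):
        from dataclasses import replace

        sp = replace(base_spec, fixed_terms=tuple(fixed))
        if method == "mcmc":
            _, fit = fit_mcmc(sp, df, corr)
        else:
            fit = fit_reml(sp, df, corr)
        return fit

    rows = []
    full_fit = _fit(records)
    ref = full_fit.pooled_estimate
    ref_sig = full_fit.fixed_estimates.iloc[0]["p"] < 0.05

    def _add(name, df, fixed=()):
        if len(df) < 5:
            import warnings

            warnings.warn(f"sensitivity variant {name!r} has k={len(df)} < 5; skipped")
            return
        fit = _fit(df, fixed)
        row0 = fit.fixed_estimates.iloc[-1 if fixed else 0]
        rows.append(
            {
                "variant": name,
                "k": fit.k,
                "n_species": fit.n_species,
                "term": row0["term"],
                "estimate": row0["estimate"],
                "lower": row0["lower"],
                "upper": row0["upper"],
                "p": row0["p"],
                "shift_vs_full": row0["estimate"] - ref if not fixed else np.nan,
                "same_significance": (row0["p"] < 0.05) == ref_sig if not fixed else np.nan,
            }
        )

    _add("full", records)
    for flag in exclusions:
        if flag in records.columns and records[flag].any():
            _add(f"excluding_{flag}", records.loc[~records[flag].astype(bool)].copy())
        else:
            _add(f"excluding_{flag}", records.copy())
    if "polyandry" in records.columns and records["polyandry"].notna().any():
        for thr in thresholds:
            df = records.copy()
            has = df["polyandry"].notna()
            df.loc[has, "mating_system"] = [
                classify_mating_system(p, thr) for p in df.loc[has, "polyandry"]
            ]
            if df["mating_system"].nunique() > 1:
                _add(f"mating_system_threshold_{thr}", df, fixed=("mating_system",))
    return pd.DataFrame(rows)
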
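"""Weighted multilevel random-effects meta-analysis with phylogeny.

The model for effect size :math:`y_i` (Pearson r, or Fisher z) of record
*i* from species *sp(i)* in study *st(i)* is

.. math::

    y_i = \\mathbf{x}_i'\\beta + a_{sp(i)} + u_{st(i)} + e_i + \\epsilon_i

with :math:`a \\sim N(0, \\sigma^2_{phylo} C)` (``C`` the phylogenetic
correlation matrix), :math:`u \\sim N(0, \\sigma^2_{study} I)`,
:math:`e \\sim N(0, \\sigma^2_{obs} I)` and known sampling variances
:math:`\\epsilon_i \\sim N(0, v_i)` — i.e. each record is weighted by the
inverse of its sampling variance.  The model is fitted two ways:

* restricted maximum likelihood (deterministic), with Wald intervals; and
* a blocked Gibbs sampler for the same Gaussian model with inverse-Wishart
  (here scalar: scaled inverse-chi-squared) variance priors parameterised
  by ``(V, nu)``, reported as posterior modes with 95% highest posterior
  density intervals and MCMC tail p-values.

Heterogeneity beyond sampling error is decomposed into phylogenetic,
between-study and observation-level shares (multilevel I²); the
phylogenetic share is the phylogenetic heritability H², equivalent to
Pagel's lambda in this model class.  Moderator models additionally report
the marginal R², the share of variance explained by fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import PhyloCorrelationMatrix

__all__ = [
    "MetaModelSpec",
    "MetaFit",
    "build_design",
    "fit_reml",
    "fit_mcmc",
    "posterior_mode_hpd",
    "mcmc_p_value",
    "heterogeneity_decomposition",
    "typical_sampling_variance",
    "marginal_r2",
]

RANDOM_TERMS = ("phylogeny", "study", "observation")

# reference level of each two-level moderator; the fitted coefficient is the
# other level minus this one
BASELINES = {
    "ms_method": "copulatory",
    "ms_range": "without_zero",
    "study_type": "field",
    "mating_system": "low",
}

_VAR_FLOOR = 1e-10   # lower bound in REML optimisation
_VAR_ZERO = 1e-8     # components below this are reported as exactly 0


@dataclass(frozen=True)
class MetaModelSpec:
    """Settings for one meta-analytic model fit.

    Default chain settings give an effective sample of 10,000 draws
    (4,400,000 iterations, 400,000 burn-in, thinning 400) under the
    weakly informative variance prior (V=1, nu=0.002).
    """

    response: str = "r"
    fixed_terms: tuple = ()
    random_terms: tuple = RANDOM_TERMS
    prior_V: float = 1.0
    prior_nu: float = 0.002
    iterations: int = 4_400_000
    burn_in: int = 400_000
    thinning: int = 400
    seed: int = 1

    def __post_init__(self):
        if self.response not in ("r", "z"):
            raise ValueError("response must be 'r' or 'z'")
        unknown = set(self.random_terms) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "random_terms", tuple(self.random_terms))

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning

    def reduced(self, factor: int = 100) -> "MetaModelSpec":
        """Scaled-down chain (same structure, 1/factor the iterations)."""
        return replace(
            self,
            iterations=self.iterations // factor,
            burn_in=self.burn_in // factor,
            thinning=max(1, self.thinning // factor),
        )


@dataclass
class MetaFit:
    """Result of one model fit (REML or MCMC)."""

    method: str
    fixed_estimates: pd.DataFrame          # term, estimate, lower, upper, p
    variance_components: dict
    heterogeneity: dict                    # I2_<level> shares
    H2: float
    marginal_R2: tuple | None              # (value, lower, upper) or None
    k: int
    n_species: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def pooled_estimate(self) -> float:
        return float(self.fixed_estimates.iloc[0]["estimate"])


# ---------------------------------------------------------------------------
# design construction

def build_design(records: pd.DataFrame, fixed_terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; two-level moderators become indicators
    against the field-standard baseline, year is mean-centered, numeric
    columns (e.g. polyandry) enter as-is."""
    k = len(records)
    cols = [np.ones(k)]
    names = ["intercept"]
    for term in fixed_terms:
        if term not in records.columns:
            raise ValueError(f"moderator column missing: {term}")
        col = records[term]
        if term in BASELINES or col.dtype == object:
            levels = sorted(col.dropna().unique())
            if len(levels) < 2:
                raise ValueError(f"moderator {term} has a single level")
            base = BASELINES.get(term, levels[0])
            for lev in levels:
                if lev == base:
                    continue
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
        elif term == "year":
            x = col.to_numpy(dtype=float)
            cols.append(x - x.mean())
            names.append("year_centered")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    return X, names


def _response(records: pd.DataFrame, spec: MetaModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """(y, sampling variances) on the requested scale."""
    if spec.response == "r":
        y = records["r"].to_numpy(dtype=float)
        v = records["var_r"].to_numpy(dtype=float)
    else:
        if "z" in records.columns and records["z"].notna().all():
            y = records["z"].to_numpy(dtype=float)
        else:
            y = np.arctanh(records["r"].to_numpy(dtype=float))
        if "var_z" in records.columns and records["var_z"].notna().all():
            v = records["var_z"].to_numpy(dtype=float)
        else:
            v = 1.0 / (records["n"].to_numpy(dtype=float) - 3.0)
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    return y, v


def _grouping(records: pd.DataFrame, corr: PhyloCorrelationMatrix | None, spec: MetaModelSpec):
    """Index arrays and covariance structures for the random terms."""
    k = len(records)
    out = {}
    if "phylogeny" in spec.random_terms:
        if corr is None:
            raise ValueError("phylogenetic random term requires a correlation matrix")
        species = records["species"].astype(str).tolist()
        missing = sorted(set(species) - set(corr.labels))
        if missing:
            raise ValueError(f"species absent from correlation matrix: {missing}")
        used = sorted(set(species))
        C = corr.submatrix(used).values
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("phylogenetic correlation matrix is not PSD")
        sp_idx = np.array([used.index(s) for s in species])
        out["phylogeny"] = (sp_idx, C)
    if "study" in spec.random_terms:
        studies = records["study_id"].astype(str)
        codes = studies.astype("category").cat.codes.to_numpy()
        out["study"] = (codes, None)
    if "observation" in spec.random_terms:
        out["observation"] = (np.arange(k), None)
    return out


# ---------------------------------------------------------------------------
# REML

def _reml_nll(sig2: np.ndarray, y, X, v, covs) -> float:
    k = len(y)
    V = np.diag(v.copy())
    for s2, G in zip(sig2, covs):
        V += s2 * G
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return np.inf
    logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
    ViX = linalg.cho_solve(cf, X)
    Viy = linalg.cho_solve(cf, y)
    XtViX = X.T @ ViX
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    resid = y - X @ beta
    quad = resid @ linalg.cho_solve(cf, resid)
    return 0.5 * (logdetV + logdetX + quad)


def fit_reml(
    spec: MetaModelSpec,
    records: pd.DataFrame,
    corr: PhyloCorrelationMatrix | None = None,
) -> MetaFit:
    """Restricted-maximum-likelihood fit of the multilevel model.

    Deterministic given the data: variance components are optimised on
    bounded scale (floor 1e-10) by L-BFGS-B from several starts, and fixed
    effects get Wald normal intervals and p-values.  With an empty
    ``random_terms`` the fit reduces exactly to the fixed-effect
    inverse-variance weighted mean.
    """
    y, v = _response(records, spec)
    X, names = build_design(records, spec.fixed_terms)
    groups = _grouping(records, corr, spec)

    # marginal covariance contribution of each random term
    covs = []
    term_names = []
    k = len(y)
    for term in spec.random_terms:
        idx, C = groups[term]
        if C is not None:
            G = C[np.ix_(idx, idx)]
        else:
            G = (idx[:, None] == idx[None, :]).astype(float)
        covs.append(G)
        term_names.append(term)

    if covs:
        scale = max(np.var(y, ddof=1), v.mean())
        bounds = [(_VAR_FLOOR, 50.0 * scale)] * len(covs)
        starts = [
            np.full(len(covs), 0.3 * scale),
            np.full(len(covs), 0.01 * scale),
            np.full(len(covs), 1.0 * scale),
        ]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                _reml_nll, x0, args=(y, X, v, covs), method="L-BFGS-B", bounds=bounds
            )
            if best is None or res.fun < best.fun:
                best = res
        sig2 = np.maximum(best.x, 0.0)
    else:
        sig2 = np.array([])

    V = np.diag(v.copy())
    for s2, G in zip(sig2, covs):
        V += s2 * G
    cf = linalg.cho_factor(V, lower=True)
    ViX = linalg.cho_solve(cf, X)
    XtViX = X.T @ ViX
    beta_cov = np.linalg.inv(XtViX)
    beta = beta_cov @ (X.T @ linalg.cho_solve(cf, y))
    # Knapp-Hartung-type adjustment: rescale the coefficient covariance by
    # the weighted residual mean square and use a t(k-p) reference, which
    # propagates variance-component uncertainty into the fixed-effect tests
    resid = y - X @ beta
    dof = max(k - X.shape[1], 1)
    s2_kh = float(resid @ linalg.cho_solve(cf, resid)) / dof
    se = np.sqrt(s2_kh * np.diag(beta_cov))
    zcrit = stats.t.ppf(0.975, dof)
    pvals = 2.0 * stats.t.sf(np.abs(beta) / se, dof)
    fixed = pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "lower": beta - zcrit * se,
            "upper": beta + zcrit * se,
            "p": pvals,
        }
    )

    varcomps = {
        t: (0.0 if s2 < _VAR_ZERO else float(s2)) for t, s2 in zip(term_names, sig2)
    }
    het = heterogeneity_decomposition(varcomps, v) if varcomps else {}
    h2 = het.get("I2_phylogeny", 0.0)

    r2 = None
    if len(names) > 1:
        fitted = X @ beta
        num = float(np.var(fitted, ddof=1))
        r2_val = num / (num + sum(varcomps.values()))
        r2 = (r2_val, np.nan, np.nan)

    return MetaFit(
        method="reml",
        fixed_estimates=fixed,
        variance_components=varcomps,
        heterogeneity=het,
        H2=h2,
        marginal_R2=r2,
        k=k,
        n_species=int(records["species"].nunique()) if "species" in records else k,
        diagnostics={"converged": bool(best.success) if covs else True,
                     "nll": float(best.fun) if covs else np.nan},
    )


# ---------------------------------------------------------------------------
# Gibbs sampler

def fit_mcmc(
    spec: MetaModelSpec,
    records: pd.DataFrame,
    corr: PhyloCorrelationMatrix | None = None,
    return_samples: bool = True,
) -> tuple[pd.DataFrame, MetaFit]:
    """Blocked Gibbs sampler for the Gaussian multilevel model.

    Location effects (fixed coefficients, species, study and observation
    deviations) are drawn from their conjugate normal full conditionals;
    each variance component from its scaled inverse-chi-squared conditional
    with prior ``(V, nu)``.  Fixed effects carry a vague N(0, 1e8) prior.
    Reproducible for a given seed; returns the thinned post-burn-in samples
    and a :class:`MetaFit` summarised as posterior modes with 95% HPD
    intervals and MCMC tail p-values.
    """
    y, v = _response(records, spec)
    X, names = build_design(records, spec.fixed_terms)
    groups = _grouping(records, corr, spec)
    k, p = X.shape
    w = 1.0 / v
    rng = np.random.default_rng(spec.seed)

    nu, pv = spec.prior_nu, spec.prior_V

    use_phylo = "phylogeny" in spec.random_terms
    use_study = "study" in spec.random_terms
    use_obs = "observation" in spec.random_terms

    if use_phylo:
        sp_idx, C = groups["phylogeny"]
        S = C.shape[0]
        Cjit = C + 1e-10 * np.eye(S)
        Cinv = np.linalg.inv(Cjit)
        Ma = np.zeros((S, S))
        np.add.at(Ma, (sp_idx, sp_idx), w)  # Zs' W Zs (diagonal)
    if use_study:
        st_idx, _ = groups["study"]
        J = int(st_idx.max()) + 1
        w_st = np.bincount(st_idx, weights=w, minlength=J)

    XtW = X.T * w
    P_beta_base = XtW @ X + 1e-8 * np.eye(p)
    L_beta = np.linalg.cholesky(P_beta_base)

    beta = np.zeros(p)
    a = np.zeros(S) if use_phylo else None
    u = np.zeros(J) if use_study else None
    e = np.zeros(k) if use_obs else None
    s2a = s2u = s2e = 0.1

    n_out = spec.n_samples
    beta_out = np.empty((n_out, p))
    var_out = {t: np.empty(n_out) for t in spec.random_terms}

    def _inv_chi2(shape, scale):
        g = rng.gamma(shape)
        return scale / g

    out_i = 0
    for it in range(spec.iterations):
        contrib = np.zeros(k)
        if use_phylo:
            contrib += a[sp_idx]
        if use_study:
            contrib += u[st_idx]
        if use_obs:
            contrib += e

        # beta | rest
        rhs = XtW @ (y - contrib)
        mean = linalg.cho_solve((L_beta, True), rhs)
        zdraw = rng.standard_normal(p)
        beta = mean + linalg.solve_triangular(L_beta, zdraw, lower=True, trans="T")
        xb = X @ beta

        # species effects
        if use_phylo:
            resid = y - xb - (u[st_idx] if use_study else 0.0) - (e if use_obs else 0.0)
            P = Ma + Cinv / s2a
            L = np.linalg.cholesky(P)
            rhs = np.bincount(sp_idx, weights=w * resid, minlength=S)
            mean = linalg.cho_solve((L, True), rhs)
            a = mean + linalg.solve_triangular(L, rng.standard_normal(S), lower=True, trans="T")
            quad = a @ Cinv @ a
            s2a = _inv_chi2((nu + S) / 2.0, (nu * pv + quad) / 2.0)

        # study effects
        if use_study:
            resid = y - xb - (a[sp_idx] if use_phylo else 0.0) - (e if use_obs else 0.0)
            prec = w_st + 1.0 / s2u
            mean = np.bincount(st_idx, weights=w * resid, minlength=J) / prec
            u = mean + rng.standard_normal(J) / np.sqrt(prec)
            s2u = _inv_chi2((nu + J) / 2.0, (nu * pv + u @ u) / 2.0)

        # observation effects
        if use_obs:
            resid = y - xb - (a[sp_idx] if use_phylo else 0.0) - (u[st_idx] if use_study else 0.0)
            prec = w + 1.0 / s2e
            mean = w * resid / prec
            e = mean + rng.standard_normal(k) / np.sqrt(prec)
            s2e = _inv_chi2((nu + k) / 2.0, (nu * pv + e @ e) / 2.0)

        state = beta.sum() + (s2a if use_phylo else 0.0) + (s2u if use_study else 0.0)
        if not np.isfinite(state):
            raise RuntimeError(f"divergent chain at iteration {it}")

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0 and out_i < n_out:
            beta_out[out_i] = beta
            if use_phylo:
                var_out["phylogeny"][out_i] = s2a
            if use_study:
                var_out["study"][out_i] = s2u
            if use_obs:
                var_out["observation"][out_i] = s2e
            out_i += 1

    samples = pd.DataFrame(beta_out[:out_i], columns=names)
    for t in spec.random_terms:
        samples[f"sigma2_{t}"] = var_out[t][:out_i]

    fit = _summarize_mcmc(samples, names, spec, X, v, records)
    return (samples if return_samples else None), fit


def _summarize_mcmc(samples, names, spec, X, v, records) -> MetaFit:
    rows = []
    for name in names:
        s = samples[name].to_numpy()
        mode, lo, hi = posterior_mode_hpd(s, 0.95)
        rows.append({"term": name, "estimate": mode, "lower": lo, "upper": hi,
                     "p": mcmc_p_value(s)})
    fixed = pd.DataFrame(rows)

    var_samples = {t: samples[f"sigma2_{t}"].to_numpy() for t in spec.random_terms}
    varcomps = {}
    for t, s in var_samples.items():
        mode, _, _ = posterior_mode_hpd(s, 0.95)
        varcomps[t] = float(max(mode, 0.0))

    het = {}
    h2 = 0.0
    if var_samples:
        s2bar = typical_sampling_variance(v)
        total = np.sum([s for s in var_samples.values()], axis=0) + s2bar
        for t, s in var_samples.items():
            share = s / total
            mode, lo, hi = posterior_mode_hpd(share, 0.95)
            het[f"I2_{t}"] = float(np.clip(mode, 0.0, 1.0))
            het[f"I2_{t}_lower"] = float(max(lo, 0.0))
            het[f"I2_{t}_upper"] = float(min(hi, 1.0))
        h2 = het.get("I2_phylogeny", 0.0)

    r2 = None
    if len(names) > 1:
        B = samples[names].to_numpy()
        fitted_var = np.var(X @ B.T, axis=0, ddof=1)
        total_var = fitted_var + np.sum([s for s in var_samples.values()], axis=0)
        r2s = fitted_var / total_var
        mode, lo, hi = posterior_mode_hpd(r2s, 0.95)
        r2 = (float(np.clip(mode, 0, 1)), float(max(lo, 0)), float(min(hi, 1)))

    n_eff = len(samples)
    acf1 = {c: float(pd.Series(samples[c]).autocorr()) for c in names[:1]}
    return MetaFit(
        method="mcmc",
        fixed_estimates=fixed,
        variance_components=varcomps,
        heterogeneity={key: val for key, val in het.items() if not key.endswith(("lower", "upper"))},
        H2=h2,
        marginal_R2=r2,
        k=len(records),
        n_species=int(records["species"].nunique()) if "species" in records else len(records),
        diagnostics={"n_samples": n_eff, "lag1_autocorr": acf1,
                     "converged": True,
                     "hpd": {key: val for key, val in het.items()}},
    )


# ---------------------------------------------------------------------------
# posterior and heterogeneity summaries

def posterior_mode_hpd(samples, prob: float = 0.95) -> tuple[float, float, float]:
    """Posterior mode (Silverman-bandwidth KDE argmax) and shortest interval
    containing ``prob`` posterior mass (sorted-sample window method)."""
    s = np.asarray(samples, dtype=float)
    if len(s) < 100:
        raise ValueError("need at least 100 samples")
    if np.ptp(s) == 0:
        c = float(s[0])
        return c, c, c
    kde = stats.gaussian_kde(s, bw_method="silverman")
    grid = np.linspace(s.min(), s.max(), 512)
    mode = float(grid[np.argmax(kde(grid))])
    srt = np.sort(s)
    n = len(srt)
    m = int(np.ceil(prob * n))
    widths = srt[m - 1 :] - srt[: n - m + 1]
    i = int(np.argmin(widths))
    return mode, float(srt[i]), float(srt[i + m - 1])


def mcmc_p_value(samples) -> float:
    """Twice the smaller posterior tail probability of the coefficient sign."""
    s = np.asarray(samples, dtype=float)
    n = len(s)
    p_pos = np.mean(s > 0)
    p_neg = np.mean(s < 0)
    return float(max(2.0 * min(p_pos, p_neg), 1.0 / n))


def typical_sampling_variance(sampling_variances, method: str = "higgins") -> float:
    """Typical within-record sampling variance s̄².

    ``higgins``: s̄² = (k−1)Σw / ((Σw)² − Σw²), w = 1/vᵢ — equals v exactly
    when all records share sampling variance v.  ``mean``: simple average.
    """
    v = np.asarray(sampling_variances, dtype=float)
    if len(v) == 0 or np.any(v <= 0):
        raise ValueError("sampling variances must be positive and non-empty")
    if method == "mean":
        return float(v.mean())
    w = 1.0 / v
    k = len(w)
    if k == 1:
        return float(v[0])
    return float((k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()))


def heterogeneity_decomposition(
    varcomps: Mapping[str, float],
    sampling_variances,
    method: str = "higgins",
) -> dict:
    """Multilevel I²: each level's share of total variance including s̄².

    I²_level = σ²_level / (Σ σ² + s̄²).  The phylogenetic share is the
    phylogenetic heritability H² (Pagel's λ equivalent).
    """
    if not varcomps:
        raise ValueError("no variance components supplied")
    vals = np.array([varcomps[t] for t in varcomps], dtype=float)
    if np.any(vals < 0):
        raise ValueError("variance components must be non-negative")
    s2bar = typical_sampling_variance(sampling_variances, method)
    total = vals.sum() + s2bar
    return {f"I2_{t}": float(varcomps[t] / total) for t in varcomps}


def marginal_r2(fit: MetaFit, design: np.ndarray) -> float:
    """Share of variance explained by fixed moderators:
    Var(Xβ̂) / (Var(Xβ̂) + Σ σ²)."""
    if len(fit.fixed_estimates) < 2:
        raise ValueError("no moderator in model")
    beta = fit.fixed_estimates["estimate"].to_numpy()
    fitted = design @ beta
    num = float(np.var(fitted, ddof=1))
    return num / (num + sum(fit.variance_components.values()))
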
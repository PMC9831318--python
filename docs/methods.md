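# Methods

## Individual-level metrics

The Bateman gradient is cov(MS, RS)/var(MS) on a sample of females, with
both axes optionally relativised (divided by the sample mean, making the
slope unitless and the intercept-free comparison across species valid).
All variances use the sample (n−1) convention throughout the package; the
choice is conventional, and every identity tested (I_s as squared
coefficient of variation, s'_max = r·sd(relative RS)) holds under it.

Two documented decisions where usage in the literature is ambiguous:

* **Zero-exclusion precedes relativization.**  The "excluding zero mating
  success" gradient is computed entirely on the mated subsample, so its
  relativised scale is the mated females' means.
* **Polyandry denominator.**  Polyandry is the proportion of *mated*
  females (MS ≥ 1) with more than one partner.  "Reproducing females"
  would require RS, which disagrees with MS in edge cases; MS ≥ 1 is the
  proxy used consistently.
* Non-integer MS/RS values (rates rather than counts) are accepted with a
  warning, since several primary studies report rates.

## Effect sizes

Published slopes are converted to Pearson correlations via
r = slope·sd(MS)/sd(RS); where only a t statistic and residual df are
available, r = √(t²/(t²+df)) with the slope's sign.  Sampling variances
are var(r) = (1−r²)²/(n−1) (an (n−2)-denominator variant is selectable)
and var(z) = 1/(n−3) for Fisher's z = artanh(r).  The binary mating
system is "high" when the species' polyandry exceeds the 0.5 threshold;
exact ties classify as high (the threshold is the reported average
polyandry of wild populations, so a species *at* the average is grouped
with the high class).  Thresholds 0.4 and 0.6 are carried through the
sensitivity suite.

## Phylogeny

UPGMA is implemented directly (cluster-size-weighted arithmetic-mean
linkage, node height = half the merge distance) so that the tie rule is
explicit: among equally close pairs, the one with the lowest label
indices merges first.  Tied divergence times therefore yield a
deterministic binary resolution rather than a polytomy.  The test suite
cross-checks merge heights against SciPy's average linkage on tie-free
matrices.

The phylogenetic correlation matrix scales tree depth to 1 and sets entry
(i, j) to the shared root-to-MRCA path fraction — the expected trait
correlation under Brownian motion.  Unit depth is required for the
interpretation of the phylogenetic variance share as heritability H² /
Pagel's λ.  For a matrix that is already ultrametric, the construction
reduces to 1 − d_ij/max(d).

## Meta-analytic model

Effect sizes are modelled as y_i = x_i'β + a_sp(i) + u_st(i) + e_i + ε_i
with known sampling variances Var(ε_i) = v_i (records weighted by inverse
sampling variance), Var(a) = σ²_phylo·C, Var(u) = σ²_study·I,
Var(e) = σ²_obs·I.  The response is r for the substantive models; the
funnel diagnostics use z, whose sampling variance is free of the effect
itself.

**Gibbs sampler.**  All location effects have conjugate normal full
conditionals (fixed effects carry a vague N(0, 10⁸) prior); each variance
component has a scaled-inverse-χ² conditional under the (V, ν) prior —
an inverse gamma with shape (ν+q)/2 and scale (νV + S)/2, where q is the
number of effect levels and S the (C⁻¹-weighted, for the phylogenetic
term) sum of squares.  Defaults mirror standard practice for this model
family: V = 1, ν = 0.002, and a chain of 4,400,000 iterations with
400,000 burn-in and thinning 400 (10,000 stored samples).
`MetaModelSpec.reduced()` scales the chain by 100 (44,000/4,000/4, still
10,000 samples); tests and the acceptance script use this scaled-down
chain, which agrees with REML to well under 0.02 on the pooled effect in
our checks.  Fixed seeds make runs byte-identical.

Posterior summaries: the point estimate is the argmax of a Gaussian KDE
with Silverman bandwidth over 512 grid points ("posterior mode" is
estimator-dependent, so the estimator is pinned down); the 95% HPD
interval is the shortest window containing 95% of the sorted samples;
p_MCMC is twice the smaller tail probability of the coefficient's sign,
floored at 1/n_samples.

**REML.**  The restricted likelihood is maximised over the variance
components by L-BFGS-B from three start points, with components bounded
below at 1e−10 (reported as exactly 0 below 1e−8) to avoid boundary
pathologies.  With all random terms removed the fit reduces exactly to
the fixed-effect inverse-variance weighted mean.  Fixed-effect inference
uses the Knapp–Hartung-type adjustment: the coefficient covariance is
rescaled by the weighted residual mean square and referred to a t(k−p)
distribution, which propagates variance-component uncertainty and
improves the calibration of moderator tests.  A test cross-checks the
full three-level fit against R's metafor (`rma.mv`) on a small dataset.

**Heterogeneity.**  I²_level = σ²_level/(Σσ² + s̄²), where the typical
sampling variance s̄² uses the Higgins formula
(k−1)Σw/((Σw)²−Σw²), w = 1/v_i, by default (a simple-mean variant is
selectable; with equal v the two coincide).  I²_phylogeny is reported as
H².  Marginal R² for moderator models is Var(Xβ)/(Var(Xβ)+Σσ²),
computed per posterior sample in the MCMC route (mode + HPD) and at the
point estimates under REML.

Moderator coding uses fixed baselines (copulatory, without_zero, field,
low) so contrast signs match the field's reporting conventions;
publication year is mean-centered for scale stability.

## Diagnostics

* **Egger regression** adds se(z) as a fixed covariate to the full
  three-level model with z as response.  z is used because var(z) depends
  only on n, avoiding the artefactual effect–variance correlation that
  the r scale induces.
* **Breusch–Pagan (Koenker studentised)**: n·R² of the auxiliary
  regression of squared OLS residuals on the predictor, referred to
  χ²(df = number of predictors); verified against statsmodels.
* **Single-case outlier test**: the squared studentized deleted residual
  of the candidate against the remaining values, referred to χ²(1).  The
  exact procedure behind published single-species outlier statistics is
  rarely named; this reconstruction is flagged in output metadata.
* **Sensitivity suite**: refits under exclusion of flagged records
  (sex-role-reversed species, humans) and under polyandry thresholds
  0.4/0.5/0.6, reporting estimate shifts and significance agreement.

## Synthetic-data generator

The generator defines the study conditions for every test.  Defaults are
frozen to the compiled-literature shape: 120 effect sizes from 77 species
in 84 studies (every species hosts at least one study, every study at
least one effect; the remainder are assigned uniformly), per-study sample
sizes lognormal with median 50 females (σ_log = 0.6, clipped to
[10, 500]), true mean effect μ = 0.4 on the correlation scale, and
variance components (σ²_phylo, σ²_study, σ²_obs) = (0.04, 0.03, 0.01) —
the phylogenetic component is half the generated heterogeneity, and the
implied I² decomposition is of the same order as published multilevel
meta-analyses in this area.  Moderators are assigned with the compiled
dataset's approximate composition (64% genetic mating success, 47%
with-zero range, 57% field studies, species polyandry ~ Beta(3.3, 1.7)
with mean 0.66) and are independent of the true effects, so moderator
models should find nothing on default synthetic data.

The phylogeny is a forward-time pure-birth tree rescaled to unit depth.
Species effects are drawn multivariate normal with covariance
σ²_phylo·C.  True per-record effects θ = μ + a + u + e are kept inside
the correlation scale by redrawing e up to 100 times and clamping to
±0.98 thereafter (clamped values are recorded as the truth, and a counter
is kept; under defaults this touches a handful of records at most).

Observed effects come from one of three routes:

* **fast mode (default)**: r = θ + normal noise with variance
  (1−θ²)²/(n−1);
* **fast mode, z-scale noise**: z = artanh(θ) + noise with variance
  1/(n−3), then r = tanh(z).  This is the exact null for the z-scale
  Egger test — on the r scale the artanh transform acquires a small
  n-dependent bias that a funnel test correctly flags — so calibration
  simulations use this route;
* **individual mode**: each record is a fully simulated study whose
  (MS, RS) pair comes from a Gaussian copula with latent correlation θ,
  quantile-mapped to Poisson matings and negative-binomial offspring; the
  observed r is the sample Pearson correlation.  Discretisation
  attenuates |r| slightly, which is why fast mode is the default for
  meta-level tests while individual mode exercises the selection-metrics
  stack end to end.

The individual-level mechanism model: matings m ~ Poisson(2.5)
(optionally zero-truncated), RS | m ~ negative binomial with mean
fecundity_mean + β_true·(m−1) for m ≥ 1 (zero otherwise) and dispersion
θ_NB = 5; genetic mating success is the number of distinct sires among
min(offspring_sampled, RS) offspring assigned uniformly to the m mates —
by construction never exceeding m, converging to m as genotyping becomes
exhaustive, and positively correlated with RS when few offspring are
genotyped, which reproduces the documented inflation of parentage-based
Bateman gradients.  Paternity is uniform across mates; skewed paternity
is deliberately out of scope.

What the generator does **not** emulate: real divergence-time trees
(pure-birth branching only), non-Gaussian heterogeneity, correlated
moderators (e.g. genetic mating success co-occurring with particular
taxa), selective publication, or shared-author dependence beyond the
study level.  Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those features of
real literature data.

## Problem sizes and numerical choices

Tests and the acceptance script use the scaled-down chain
(44,000/4,000/4), 20-replicate recovery runs at k = 150, and 200-replicate
calibration loops at k = 200 — sizes chosen so the whole suite runs on a
single CPU in a few minutes while keeping Monte-Carlo error well below
the tolerances asserted.  The Egger size check empirically lands around
0.07–0.09 at nominal 0.05: multilevel Wald-type funnel tests are known to
run slightly liberal, and the Knapp–Hartung adjustment narrows but does
not remove this.

Known limitations: with 77 species and 84 studies the phylogenetic and
study variance components are weakly separated, so their individual I²
shares have wide intervals (their sum is stable) — the same behaviour
reported for real datasets of this shape; REML may attribute the shared
heterogeneity to either level depending on the realisation.  The
single-outlier test and the Egger regression are reconstructions of
procedures that published analyses name only loosely; both are flagged as
such in metadata.
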
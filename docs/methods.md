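# Methods

## The modelling problem

The unit of observation is the operational geographic unit (OGU): one
1°×1° cell of a rectangular study window (default 20°W–60°E,
9.5°N–70°N, the Western Palearctic and its African margin). The target is
binary: an OGU is a presence (y = 1) if at least one occurrence record
dated inside the breeding window falls in it, an absence otherwise. No
sampling-effort or detectability correction is applied; absence means
"no breeding-season record", which is how the training labels of this
kind of atlas-scale analysis are constructed. The breeding window is
"late February to late July"; the package fixes it to February 21 –
July 31 (closed on both ends, any year) and exposes it as a parameter,
since exact calendar bounds are a judgement call. Cells are labelled by
their lower-left corner and membership is half-open,
[x, x+1) × [y, y+1), so every point belongs to exactly one cell.
Covariate values per OGU follow a zonal-mean contract: the arithmetic
mean of fine-resolution pixel values tagged with the cell id, missing
values excluded from numerator and denominator.

## Screening

Candidate predictors (21 by default: altitude and slope plus 19
bioclimatic variables) are reduced in two fixed-order stages:

1. **Collinearity.** Pairwise Spearman correlations (product-moment
   correlation of mid-ranks; ties get average ranks; a constant column
   yields an undefined correlation, treated as 0). Pairs with |r| > 0.8
   are processed greedily in descending |r|; in each pair still alive,
   the member with the smaller univariate Rao score statistic is dropped.
   Ties — on |r| or on the statistic — break by catalogue order, so the
   outcome never depends on input ordering. "Individual predictive
   power" is operationalised as the univariate score statistic by
   default, with a univariate-AUC alternative behind a flag; the choice
   is deliberately configurable because the concept admits both readings.
2. **FDR.** Of the survivors, only variables whose univariate score-test
   p-value clears the Benjamini–Hochberg step-up procedure at q = 0.05
   are admitted to modelling. On fully null candidates the admitted
   fraction stays near or below q (checked by simulation in the suite).

## Stepwise fit

The fit starts from the intercept-only model, whose constant probability
is the prevalence. Each forward step evaluates Rao's score test for every
excluded candidate at the current fit — efficient score U = x'(y − p)
with variance x'Wx − x'WZ(Z'WZ)⁻¹Z'Wx, W = diag(p(1−p)) — and enters the
most significant candidate if p < α_in = 0.05. After each entry, any
included variable whose Wald p exceeds α_out = 0.10 is removed, largest
first. The removal test and α_out are not uniquely determined by the
procedure's description in the SPSS software family this mirrors; Wald at
0.10 is that family's default and both thresholds are configurable. A
cycling guard forbids a variable removed immediately after entry from
re-entering while the included set is unchanged. At termination every
included variable has Wald p ≤ α_out and every excluded candidate scores
p ≥ α_in (asserted on every replicate in the suite).

Maximum likelihood uses IRLS/Newton with step-halving, convergence when
the log-likelihood improves by less than 1e-8 (50 iterations cap),
standard errors from the inverse observed information; the gradient norm
at the optimum is below 1e-6 in tests, and the fit matches an independent
GLM implementation to 1e-6 on shared data. Complete or quasi-complete
separation — possible on synthetic data even though rare-species atlas
data cannot produce it — is detected as coefficient divergence (any
standardized coefficient |β·sd(x)| exceeding 30, far beyond anything
data-supported) and raised as an explicit error rather than returned as
huge coefficients.

## Favourability

The favourability function is implemented in its odds form
F = odds(P)/(n1/n0 + odds(P)), computed as expit(logit(P) − ln(n1/n0)) so
extreme logits cannot overflow; endpoints F(0) = 0, F(1) = 1 hold by
continuity and the map is a strictly increasing bijection of [0,1] with
an exact inverse. F = 0.5 at P = prevalence is an algebraic identity.
Bands: F > 0.8 highly favourable (odds better than 4:1), F < 0.2
unfavourable, boundaries inclusive to the intermediate band. Response
curves split a variable's observed range into 20 equal-width bins and
report the mean favourability per bin (NaN for empty bins).

## Assessment

AUC uses the rank-sum formulation (ties count one half; equal to the
pairwise-ordering fraction, checked against an O(n²) oracle to 1e-12)
with a two-sided p-value from the tie-corrected normal approximation to
the Mann–Whitney statistic — the approximation is a package choice, made
because the assessment literature this follows does not pin one down.
Classification at F = 0.5 counts a cell favourable only for F strictly
greater than 0.5. Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
over-prediction rate OPR = FP/(TP+FP), under-prediction rate
UPR = FN/(TN+FN); empty denominators give NaN, never 0. At prevalence
≈ 0.025 a well-discriminating model necessarily shows high OPR — the
favourable area dwarfs the set of recorded presences — and the suite
reproduces this qualitatively.

## Projection and fuzzy ensemble

Projection substitutes scenario climate values into the fitted logit;
coefficients, n1 and n0 stay at their training values, and topographic
variables are always carried from the present table (topography does not
change on these horizons). The identity scenario reproduces the present
surface bit for bit. Environmental novelty — the fraction of scenario
values inside the training min–max range per model variable — is
reported but never used to mask projections. Per period the member
surfaces (default 8 = 4 RCPs × 2 GCMs) are combined as the per-OGU mean,
fuzzy union (max), fuzzy intersection (min) and uncertainty
(union − intersection); the scalar summary is the mean uncertainty over
OGUs, averaged over every OGU in the table (land-only subsetting is left
to the caller's mask).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not real geography:

* **Covariates** come from a Gaussian copula: a latent correlation
  matrix with targeted pairs (Spearman target rs mapped to the latent
  Pearson ρ = 2 sin(π·rs/6)), Cholesky-factored and transformed through
  monotone marginals — log-normal for non-negative variables
  (precipitation amounts, altitude, slope, seasonality), affine Gaussian
  for temperatures and indices — so rank correlations survive exactly.
  The default structure uses disjoint correlated pairs (four above the
  0.8 screening threshold), which keeps the matrix positive definite by
  construction; an infeasible user structure raises an explicit error.
  Marginal locations and spreads are plausible for the study window.
* **Presence** is Bernoulli(expit(a + Σβx)) with three active variables,
  Pwarm −0.026, Prec +0.0017, Alti +0.0015 (standardized effects ≈ −0.9,
  +0.5, +0.5 — a dominant negative warm-quarter-precipitation effect with
  two weaker positive ones, the qualitative structure of an arid-zone
  breeder), and the intercept solved by root-finding on [−30, 30] so the
  mean probability equals the target prevalence 0.025 to 1e-6. The true
  intercept and per-OGU probabilities are returned for recovery tests.
* **Scenarios**: additive climate offsets (warming ordered by RCP and
  period, precipitation reduced proportionally to warming) plus i.i.d.
  Gaussian cell noise so the eight members disagree and fuzzy uncertainty
  is non-zero; non-negative variables are clipped at 0. Topography is
  never shifted; asking to shift it is an error.
* **Point records**: 1–3 in-window records inside each presence cell,
  plus off-season decoys in presence and absence cells, so the season
  filter and the gridding have something to reject; filtering then
  gridding the records reproduces the presence table.

What the generator does not emulate: spatial autocorrelation of climate
fields, real WorldClim marginal shapes beyond sign and support, uneven
observer effort, and coastline/land masks. Tests passing on this
generator therefore demonstrate the statistical machinery (selection,
calibration, invariants), not performance on real rasters.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixed seeds give byte-identical tables,
reports and artifacts.

## Problem sizes and verification

The default study size (4177 OGUs, 21 covariates, 8 scenarios × 2
periods) runs the full pipeline in about a second, so the packaged
configuration is also the test configuration. Parameter recovery is
verified on 100 seeded full-scale replicates: "recovered" means every
planted variable is selected — forward entry at α = 0.05 admits an
occasional extra noise term by design, which is the procedure's type-I
behaviour rather than a recovery failure (the exact-set rate, ~0.80 on
the defaults, is tracked alongside). Coefficient ±2·SE coverage sits at
the nominal ~95%.

## Known limitations

* Absences are pseudo-absences of convenience (no record ≠ no breeding);
  the favourability transform corrects for prevalence, not for effort.
* Stepwise selection inherits the usual caveats: post-selection p-values
  are optimistic and correlated candidates can swap roles; the screening
  stages mitigate but do not remove this.
* The ensemble treats the eight scenario members as exchangeable; no
  member weighting or bias correction is attempted.
* Grid cells are treated as planar; no area weighting by latitude.
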
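# Methods

This note documents the models implemented in `thermoresp`, the
assumptions behind them, the synthetic-data generator used to validate
the chain end to end, and the numerical choices that were genuinely open.

## Gas-exchange mass balance

All rate calculations assume steady state: the animal's V̇O₂, V̇CO₂ and
evaporative water output are constant over the averaging window, so
species conservation links incurrent and excurrent composition exactly.
Washout dynamics are *not* deconvolved (no instantaneous/Z-transform
correction); instead the transient after each multiplexer switch is
discarded and a steady window is selected downstream. This matches how
steady-state respirometry is normally analysed and means short metabolic
fluctuations are smoothed over.

Conventions follow the usual instrument chain: water-vapour pressure is
read on the wet stream (fraction = P_H2O/BP), O₂ and CO₂ after drying
(dry-basis fractions). Writing FRi for wet incurrent flow, FRed for dried
excurrent flow, conservation of the inert fraction gives
FRi·(1−FiO₂−FiCO₂−FiH₂O) = FRed·(1−FeO₂−FeCO₂), from which either flow
follows from the metered one (incurrent in push mode, dried excurrent in
pull mode). Then V̇O₂ = FRi·FiO₂ − FRed·FeO₂, V̇CO₂ symmetrical, and the
water rate comes from the wet excurrent flow FRe = FRed/(1−FeH₂O) as
V̇H₂O = FRe·FeH₂O − FRi·FiH₂O, converted at 0.803 mg per ml of vapour
(STP). The inversion is exact — the forward simulator in
`thermoresp.synthetic` and the inversion in `thermoresp.calorimetry` are
derived independently and agree to machine precision, which the test
suite checks on randomized grids.

Barometric pressure defaults to 101.325 kPa and is a per-run
configuration value. Small negative rates (|rate| < 0.01 ml min⁻¹ or
mg min⁻¹), which arise from analyzer noise around a true zero, are set to
zero with a warning; larger negative rates flag the record instead of
being clamped, so non-physical data cannot silently enter a fit.

Energy conversions: MR (W) = V̇O₂·(16 + 5.164·RER)/60 — the oxyjoule
equivalent (16 + 5.164·RER) J per ml O₂ — and EHL (W) = EWL·2.4/60 with
the latent heat of vaporization 2.4 J mg⁻¹. Dry thermal conductance
C = (MR − EHL)/((T_b − T_a)·A_s) with A_s = 10·m_b^0.667 cm² is only
meaningful below the lower critical temperature; the function refuses
T_b ≤ T_a rather than returning a sign-flipped value.

## Trace processing

A multiplexed run cycles the analyzers over animal chambers (5-min
dwells) and a reference airline at least every 20 min. Choices the
upstream literature leaves open, fixed here:

* **Washout discard**: 60 s after every valve switch (configurable). A
  0.85 L chamber at 500 ml min⁻¹ has a ~1.7 min time constant, but since
  a steady plateau is selected afterwards, removing only the sharpest
  transient suffices.
* **Reference summary**: mean of the last 3 min of each 5-min reference
  dwell (discarding the reference's own washout).
* **Drift correction**: incurrent composition at each sample time is the
  linear interpolation between the bracketing reference summaries. Any
  affine analyzer drift is removed exactly (zero residual in the
  noise-free case, a property the tests assert); slower-than-affine drift
  between references is approximated. With a single reference the
  correction degenerates to a constant baseline with a warning.
* **Steady-state selection**: `lowest_mean` minimises the window mean of
  V̇O₂ (2-min default, the convention for resting whole-body metabolism);
  `most_stable` minimises within-window variance (5-min default, used
  for mask sessions). Windows slide one sample at a time; ties break to
  the earliest window. A slope-based stability metric would be a
  reasonable alternative to variance; variance was chosen because it is
  parameter-free and matches "most unchanging" on the data patterns the
  generator produces. Concurrent EWL/T_b are averaged over the window
  selected on V̇O₂, keeping the triplet synchronous.

## Segmented regression

The profiled model is continuous by construction:
f(x) = a + Σ_j s_j·(clip(x, L_j, U_j) − L_j). For fixed breakpoints it is
linear, so breakpoints are profiled out by least squares and located by
search: candidates are the midpoints between consecutive sorted unique x
plus the interior unique x themselves (so a knot can sit exactly on a
data point), each admissible data interval is polished by bounded scalar
minimisation to 1e-4, and for two breakpoints the pair grid is followed
by three coordinate-polish passes. The SSE as a function of a breakpoint
is smooth within a data interval but only piecewise-smooth globally,
which is why every interval is polished rather than only the best grid
cell; the tests hold the fitter to an exhaustive 0.01-step grid oracle.
Candidate breakpoints must leave at least two observations per side, and
a fit requires at least five observations per prospective segment.

Horizontal constraints pin a segment's slope to exactly zero (the column
is simply omitted). Discontinuous piecewise families are intentionally
not offered — the physiological profiles are continuous.

Model-shape selection (`select_model_type`) orders candidates by model
degrees of freedom (one per breakpoint, per free slope, plus intercept)
and adopts a richer shape only when the extra-sum-of-squares F-test is
significant at α = 0.05, preferring fewer breakpoints otherwise. The
candidate shapes here are not all strictly nested (a flat-then-rise
two-parameter model vs a free line, for instance); the nested-F cascade
is the documented convention and behaves conservatively in the
simulations the tests run.

Breakpoint, slope and plateau standard errors come from a nonparametric
**cluster bootstrap that resamples individuals**, not rows, because each
bird contributes many points and row resampling would understate the
uncertainty. Degenerate resamples (too few distinct x) are dropped with a
warning. B = 1000 is the default at the CLI; the test suite uses B = 200
and below to keep runtimes short.

## Thermoregulatory profile

Fits are pooled across birds (per-group fitting is available by
subsetting; pooling is the default because the emulated design found no
group differences before acclimation). Shapes are fixed a priori: MR has
two breakpoints with a horizontal middle segment (T_LC, T_UC, BMR); T_b,
EHL and EHL/MR have one breakpoint with a horizontal first segment.
`derive_profile` refuses fits of the wrong shape by name rather than
guessing.

EHL/MR is fitted directly on the per-observation ratio, not derived from
the MR and EHL fits — the ratio of two fitted piecewise functions is not
piecewise-linear and has no single well-defined inflection, whereas the
direct fit does. Note the fitted EHL/MR at the hottest exposure
(~1.15 on default synthetic data) is what the piecewise truth implies;
real birds show steeper terminal efficiency because both curves bend
upward near the thermal limit, a curvature the piecewise generator does
not emulate.

## Partitioning

Mask sessions produce two pull-mode lines: mask (respiratory water, plus
O₂/CO₂ so the restrained bird's MR comes along) and chamber (cutaneous
water only). Each line is inverted with the same mass balance; REHL and
CEHL follow by the latent-heat conversion, with TEHL = REHL + CEHL by
construction. The mask encloses the whole head, so "respiratory" water
includes head-skin and ocular evaporation; no correction is applied, and
no metabolic-water correction is subtracted either — both are semantic
caveats, not adjustable knobs. Summaries report means, medians and
quartiles per temperature stratum, and *two* aggregate cutaneous
contributions — the mean of per-bird fractions and the pooled
Σ CEHL/Σ TEHL — because the two answer different questions and differ
under among-bird heterogeneity.

## Repeatability

The ANOVA intraclass correlation: n₀ = (N − Σnᵢ²/N)/(a−1),
s²_A = (MS_A − MS_W)/n₀, τ = s²_A/(s²_A + MS_W), p from the ANOVA F.
Negative among-individual variance truncates to zero and is flagged.
Adjusted repeatability removes fixed effects (numeric covariates linear,
categorical factors dummy-coded; rank-deficient designs are refused) by
OLS and applies the estimator to residuals grouped by individual, with a
cluster bootstrap over individuals for the SE. A mixed-model (REML)
variance-components estimate is the natural alternative; the
residual-ANOVA estimator was chosen for dependency-free determinism, and
the test suite demonstrates agreement within 0.02 with statsmodels'
MixedLM on balanced designs. On strongly unbalanced designs the two can
diverge more; for such data prefer a dedicated mixed-model workflow.

## Synthetic-data generator

The generator emulates the study design the package targets: 36 birds in
four acclimation groups (8/10/9/9), T_a on a 22–44 °C grid at 0.5 °C
steps, two randomly chosen temperatures per bird per measurement day.
The number of days (6, giving 12 points per bird, 432 total) is the
package's own choice of a realistic campaign length; it is not varied per
analysis. Default truth: TNZ 34.87–37.47 °C, BMR 0.24 W, MR slopes
0.015/0.013 W °C⁻¹ below/above, T_b plateau 40.98 °C with threshold
35.94 °C and slope 0.43, EHL plateau 0.061 W with inflection 37.45 °C
and slope 0.045 W °C⁻¹.

Noise: residual SDs 0.020 W (MR), 0.30 °C (T_b), 0.008 W (EHL);
among-individual intercept SDs 0.016 W (MR) and 0.25 °C (T_b). These are
chosen so that (a) recovered breakpoint SEs at n = 36 are of the same
order as a real study of this size reports, and (b) the true intraclass
correlation of MR is 0.016²/(0.016²+0.020²) = 0.390. Noise is injected
on MR and EHL and the gas columns are then **back-computed from the noisy
values** (RER ~ U(0.75, 0.95), a plausible post-absorptive span), so
every generated row satisfies the calorimetry identities exactly — the
generator cannot hide unit errors. Identical seeds give byte-identical
tables.

What the generator does *not* emulate: curvature near the thermal limits,
acclimation-induced group differences (supported via per-group truth
overrides, not defaulted), temporal autocorrelation within a bird's day,
and heteroscedastic analyzer noise. Passing recovery tests therefore
demonstrates correctness of the estimation chain under the stated model,
not robustness to every feature of real data.

The trace generator builds analyzer readings with the forward mass
balance per 5-min dwell (reference every fourth dwell), optionally adding
affine drift and Gaussian sensor noise; gas concentrations step instantly
at valve switches, so the washout masking is exercised structurally
rather than dynamically. Mask-session truth defaults make the cutaneous
avenue carry ~61 % of total EHL at 25 °C and ~21 % at 40 °C with 20 %
lognormal among-bird variation.

## Problem sizes and determinism

The validation suite runs the full recovery pipeline at the study's
actual scale (36 birds, 432 observations) — small enough that the
complete test suite and the acceptance script each finish in minutes on
one CPU. The acceptance script reports point estimates without
bootstrap resampling (SEs are not among its outputs); the repeatability
target averages 20 replicate simulations. Every stochastic step takes an
explicit seed, and child seeds are spawned from a single generator so
results are reproducible for a given seed.
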
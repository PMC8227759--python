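# Methods

## Model

A compound's equilibrium constant measured at several temperatures is
modelled with a constant hydration heat capacity:

    R·lnK(T) = −ΔH_mot/T + (ΔS_mot − ΔCp_hydr) + ΔCp_hydr·lnT

This is the classical extended van't Hoff form, reparametrised so that
the coefficients are the *motive* enthalpy (the T → 0 intercept of the
dual enthalpy ΔH_dual = ΔH_mot + ΔCp·T) and the *motive* entropy (the
lnT → 0, i.e. T = 1 K, intercept of ΔS_dual = ΔS_mot + ΔCp·lnT). Those
extrapolation anchors are implicit in the parametrisation: no
extrapolation is ever performed numerically, the intercepts simply are
the fitted coefficients. For data measured above 273 K the distinction
between a 0 K and a 1 K anchor is immaterial at the resolution of the
fit.

Model assumptions, in decreasing order of importance:

1. ΔCp_hydr is independent of temperature over the measured range.
2. Errors live on lnK and are additive, homoscedastic and independent
   across temperatures (per-point weights are accepted for callers who
   know better, but no weighting scheme is applied by default).
3. Within a compound family the motive functions are linear in the
   water count ξ_w, with a common unitary slope.

The "thermal" remainder ΔH_th = ΔCp·T, ΔS_th = ΔCp·lnT is treated as a
compensative implicit-solvent contribution carrying zero free energy;
all free energy is motive, ΔG_mot = ΔH_mot − T·ΔS_mot. The algebraic
combination ΔH_th − T·ΔS_th = ΔCp·T·(1 − lnT) does not vanish, and is
therefore reported only as a diagnostic (`dG_th_algebraic`), never used
in any downstream computation. The related textbook stability-curve
expression is available as `eq7_thermal_term` under the same
diagnostic-only contract.

## Estimation and classification

The model is linear in its three parameters, so the fit is ordinary
least squares of R·lnK on the basis {1/T, 1, lnT} (statsmodels OLS/WLS;
at least four distinct temperatures required, and a column-normalised
condition number above 1e10 raises a singular-fit error rather than
returning garbage). Standard errors for (ΔH_mot, ΔS_mot, ΔCp) come from
the OLS covariance; ΔS_mot is a sum of two basis coefficients, so its
variance includes the covariance term. With exactly four points the fit
has one residual degree of freedom and results carry a `low_df` flag.

Thermal Equivalent Dilution then reads the water count off the
curvature: n_w = ΔCp_hydr / Cp_w with Cp_w = 75.3 J·K⁻¹·mol⁻¹ (liquid
water at 298 K; configurable in `ThermoConstants`, and every reported
ξ_w scales inversely with it). ξ_w = |n_w| is continuous —
pseudo-stoichiometric — and never rounded. Classification requires the
curvature to be resolved against its own uncertainty: Class A needs
ΔCp > +k·se, Class B needs ΔCp < −k·se, with k = 2 by default;
otherwise the compound is `indeterminate` (an effectively linear van't
Hoff plot). The measurements themselves give no criterion for k; 2
standard errors is the conventional two-sigma choice and is exposed as
a parameter.

R² is computed with a scale-aware zero test so that a constant-lnK
series (zero total sum of squares) reports a perfect fit rather than a
0/0.

## Family disaggregation and class comparison

Per-family, ΔH_mot and ΔS_mot are regressed on ξ_w by OLS. Two
compounds interpolate exactly (no standard errors); at least two
distinct ξ_w values are required, otherwise the regression is refused
(`SingularFitError`) rather than returning an arbitrary slope. The
class label follows the slope signs (A: both negative; B: both
positive); mixed signs yield `indeterminate` plus a structured
`SignConventionWarning` — never a silent relabel. The null-iceberg free
energy ΔG₀(T_ref) = ΔH₀ − T_ref·ΔS₀ is evaluated at a configurable
reference temperature (default 298 K).

Unitary slopes pooled within a class are summarised by mean, sample
standard deviation (n−1) and relative error 100·sd/|mean|. Because the
historical class means are not simple averages of the per-family values
and their weighting is unstated, `pool_unitary` reports both the simple
and the inverse-variance-weighted mean.

The A/B equal-magnitude decision uses the ratio

    r = ||mean_A| − |mean_B|| / 2 / sqrt(sd_A² + sd_B²)

accepted below a threshold of 2.0 by default (the historical analyses
accept ratios of 1.3 and 0.815 without stating a cutoff; 2.0 keeps the
two-sigma convention). This is deliberately *not* a textbook two-sample
t statistic — it reproduces the published arithmetic exactly — and a
conventional Welch t test (`welch_t_statistic`) is provided as a
labelled cross-check, not as the decision rule. Zero pooled sd with a
non-zero gap reports an infinite ratio and rejects.

## Derived quantities

`derived` works in the kJ convention of the published vector arithmetic
(unitary enthalpy kJ·mol⁻¹·ξ_w⁻¹, unitary entropy kJ·K⁻¹·mol⁻¹·ξ_w⁻¹),
with explicit converters to the SI-joule core. It composes iceberg
free-energy lines ΔG(T) = ξ_w·Δh − T·ξ_w·Δs, evaluates them pointwise,
inverts configurational entropy into an equivalent dilution
(N = exp(ΔS/R), x = N/N_Avo, with overflow guarded and x > 1 flagged
rather than clipped), and forms ergodic activities a = Φ·x with
Φ = T^(−Cp/R) and the quasi-chemical constants
K = a_A·a_B⁻¹·a_WII^(±ξ_w), the exponent sign chosen by the
dissociation/association mode mirroring the sign of n_w.

## Synthetic data

The generator is the exact forward model of the analysis: lnK(T) from
the dual function plus iid Gaussian noise on lnK, and families drawn
from the linear ξ_w laws plus compound-level Gaussian scatter on
(ΔH_mot, ΔS_mot). Defaults, chosen once: noise sd 0.02 on lnK; grid
273.15–373.15 K in 10 K steps (11 points, the liquid-water range);
scatter 2.0 kJ·mol⁻¹ / 15 J·K⁻¹·mol⁻¹, the order of the per-family
standard deviations seen in published compilations. Presets cover the
canonical families with their characteristic coefficient sets and ξ_w
ranges: gas dissolution (ξ_w 2–6), liquid dissolution (2.7–5.4),
carboxylic-acid protonation (1.8–2.3), protein denaturation (80–140)
and their Class B mirrors (micelles 4–19, protein folding,
deprotonation). The deprotonation preset stores the sign-reversed
protonation coefficients so that its slopes satisfy the Class B
convention. Seeds are mandatory; there is no global random state.

What the generator does *not* emulate — and hence what green tests do
not establish about real data: temperature-dependent ΔCp, correlated or
heteroscedastic measurement error, errors in the temperatures
themselves, uncertainty in ξ_w propagating into the family regression
(no errors-in-variables treatment), and family laws that are only
approximately linear. Recovery and coverage results are statements
about the model's self-consistency and the estimator's calibration
under its own assumptions.

## Numerical and testing choices

- Exact-recovery tests demand ≤ 1e−8 relative error on noiseless
  series; the OLS solution typically achieves ~1e−12 on the default
  grid.
- Confidence-interval calibration uses 200 replicates at noise sd 0.02
  (11 points each), asserting 90–99% coverage of the nominal 95%
  t-interval for ΔCp; replicate counts keep the whole suite under a few
  seconds on one CPU.
- Monotone-degradation and noise-spread checks use common random seeds
  across noise levels so the comparison is paired.
- Decomposition identities are asserted to within a few ulp of the
  additions that define them.
- Display rounding (1 decimal for percentages, 2–3 significant decimals
  for ratios and kJ values) is applied only in `*_display` fields and
  rendered reports; all stored numbers are full precision.

## Known limitations

- No temperature-dependent ΔCp variants, Bayesian fitting, or direct
  fitting of calorimetric traces: input is lnK(T) series only.
- ξ_w enters the family regression as a fixed regressor; its estimation
  error is ignored (attenuation bias is possible at high lnK noise).
- The equal-magnitude ratio has no exact sampling distribution here;
  it reproduces a published procedure, with Welch's t as the
  conventional alternative.
- Pipeline class summaries treat each family's slope as one value;
  with a single family per class the class sd is zero and the
  comparison degenerates accordingly.
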
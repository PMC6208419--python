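# Methods

## The compartment model and its variants

Every ROI is treated as one well-mixed compartment fed by its local artery.
Influx is first order in the arterial concentration `C_b(t) = C_0 e^(−k_in t)`
and efflux first order in the ROI concentration, giving

    dC/dt = k_in C_b(t) − k_out C,   C(0) = 0
    C(t)  = A (e^(−k_out t) − e^(−k_in t)),   A = k_in C_0 / (k_in − k_out).

The family has four members, selected per ROI class and route:

| variant      | form                      | parameters      | used for |
|--------------|---------------------------|-----------------|----------|
| double exp   | `A(e^(−k_out t)−e^(−k_in t))` | A, k_in, k_out | i.p. arms of heart/source-like/kidney ROIs; lymph nodes i.p. |
| washout      | `A e^(−k_out t)`          | A, k_out        | i.v. arms of heart/source-like/kidney ROIs; declining sink-like i.v. profiles |
| uptake       | `A(1−e^(−k_in t))`        | A, k_in         | sink-like ROIs without an elimination phase |
| excretion    | `U_t(1−e^(−k_u t))`       | U_t, k_u        | cumulative excreted activity, 100 − whole-body %ID |

Units are hours, 1/h, %ID g⁻¹ for tissue concentrations and %ID for
bladder/whole-body/excretion activities. The washout and uptake forms are
exact limits of the double exponential (`k_in → ∞` and `k_out → 0`), which
the tests verify numerically against an adaptive ODE integration of the
balance equation (DOP853, rtol 1e−10) and against quadrature for the AUC.

Assumptions worth keeping in mind: no organ-to-organ mass transfer is
modelled (each ROI sees only its arterial forcing); the heart ROI stands in
for plasma, so "systemic" parameters inherit any extravascular heart signal;
decay correction and dose normalisation happen upstream.

### Sink-like i.v. model choice

Whether a sink-like organ shows an elimination phase after an i.v. bolus is
an empirical matter (liver and spleen genuinely differ across particle
types). The rule used here: fit the washout model when the group-mean
concentration at the last imaging time is below the group-mean at the first
time, the saturating uptake model otherwise. A per-ROI variant override is
available in the pipeline configuration for cases where the analyst knows
better, and AICc is reported when degrees of freedom permit comparison.

### Degeneracy and the flip-flop convention

At `k_in = k_out` the macro-constant A is undefined; parameterisations with
`k_in − k_out < 1e−8 /h` are rejected rather than silently switched to the
confluent limit `A k t e^(−kt)`. The double exponential is invariant under
swapping the two rates with `A → −A`; the convention `k_in > k_out` (the
late phase is elimination) is enforced everywhere, implemented in the fit by
estimating the positive gap `dk = k_in − k_out` rather than `k_in` itself.

### Intraperitoneal initial concentration

Absorption from the peritoneum is approximated as constant-rate, so the
effective initial arterial concentration is the time-average of the linear
ramp: `C_avg = C_b^max / 2`. `C_0` is never fitted — the fitted scale is A,
and `C_0 = A (k_in − k_out)/k_in` is recoverable for reporting.

## Estimation

Per-subject nonlinear least squares by Levenberg–Marquardt (lmfit/MINPACK),
unweighted by default (optional `1/value²` weighting), with:

* data normalised internally by their maximum, making the amplitude
  estimate exactly scale-equivariant (absolute optimizer bounds would
  otherwise break homogeneity at the 1e−9 level);
* positivity floors on all parameters; `U_t ≤ 100 %ID` imposed lazily —
  the unconstrained optimum is accepted when it already respects the bound;
* up to 20 restarts from deterministically jittered starting values
  (log-uniform factors in [0.2, 5] from a fixed internal seed), triggered
  only when the first attempt fails, so fits are reproducible;
* starting values from log-linear regression (washout), half-rise time
  (saturating forms), and terminal-slope/peak heuristics (double
  exponential);
* tight MINPACK tolerances (ftol = xtol = 1e−13) so noiseless data are
  recovered to ~1e−15 and equivariance holds to 1e−10.

With the three-scan clinical design the double exponential has zero degrees
of freedom: the fit interpolates, standard errors are reported as
unavailable (not zero) and the fit carries an explicit warning. Group
summaries are per-subject means ± s.d. by default (matching how such
studies tabulate parameters); pooled fitting over all subjects' points is
available. Excluded subjects (flagged rows, e.g. subject motion or a
misplaced injection) never enter fits and are reported in summaries and in
the pipeline's record accounting.

Calibration, measured by the acceptance script at 5% proportional noise on
a 12-point grid over 100 subjects per variant: rate-parameter bias below
~1%, RMSE 3.5–8%.

## Derived quantities

AUC is analytic per variant (antiderivatives of exponentials), additive
over subintervals to 1e−10. Half-life is `ln 2 / k_out`; for the uptake
variant there is no elimination phase within the study window, so `t_half`
and `k_out` are reported absent with a reason, `C_max` as the asymptote A
and `t_max` as the horizon. Bioavailability is the dose-normalised
i.p./i.v. ratio of group-mean per-subject AUCs; doses default to 1 because
%ID-scaled data are already dose-normalised. ROI-to-heart ratios flag
zero-heart time points as undefined rather than dividing.

Power-law structure–activity fits use OLS of log AUC on log size
(statsmodels/scipy): exact for noise-free power laws and natural under
multiplicative noise; a nonlinear refit on the original scale is available
for sensitivity analysis. The size covariate is the TEM core diameter by
design (hydrodynamic diameter selectable via the design table column).
The CI for the exponent is the standard t interval on the log-log slope.
Group statistics are one-way ANOVA, Tukey HSD pairs, and unpaired t-tests
at α = 0.05, refusing degenerate inputs per affected test; no additional
multiplicity layer beyond Tukey is applied.

## The synthetic-data generator

The generator emulates the shape of the imaging experiments: a panel of
PEGylated mesoporous silica particles (core diameters ~32–142 nm, neutral
TMS and cationic PEI/QA coatings), i.v. and i.p. routes, n = 4 subjects per
arm, imaging at 0.5, 5 and 24 h (a 12-point dense grid is provided for
identifiability-sensitive work). Per-ROI generating kinetics are set near
the magnitudes such studies report — systemic half-life ≈ 7.8 h, liver and
spleen saturating within 24 h, brain and muscle at low %ID g⁻¹ — with
source-like ROIs sharing the heart's elimination rate (blood-pool
coupling), systemic/source amplitudes scaling as 1/size and sink amplitudes
as size, and the i.p. heart amplitude solved so the noiseless i.p./i.v.
AUC ratio is 72.8% at every size. These are fixture choices that make
synthetic studies *look like* real ones, not claims about any particular
dataset.

Noise is multiplicative Gaussian with cv = 0.05 by default (ROI
quantification error scales with signal), truncated at zero with the
truncation count recorded. All randomness flows from one integer seed
through numpy `SeedSequence` spawning, so identical configurations
regenerate studies bit for bit. `generate_sar_study` solves the heart
amplitude per size so the noiseless systemic AUC equals `λ·size^exponent`
exactly (AUC is linear in the amplitude at fixed rates); sink-like
amplitudes scale with the opposite sign.

What passing tests on synthetic data do not show: robustness to
non-multiplicative error (partial-volume effects, segmentation error,
motion), to model misspecification (real organs are not single well-mixed
compartments), or to inter-subject kinetic heterogeneity, which the
generator omits — subjects within an arm share identical generating
parameters and differ only in measurement noise.

## Problem sizes and numerical choices

The packaged simulations use 100 subjects per variant for estimator
calibration, 200 replicated four-size studies for CI coverage, and 1000
null simulations for ANOVA calibration — sizes at which the Monte Carlo
error of each summary is comfortably below the margins being checked.
Tolerances: ODE oracle rtol 1e−10/atol 1e−13; quadrature 1e−12; rate-gap
degeneracy threshold 1e−8 /h; positivity floor 1e−12. Ties in the
half-rise starting-value heuristic resolve to the earliest qualifying time
point; all-zero series are refused at the starting-value stage with an
explicit error.

## Known limitations

* No population (mixed-effects) estimation; per-subject fits only.
* No kidney-mechanism modelling (glomerular filtration vs label
  degradation is not distinguished) and no bladder kinetic model.
* Power-law correlations are interpolative over the fitted size range;
  the machinery makes no claim below ~5.5 nm (renal-clearance regime) or
  far above the largest fitted size.
* Three-point designs leave the double exponential exactly identified:
  parameters are reported but carry no within-subject uncertainty.
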
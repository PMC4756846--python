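# Methods

## Models

**Four-parameter logistic (4PL).** Univariate dose-response slices are
modelled as `y(x) = y0 + (ymax − y0)/(1 + (EC50/x)^n)`. This
parameterization — rather than the equivalent log-EC50 form — is used
because induction matrices include zero-inducer rows and columns, and this
form is defined by continuity at `x = 0` with `y(0) = y0` exactly, so
basal cells enter the fit directly without pseudo-concentration
substitution. The model is restricted to activating curves
(`ymax > y0`); inhibitory data are not silently reparameterized — the
fitted span is bounded at zero and a spanless fit is reported as not
converged. Derived quantities are analytic: `ECq = EC50·(q/(1−q))^(1/n)`
and `DRLR = EC90/EC10 = 81^(1/n)`, a function of the Hill coefficient
alone.

**Leaky AND gate.** The bivariate surface is
`y(I,P) = y0 + Δy·H(I;K1,n)·[f1 + (1−f1)·H(P;K2,n)]` with Hill occupancy
`H(x;K,n) = x^n/(K^n + x^n)` (defined 0 at `x = 0`). This is the unique
product-of-Hills form satisfying the three anchor identities that define
the gate: output `y0` with neither inducer, `y0 + Δy` under dual
saturation, and `y0 + f1·Δy` under saturating I alone. A single Hill
coefficient is shared between the axes by default, reflecting that a
cascade output is reported through one reporter; a per-axis coefficient
(`shared_n=False`) is available where the two layers visibly differ in
steepness. The surface is monotone nondecreasing in both inducers by
construction.

A note on finite "saturation": with concentrations at 10^6×K the dual
anchor holds to absolute 1e-9 (on a unit-span gate) only for Hill
coefficients ≳ 1.5, since the occupancy deficit is ≈ (10^-6)^n. Tests
therefore verify the anchors exactly in the saturating limit and at
10^6×K with a steep coefficient.

## Fitting

Both fits minimize unweighted least squares on raw RFU/OD with every
replicate as an observation (pooling preserves degrees of freedom for the
curvature-based standard errors; means are taken only at reporting time).
An optional `1/y` weighting serves variance-proportional noise. The
optimizer is bounded Levenberg–Marquardt (lmfit); the span `Δy` (and
`ymax − y0`) is bounded at 0, Hill coefficients at [0.05, 50], EC50s
strictly positive, `f1` in [0, 1].

Starts are deterministic and data-driven so fits are reproducible:
basal ← grid minimum, span ← grid range, EC50/K ← geometric median of the
nonzero levels, plus a multi-start grid over `f1 ∈ {0.01, 0.1, 0.5, 0.9}`
× `n ∈ {0.5, 1, 2}` (and a corner-derived `f1` start,
`(y(I_max,0) − y0)/(y(I_max,P_max) − y0)` clipped to [0.01, 0.99]). The
lowest-RSS start wins; ties break toward the lower Hill coefficient.
A fit with `f1` at the upper bound flags `K2` and the P-axis response as
unidentifiable. Standard errors come from the Gauss–Newton covariance at
the optimum; no bootstrap is attempted.

**Contours.** Iso-response lines at normalized level `q` (fraction of Δy
above basal) are solved analytically: at each log-spaced I grid point,
`H(P) = (q/H(I) − f1)/(1 − f1)` gives P where that value lies in (0, 1);
grid points where the level is unreachable, or already exceeded at
`P = 0` through the `f1` leak, are omitted. The symmetric P→I branch is
merged in so near-vertical and near-horizontal contour segments are both
sampled. Every returned point re-evaluates to its level within 1e-6.

**Numeric DRLR.** For curve shapes that are not exact logistics (e.g.
gate slices at sub-saturating co-inducer), EC10 and EC90 are found by
bracketed root-finding (Brent) on the normalized curve with interval
expansion; monotonicity is checked on a probe grid first.

## Logic and summary statistics

D-OUT digitizes the four corner states at a threshold (default 10%) of
the basal-subtracted dual-induced output; A-OUT is the basal-subtracted
synergy ratio `(IP − UU)/((I − UU) + (P − UU))`. Basal subtraction is the
default because without it a leaky system trivially approaches A-OUT = 1
and the classification is dominated by basal signal; a no-subtraction
mode (`subtract_basal=False`) is provided for comparison with
conventions that skip it. For a strict gate whose single-inducer outputs
do not exceed basal, A-OUT is undefined; `truth_table` reports it as
infinite while `a_out` alone raises. Gate labels come from the canonical
two-input truth-pattern dictionary (AND, OR, I-only, P-only,
constitutive, dead; anything else "other"). The matrix-wide "maximum" in
induction summaries is the highest cell mean wherever it sits, not an
assumed corner.

## Kinetics and quantitation

Expression accumulation is fitted linearly (OLS of RFU/OD vs time) over a
0–5 h default window; r² is reported so plateauing kinetics are visible,
and the window is adjustable rather than the model made saturating.
Growth is log-linear OLS of ln OD600; non-growing cultures get a
declining-culture flag and an unbounded doubling time instead of a
negative one.

The two-stage calibration fits straight lines with intercept (a
through-origin option exists) and predicts by inverting the forward
regression, so exact linear inputs round-trip exactly. Conversion of a
specific rate (RFU/OD/h) to volumetric productivity treats the RFU→ng
slope as per ml of culture at the measured OD — the per-ml convention —
giving `mg/l/h = rate · OD · (ng/RFU) / 1000`. How OD-normalized sample
volumes map a per-OD fluorescence onto absolute mass is genuinely
underdetermined by typical protocols, so conversions outside the
calibrated standard range (70–500 ng by default) are flagged
`extrapolated` rather than refused.

## Cytometry

The default gate is the 99.5th percentile of an uninduced reference
sample — deterministic, and by construction at most 0.5% of a
reference-like population gates fluorescent. Without a reference, the
threshold is the kernel-density valley between the two dominant modes of
log10 fluorescence; modes below 5% of the peak density are ignored and a
valley that does not dip below 90% of the smaller mode is rejected as
unimodal rather than guessed at. CVs are computed on the linear scale
(matching percent-CV reporting conventions); subpopulation percentages
are computed so the two gates sum to 100 exactly.

## Synthetic data

Generators emulate: plate-reader induction matrices (AND-gate means, by
default zero plus 8 log-spaced levels spanning 0.01–100× each K, three
replicates), expression/growth time courses (exponential OD, linear
RFU/OD), lognormal-mixture cytometry samples (100 000 events by
default), and two-stage calibration tables (standards spanning
70–500 ng). The default noise model is mean-preserving multiplicative
lognormal with CV 5%, reflecting plate-reader replicate scatter that
grows with signal; additive Gaussian and noiseless modes exist. All
generators are bit-reproducible under a fixed seed.

What the generators do **not** emulate — and hence what passing recovery
tests do not show about real data: systematic (non-mean-zero) instrument
drift, OD-dependent fluorescence quenching, inducer toxicity feeding back
on growth, autofluorescence spectra, cytometry doublets/debris, and
model misspecification (real surfaces need not be product-of-Hills).
Recovery results certify the estimators, not the biology.

## Problem sizes and tolerances

Noiseless recovery experiments use 12×12 grids (11 log-spaced levels plus
zero per axis) where parameters are recovered to ≪0.1%; noisy recovery
uses 5% CV, 3 replicates and 50 random draws with a median-relative-error
< 10% criterion per parameter. 4PL fits require ≥5 distinct
concentrations; global fits ≥4 levels per axis and >8 observations.
Convergence is lmfit's Levenberg–Marquardt default with a generous
evaluation budget (several thousand); contour points are verified to
1e-6 normalized, closed-form vs numeric DRLR to 1e-8 relative.

## Known limitations

* The AND-gate fit assumes a shared Hill coefficient by default; strongly
  mismatched layer steepness biases `n` toward a compromise value.
* A flat titration slice with noise can converge to a spurious steep
  logistic riding the noise (visible as an extreme EC50 outside the
  tested range); inspect `warnings`, standard errors and the global fit
  rather than single flat slices.
* Standard errors are curvature-based and understate uncertainty near
  parameter bounds (notably `f1 → 0` or `1`).
* DRLR is reported from fitted curves, not raw-data interpolation.
* FCS binary parsing is out of scope; event tables are expected as CSV.
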
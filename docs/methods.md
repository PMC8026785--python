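# Methods

`petkin` quantifies the brain pharmacokinetics of a reversible PET
radioligand (the package was built around an SV2A tracer workflow in the
non-human primate, but nothing in the code is tracer-specific) from regional
time–activity curves (TACs) and arterial blood data. This note documents the
models, the numerical choices, and what the synthetic data generator does and
does not emulate.

## Input function

Total plasma activity is corrected for radiometabolites by multiplying it
with the intact-parent fraction

    pf(t) = A1·exp(−λ1 t) + (1 − A1)·exp(−λ2 t),      pf(0) = 1,

fitted to the HPLC parent-fraction measurements by uniform-weight least
squares on the fraction scale. The intercept constraint is enforced by the
A2 = 1 − A1 reparameterization: at injection the circulating activity is by
definition all parent. The fit uses a multi-start over eight log-spaced
(λ1, λ2) pairs (λ ∈ [10⁻³, 5] min⁻¹) because the biexponential objective has
local minima when the two rates approach each other; the lowest-RSS converged
start wins and components are reordered so λ1 ≥ λ2. Fewer than four samples
is an error; non-convergence raises an error carrying the best candidate.

Between blood samples the input function is linearly interpolated; before
the first sample it rises linearly from (0, 0). It is undefined beyond the
last sample — fitting frames outside the sampled window is a domain error
rather than an extrapolation. All times are minutes post injection and all
activities are assumed decay-corrected to injection time.

The plasma free fraction is the ultrafiltrate/plasma count ratio (mean and
SEM over replicates); the tissue free fraction is f_ND = f_p / V_ND.

## Compartment models

The reversible two-tissue model (rate constants K1 [mL/cm³/min], k2, k3, k4
[1/min]) has the analytic solution

    C_T(t) = [φ1 e^(−θ1 t) + φ2 e^(−θ2 t)] ⊗ C_p(t)

with θ1,2 = ((k2+k3+k4) ± √((k2+k3+k4)² − 4 k2 k4))/2 and φ coefficients as
implemented in `kinetic._impulse_terms`; the one-tissue model is the
k3 = k4 = 0 special case. The convolution is evaluated exactly for the
piecewise-linear input on a uniform grid (Δt = 0.05 min) via a first-order
recursion implemented as an IIR filter, then averaged over each frame —
frame values are duration averages, not midpoint samples. Agreement with an
independent stiff ODE integration of the mass balance is ≤ 0.1 % of the curve
peak (tested over 50 random admissible parameter sets).

A fractional blood volume term vB is supported
(measured = (1−vB)·C_T + vB·C_wb) but fixed at 0 by default; none of the
shipped analyses fit it.

**Weights.** w_i ∝ frame duration / max(activity, ε), with ε = 1 % of the
curve maximum to guard near-zero frames — approximate count statistics
(frame variance ∝ activity/duration). The AIC *comparison* between models is
invariant to rescaling all activities when weights rescale accordingly.

**Optimiser.** Bounded multi-start nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with bounds
K1 ∈ (0, 2], k2 ∈ (0, 1], k3, k4 ∈ [0, 1] min⁻¹; ten deterministic starts
from a seeded Latin hypercube (log-scaled) plus one mid-range start at
typical grey-matter kinetics. Ties break on lowest weighted RSS. A k4
estimate below 10⁻⁴ min⁻¹ (e-folding far beyond any scan) is snapped to the
bound and reported as the irreversible limit: converged, but BP_ND and V_T
undefined rather than infinite. This mirrors the instability of slow-k4
tracers, where k4 collapses toward zero in a substantial fraction of fits.

**Uncertainty.** The covariance is the Gauss–Newton (J′WJ)⁻¹ at the optimum
scaled by the reduced chi-square; %SE = 100·SE/estimate. Macroparameters
V_ND = K1/k2, BP_ND = k3/k4, V_T = V_ND(1+BP_ND) get delta-method SEs. An
estimate is *reliable* when the %SE of V_T is below 25 %; only reliable
estimates enter reliability summaries.

**AIC.** AIC = n·ln(RSS/n) + 2k on the weighted RSS, for ranking 1T vs 2T.

**Coupled fit (2TCM-c).** All regions are fitted simultaneously with a
single shared V_ND; the parameter vector is {V_ND} ∪ {K1, k3, k4 per region}
and each region's k2 is K1/V_ND — the coupling is on the K1/k2 *ratio*, not
on k2 itself, so regions may differ in perfusion while sharing the
non-displaceable partition. The joint covariance propagates the shared
parameter's uncertainty into every region's %SE via the (V_ND, K1) → k2
transformation.

## Graphical analysis

Logan analysis regresses ∫₀ᵗC_T/C_T against ∫₀ᵗC_p/C_T by ordinary least
squares over frames with mid-time ≥ t* (default 60 min); the slope is V_T.
Tissue integrals are trapezoids over frame mid-times with a (0, 0) anchor;
plasma integrals are exact integrals of the interpolated input. Frame time
for the t* threshold is the frame mid-time. MA1 is the multilinear
rearrangement C_T = β1·∫C_p + β2·∫C_T (no intercept), V_T = −β1/β2, which
trades the Logan noise-induced negative bias for a smaller one. Plain OLS is
used for both — standard practice absent a stated weighting. Non-positive
tissue values inside the window are excluded with a warning; fewer than
three usable late frames is an error.

On noiseless reversible TACs the Logan slope is within ~1 % (one-tissue,
exact linearity) to ~3 % (two-tissue at t* = 60 min) of the true V_T, and
the residual linearization bias shrinks monotonically as t* grows.

## Reliability

aTRV = 100·|test − retest| / mean(test, retest); region summaries average
per-subject aTRV over subjects with both sessions reliable (not the aTRV of
region means). ICC comes from the two-way (subject × session) mixed-model
mean-squares decomposition; the default flavor is single-measure absolute
agreement ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), with
consistency ICC(C,1) behind a switch, because "two-factor mixed model" does
not pin down the variant. Degenerate variance (all cells equal) or fewer
than two complete pairs yields NaN with a warning, not a number.

## Displacement and occupancy

SUV(t) = C(t)[kBq/cc] / (injected dose [kBq] / body weight [g]). Each curve
is normalized to the last frame ending at or before the drug time (90 min in
the emulated design — the frame immediately preceding administration);
baselines are averaged pointwise *after* normalization; percent displacement
is 100·(B − D)/B at the frame covering the chosen post-drug time. Default
readouts: 35 min post drug for a fast-penetrant competitor, 150 min for a
slow one.

Occupancy arithmetic uses the single-site isotherm occ = C/(C + K_D); a
maximal displaceable fraction f of total uptake implies BP_ND = f/(1 − f),
the inverse of the specific fraction V_S/V_T = BP/(1+BP). Concentration
units are taken exactly as given (the functions are unit-agnostic as long as
C and K_D match); no silent rescaling is performed.

## Synthetic data generator

The generator emulates the study design the analysis assumes: 7 regions
(6 grey + white matter) sharing V_ND = 7.89 mL/cm³, grey-matter
K1 = 0.37 mL/cm³/min (white matter 0.30), regional k3/k4 spread
{1.19, 1.10, 1.15, 0.95, 1.07, 1.00, 1.03} averaging exactly 1.07,
k4 = 0.028 min⁻¹; a 2-h schedule of 36 frames (15 s early frames coarsening
to 5 min) extendable to 4 h with 10-min frames; 28 arterial samples over 2 h
(15 in the first 5 min, then every 5 and every 10 min) and 34 over 4 h;
parent-fraction truth (A1, λ1, λ2) = (0.7, 0.08, 0.005); and a constant
plasma/whole-blood ratio of 0.90.

The plasma shape — a linear rise to a peak at 1 min followed by a
three-exponential washout (fractions 0.72/0.20/0.08 at rates
1.5/0.2/0.004 min⁻¹) — is invented: no analytic form is available for the
measured input. It was chosen so the regional TAC peak lands in the 5–15 min
window the design describes. TAC noise is zero-mean Gaussian with
sd = σ·√(activity/duration); test and retest differ by the noise
realization and a small multiplicative session K1 perturbation applied at
fixed k2 (so it propagates to V_T like a physiological delivery change).
Between-subject variability is lognormal on K1, V_ND and BP_ND.

The default noise σ = 1.5 was set so the seeded test–retest battery lands
region-mean Logan aTRV inside the 5–20 % band while the Logan vs coupled-fit
V_T correlation across the battery stays high (R² ≈ 0.9) and some
single-region 2T fits fall near the 25 %SE reliability threshold — the
instability phenomenology the coupled fit exists to repair. These demands
pull against each other (frame noise large enough to dominate V_T
variability destroys the cross-method correlation), so σ favors the
asserted invariants; the session-level K1 effect (sd 4 %, clipped at ±5 %)
supplies the rest of the between-session V_T variability. The
between-subject V_ND spread (lognormal, 20 % CV) is the conservative end of
the dispersion implied by a non-displaceable volume of 7.89 ± 1.23 (SEM,
4 animals → between-animal SD ≈ 2.5 mL/cm³).

Displacement arms integrate the mass balance numerically with a
time-varying k3(t) = k3·(1 − occ(t)) (LSODA, rtol 1e-8), occ(t) being an
instant or one-exponential rise after the drug time. With full occupancy
the displaceable fraction of the signal is BP/(1+BP) ≈ 51.7 % *at transient
equilibrium*. The full-blockade check reads the displacement ≈ 2.5
bound-pool time constants (2.5/k4 ≈ 89 min) after the drug: earlier the
bound pool has not emptied; later the slowly decaying input makes the
two-tissue baseline lag equilibrium progressively more than the displaced
one-tissue curve, and the measured displacement drifts above the
equilibrium value (≈ 60–65 % by end of a 4-h scan). That drift is a real
feature of the (B−D)/B readout under a decaying input, not an artifact.

What the generator does **not** emulate: voxel-level noise and its regional
covariance, scanner resolution and partial-volume spill-in (the emulated
white matter is a clean region, unlike real data), metabolite-assay and
blood-sampling measurement error, and any between-session structure beyond
the K1 shift. Passing tests therefore demonstrate correctness of the
estimators under the assumed data-generating process, not robustness to
every artifact of acquired data.

All stochastic outputs are derived from `numpy` generators keyed by
(seed, subject, stream); identical config + seed regenerates bit-identical
tables.

## Problem sizes

Default analyses use the 2-h schedule (36 frames, 28 blood samples), 7
regions, 4 subjects × 2 sessions; Monte-Carlo checks use 20–50 seeded
replicates. A full noiseless 7-region coupled fit takes a few seconds; the
complete seeded battery (fits for all subjects and sessions) runs in about
a minute on one core.

## Known limitations

* The Gauss–Newton covariance understates uncertainty when the optimum sits
  on a bound (k4 = 0); such fits are flagged rather than given SEs for
  BP_ND/V_T.
* The coupled fit assumes a common V_ND; when regions genuinely differ the
  misfit shows up as inflated joint residual (tested), but no automatic
  diagnostic is emitted.
* Logan/MA1 integrals use the native frame sampling; very coarse late frames
  would bias the integrals, though not at the shipped schedules.
* The displacement readout depends on the post-drug evaluation time under a
  decaying input, as discussed above.
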
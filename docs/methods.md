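# Methods

## Protocol and timing model

All times are minutes from the first injection; frame intervals are
half-open `[start, start + duration)`.  The canonical 60-min simulation
schedule has 50 frames (3×20 s, 4×30 s, 3×60 s, 22×90 s, 3×60 s, 3×20 s,
4×30 s, 3×60 s, 2×90 s, 3×180 s; exactly 60 min) and four windows:
validation [0, 36), late brain [36, 39), cardiac [39, 48), early brain
[48, 60).  Injections are at 0, 42.5 and 49 min with equal dose
fractions; the fractions are configurable (and deliberately not forced
to sum to one) so that the effect of unequal dose splits can be
explored.  The second injection falls inside a 20-s cardiac frame by
design — the short frames exist to catch the second activity peak.

## Input-function model

The plasma input uses the third-order Feng form with amplitudes A1, A2
(kBq/ml) and rates μ1 > μ2 (1/min); the multi-bolus curve is the exact
closed-form sum of dose-fraction-weighted, time-shifted copies.  No
decay term appears anywhere: all activities are assumed
decay-corrected, as reconstruction pipelines do.  Population shape
values A1 = 263 ± 120, A2 = 16 ± 1.32, μ1 = 3.56 ± 1.31,
μ2 = 0.029 ± 0.012 drive the simulation designs.

Measured PET frames are means over the frame interval, not point
samples, so model curves are always compared with data through frame
averages.  Direct input sampling integrates each frame by trapezoid on a
0.01-min sub-grid; convolution-based tissue curves live on a uniform
grid with step 1/150 min (0.4 s).  That step was chosen because it
divides every canonical frame duration *and* the injection times, so
frame boundaries and input kinks land exactly on grid points; 0.01 min
does not divide a 20-s frame.

## Tissue model

The irreversible 2TCM (free + phosphorylated pools, k4 = 0) with a
plasma volume fraction vb gives the measured concentration

    C_T(t) = (1 − vb)·(h ⊗ Cp)(t) + vb·Cp(t),
    h(t) = K1k2/(k2+k3)·e^(−(k2+k3)t) + K1k3/(k2+k3).

vb is fixed at 0.03 in simulation and fitting alike (the same quantity
is sometimes written v_p for the plasma pool).  The exponential
convolution is evaluated with an exact trapezoid recursion (a
first-order IIR filter), which an independent stiff-ODE integration of
the compartment system confirms to < 0.5 % per frame across all 27
simulated parameter combinations.  Degenerate k2 + k3 = 0 uses the
analytic kernel limit (a constant K1) in the forward model, while the
net influx rate Ki = K1k3/(k2+k3) deliberately raises there — the
quantity is undefined.

The Patlak transform plots C_T(t)/Cp(t) against (∫₀ᵗ Cp)/Cp(t) at frame
midtimes; the integral runs from time zero (the first injection, where
plasma activity is zero) by trapezoid over the midpoint samples.  Frames
with non-positive plasma are excluded with a warning.  Patlak fitting
uses ordinary linear least squares on points with midtime ≥ 15 min, the
pseudo-equilibrium region of this protocol.

## Noise model

Simulated frames receive independent Gaussian noise with
SD = c·√(C/Δt): variance proportional to activity, inversely
proportional to frame duration in minutes, with the unitless level c.
Canonical levels are c ∈ {0, 0.15, 0.6} for input-function curves and
c ∈ {0.1, 0.4} for tissue curves.  Negative noisy values are kept —
clipping would bias low-activity frames — and the estimators tolerate
them.  Every stochastic operation takes an explicit seed;
(combination, noise-level) cells of the studies draw from independent
substreams of the master seed, so results are order-insensitive and
bit-reproducible.

## Estimators

Nonlinear fits use bounded trust-region least squares
(`scipy.optimize.least_squares`, method `trf`) with analytic Jacobians,
unweighted residuals, step/cost/gradient tolerances of 1e-8 and an
iteration cap of 500.  Classic Levenberg–Marquardt cannot honour the box
bounds the protocol calls for; the trust-region reflective variant is
the standard bounded equivalent.  Non-convergence is flagged on the
result object, never raised.

Bounds follow a [0.5 × smallest, 2 × largest] convention around the
values each simulation uses: A1 ∈ [71.5, 766] kBq/ml,
A2 ∈ [7.34, 34.6] kBq/ml, μ1 ∈ [1.125, 9.74]/min,
μ2 ∈ [0.0085, 0.082]/min for the input function, and
K1 ∈ [0.025, 0.2] ml/g/min, k2 ∈ [0.025, 0.5]/min,
k3 ∈ [0.01, 0.08]/min for the tissue fit.  (Human-style input fitting
with A1 constrained to 300–800 kBq/ml is available through the bounds
argument / CLI config.)  Initialisation, unstated in the source
protocol, is the bound midpoint for the input function and
(0.1 ml/g/min, 0.1/min, 0.05/min) for the tissue model; on noiseless
data both fits recover the generating parameters to ≤ 1e-6 relative,
and initialising at the truth does not change the noisy-fit optima, so
the results are not initialisation artifacts.

In the tissue-recovery study the input function handed to the 2TCM fit
is not the truth: it is re-estimated from noiseless cardiac-window
samples of the mean-parameter triple-injection curve, mimicking the
protocol pathway (the study adds noise only to tissue curves, and the
noiseless input fit is exact in any case).

## Monte-Carlo studies

*Input-function recovery:* 81 curves (mean and mean ± SD per Feng
parameter), each fitted from the 13 cardiac-window frames; accuracy is
judged on the full 0–60 min curve at the 50 frame midtimes with the
AUC error (mean signed percentage area error over repetitions; an
absolute variant averages |per-repetition| errors and is what the pooled
tables report per combination) and the NRMSE (per-point relative errors,
root-mean-squared per repetition, averaged over repetitions).  Default
1000 repetitions per cell; the packaged studies and acceptance runs use
200, whose sampling error is well inside the reported spreads.  A
noiseless cell is deterministic and runs once.

*Kinetic recovery:* 27 tissue curves (K1 ∈ {0.05, 0.075, 0.1} ml/g/min,
k2 ∈ {0.05, 0.15, 0.25}/min, k3 ∈ {0.02, 0.03, 0.04}/min, vb = 0.03),
fitted either from both short-window segments (36–39 + 48–60 min) or
from 48–60 min only (the window-ablation case).  Reported per parameter
and noise level: mean and SD of estimates, relative error of the mean,
and CV, per cell and pooled over cells.

### What this design can and cannot achieve

The frame noise model fixes the attainable precision.  Writing the
Fisher information of the 7-frame short-window design at the central
combination (K1 = 0.075, k2 = 0.15, k3 = 0.03), the Cramér–Rao bounds on
the CVs are ≈ 14 % (K1), 35 % (k2) and 44 % (k3) at c = 0.1, and ≈ 56 %,
139 % and 176 % at c = 0.4 — and total information over a fixed window is
invariant to how the window is cut into frames, so no re-framing evades
this.  An estimator with that much variance on a bounded, strongly
nonlinear model necessarily shows mean biases of order tens of percent
at the high noise level, which is exactly what the study measures
(e.g. pooled mean relative error of k2 ≈ +58 % at c = 0.4, ≈ +14 % at
c = 0.1, with Ki far more stable at ≈ −3 to −8 %).  Claims of
few-percent mean accuracy for the micro-parameters at these noise levels
are not attainable in this design; Ki, the macro-parameter, is the
robust quantity — consistent with the window-ablation result, where
dropping the 36–39 min frames inflates the micro-parameter CVs
(K1 17→23 %, k2 41→49 %, k3 50→69 % at c = 0.1) while moving Ki's mean
error by only a fraction of k2's shift.

## Phantom and voxel-wise pipeline

The synthetic dynamic phantom is a scaled-down ellipsoidal brain on a
48×48×24 grid at the protocol's reconstruction voxel size
(1.028 × 1.028 × 2.02 mm): a gray-matter shell split into four sectors
with region-typical parameters spanning reported human ranges
(K1 0.07–0.10 ml/g/min, k2 0.11–0.16/min, k3 0.04–0.05/min), a
white-matter core (0.05, 0.07, 0.03), a zero-uptake CSF ventricle, and a
separate 10-mm left-ventricle sphere carrying the pure plasma input.
Every voxel of a region holds the region's noiseless model curve; frame
noise is drawn per voxel and frame.  The geometry is miniature but the
voxels are full size, so the 4.11-mm 2D in-plane Gaussian smoothing of
the image pipeline (σ = FWHM/2.355 per in-plane axis, reflective
boundaries, never across slices) has a realistic width relative to the
voxel grid.  Independent resolution components combine as
root-sum-of-squares; for the protocol's chain (4.37, 2, 4.11 mm) the
formula gives 6.32 mm.

Voxel-wise mapping fits the short-window 2TCM per masked voxel (LV data
are never smoothed — only brain images are) and assembles K1/k2/k3/Ki
maps plus residual and convergence grids; a vectorised Patlak-slope map
from the validation window provides the cross-check.  On the noiseless
phantom the round trip recovers the generating maps to well under 1 %;
on the c = 0.1 phantom, smoothed as in the pipeline, short-window Ki
correlates with validation-window Patlak Ki at r ≈ 0.96 across tissue
voxels.

What the phantom does *not* emulate: scanner resolution/partial-volume
blur in the generated data (regions are piecewise constant), motion,
attenuation/scatter residuals, spatially correlated reconstruction
noise, and anatomical variability.  Passing phantom tests therefore
validates the estimation chain, not scanner physics.

## Numerical and design choices

* Grid step 1/150 min for convolution/frame averaging (commensurate
  with all frame boundaries); 0.01 min for direct input sampling.
* Trapezoid quadrature throughout; the exponential-kernel convolution
  recursion is exact trapezoid quadrature, O(n).
* Metric evaluation grid: the 50 frame midtimes (n in the NRMSE is the
  number of sampled time points); the t = 0 point is never on the grid,
  so the zero plasma value at injection cannot divide a metric.
* Ties/degeneracies: exactly-zero truth points are excluded from NRMSE
  with a warning; Patlak points with non-positive plasma are dropped
  with a warning; k2 + k3 → 0 at a 2TCM optimum flags the fit and
  leaves Ki undefined.
* Parametric maps store NaN outside the mask; per-voxel fit failures
  are recorded in the convergence grid.

## Known limitations

* The micro-parameter accuracy of the short-window design is noise-
  limited (see the Cramér–Rao analysis above); at c = 0.4 only Ki is
  recovered with small mean error.
* The fitted input function extrapolates the 0–36 min validation window
  from the 39–48 min fit; its accuracy there rests on the Feng form
  being correct.
* No dispersion/delay correction between the left ventricle and brain,
  no metabolite or whole-blood-to-plasma correction, no reversible
  (k4 > 0) model.
* Label maps replace atlas co-registration; images are assumed
  axis-aligned with the label grid.
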
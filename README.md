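# petkin

Kinetic modeling for a triple-injection, short-window dynamic
<sup>18</sup>F-FDG PET protocol.

Parametric FDG PET estimates the rate constants of glucose uptake from a
dynamic scan, but routine use is blocked by hour-long acquisitions and
the need for an arterial input function (AIF).  A triple-injection
protocol addresses both on a standard field-of-view scanner: the tracer
dose is split into three equal boluses (at 0, 42.5 and 49 min), the
subject rests outside the scanner for 36 min, and a single 24-min
acquisition then covers a late brain window (36–39 min), a 9-min cardiac
window (39–48 min, spanning the second bolus) and an early brain window
(48–60 min, spanning the third).  The cardiac window alone determines
the whole input function; the two brain windows determine the tissue
kinetics.

`petkin` implements the protocol's full computational chain plus the
Monte-Carlo simulation studies that motivate it:

* **Input function.** Third-order Feng model
  `f(t) = A1·t·e^(−μ1 t) + A2(e^(−μ2 t) − e^(−μ1 t))`, convolved in
  closed form with the three-bolus impulse train; bounded nonlinear
  least squares recovers (A1, A2, μ1, μ2) from frame-averaged samples of
  the 39–48 min window only.
* **Tissue model.** Irreversible two-tissue compartment model (2TCM)
  with fixed plasma volume fraction v<sub>b</sub> = 0.03:
  `C_T = (1−vb)·[(K1k2/(k2+k3))·e^(−(k2+k3)t) + K1k3/(k2+k3)] ⊗ Cp + vb·Cp`,
  fitted to the 36–39 + 48–60 min frames; the net influx rate is
  `Ki = K1·k3/(k2+k3)` (ml/g/min).
* **Patlak analysis.** Linear estimation of Ki from the
  pseudo-equilibrium portion (≥ 15 min) of the validation window, used
  to cross-check the short-window estimates.
* **Noise model and studies.** Frame noise `C + η·c·√(C/Δt)`;
  Monte-Carlo recovery studies over 81 input-function shapes and 27
  kinetic-parameter combinations, scored with AUC error, NRMSE, relative
  error and CV.
* **Imaging.** Voxel-wise parametric mapping (K1, k2, k3, Ki maps),
  label/spherical ROI extraction, 2D in-plane Gaussian smoothing, and a
  synthetic dynamic brain + left-ventricle phantom generator with ground
  truth, in NIfTI with CSV/JSON sidecars.

## Worked example

Simulate a noiseless tissue curve for the canonical protocol and recover
its parameters from the 24-min short window alone:

```bash
petkin simulate-tac --k1 0.075 --k2 0.15 --k3 0.03 --noise 0 --out tac.csv
petkin fit-tac --tac tac.csv --out fit.json
```

`fit.json` (abridged):

```json
{
 "K1": 0.0750000000000172,
 "k2": 0.15000000000018063,
 "k3": 0.030000000000056717,
 "Ki": 0.012500000000010015,
 "converged": true
}
```

The fit sees only the 36–39 and 48–60 min frames yet recovers the
generating values (K1 in ml/g/min; k2, k3 in 1/min) to machine-level
accuracy, and Ki = 0.075·0.03/0.18 = 0.0125 ml/g/min follows from the
estimate.  With realistic cardiac-window noise the input function is
still recovered well:

```bash
petkin simulate-aif --noise 0.15 --seed 7 --out aif.csv
petkin fit-aif --tac aif.csv --out aif_fit.json
```

gives A1 = 311.6 kBq/ml, A2 = 16.8 kBq/ml, μ1 = 3.92/min,
μ2 = 0.0323/min (truth: 263, 16, 3.56, 0.029) — a single noisy
9-min-window realization whose regenerated 0–60 min curve deviates from
the truth by a few percent in area.  The population-level behaviour is
what the studies quantify:

```bash
petkin study aif --reps 200 --seed 1 --out-dir results/aif_study
```

reports, across the 81 input-function shapes, a mean absolute AUC error
of ≈ 2.2 % and NRMSE ≈ 0.053 at the low noise level (c = 0.15) and
≈ 8.9 % / 0.196 at the high level (c = 0.6); the noiseless fits are
exact.  `petkin study tac` runs the 27-combination kinetic recovery
experiment (`--late-only` ablates the 36–39 min window), `petkin
phantom` / `map` / `roi-tac` exercise the voxel-wise pipeline.

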
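# Methods

## The problem

Quantitative real-time PCR infers the amount of template present before
cycling from the per-cycle fluorescence trajectory. The two traditional
routes both have well-known failure modes: relative methods (ΔΔCq, and its
efficiency-corrected generalization) stand or fall with the stability of a
reference gene, and standard-curve absolute quantification requires an
amplified dilution series per target, inheriting that series' own
amplification errors.

`qpcrcal` implements a third route: a dilution series of a *non-amplified*
DNA calibrator is cycled on the same plate as the samples. Because the
calibrator is never amplified, its fluorescence is constant across cycles
and linear in the loaded amount, giving a per-plate linear map from
fluorescence to molar amount that applies to every target simultaneously.
Combined with a per-reaction amplification efficiency estimated from each
well's own curve, any fluorescence reading inside the exponential phase can
be back-calculated to the starting amount.

## Model and estimators

For a well with starting amount `pmz` (pmol at cycle zero) amplifying at
per-cycle efficiency `E`, the amount at the end of cycle `n` during the
exponential phase is `pm(n) = pmz * E^n`. The pipeline inverts this in four
steps:

1. **Baseline.** Each sample well's baseline is the mean of its own raw
   fluorescence over cycles `3..b`, `b = max(5, floor(takeoff) - 3)`, where
   a provisional take-off is located on lightly smoothed raw data. Sample
   wells use their own pre-take-off signal, not the 0 ng calibrator wells:
   the 0 ng level serves only the calibration curve, since sample wells
   contain primers and template and carry their own background.
2. **Landmarks.** The second-derivative maximum (SDM) bounds the usable
   window from above: beyond it the curve bends into plateau and the
   exponential model no longer holds. The take-off (used as the well's Cq)
   is the interpolated cycle where the discrete second derivative last rises
   through 20% of its maximum and stays above it — a parameter-light
   convention in the comparative-quantitation style. The window is the
   integer span `ceil(takeoff) .. floor(sdm)`, at least 3 cycles.
3. **Efficiency.** Ordinary least squares of `log10 f_corr` on cycle number
   over the window; `E = 10^slope`. Smoothed data are used only for
   landmark detection, never for this regression, because smoothing biases
   slopes. Estimates outside `[1.5, 2.1]` or with `r² < 0.99` are flagged,
   never clamped or discarded.
4. **Back-calculation.** The calibration curve converts each window cycle's
   corrected fluorescence to `pm(n)`; then `pmz(n) = pm(n) / E^n` with `n`
   the absolute cycle number counted from 1 — the only reading under which
   `pmz` is literally the amount at time zero. Cycles back-calculating to
   `pm <= 0` are dropped (they are calibration noise, not signal); at least
   3 must survive. The per-cycle `pmz` values are summarized as mean, SD
   and SEM (over window cycles); replicate-level statistics are a separate
   aggregation and both are reported. Copies per reaction =
   `pmol * 6.022e23 * 1e-12`.

The calibration itself is an OLS of background-subtracted per-level mean
fluorescence on loaded pmol (ng converted at a flat 650 g/mol per base pair
for the 90 bp calibrator; configurable). At least one 0 ng well and five
distinct non-zero levels are required; replicates are averaged per level so
levels are equally weighted. The intercept is left free — background
subtraction should drive it to ~0, and a large residual intercept is a
pipetting diagnostic that forcing the fit through the origin would hide.

### Relative-quantification comparators

* ΔΔCq: `fold = 2^-(ΔCq_g - ΔCq_ctrl)` with `ΔCq = mean Cq_target - mean
  Cq_ref` per group; assumes perfect doubling for both genes.
* Efficiency-corrected (Pfaffl-style): `fold = E_t^dCq_t / E_r^dCq_r`,
  `dCq = mean Cq(control) - mean Cq(group)` per gene; each gene's `E` is the
  arithmetic mean of per-reaction estimates over the two groups compared.
* Absolute ratio: group mean copies over control mean copies; needs no
  reference gene. The fold's standard error is propagated from group SEMs
  by the delta method.

The Cq entering the first two is the take-off point (configurable to SDM).
All three return exactly 1 for the control group by construction, and the
second reduces exactly to the first when all efficiencies equal 2.

## Numerical choices

* **Smoothing** is a centered local quadratic over 5 cycles
  (Savitzky–Golay, `scipy.signal.savgol_filter` with polynomial edge
  handling); exact on polynomials of degree ≤ 2.
* **Second derivative** on integer cycles is the central difference with
  spacing 1 — transparent and directly checkable against closed forms
  (`d2/f = (E-1)²/E` on exponentials).
* **SDM refinement.** The integer argmax of the discrete second derivative
  (earliest cycle on ties) is refined to a fractional cycle by a dense
  argmax of the analytic second derivative of a quintic interpolating
  spline through the *unsmoothed* corrected signal, restricted to ±1.5
  cycles. A parabola through the three discrete values around the argmax
  (available as `refine="parabola"`) is systematically early by 0.1–0.4
  cycles on realistically steep sigmoids, which the spline refinement
  reduces to ≤ 0.012 cycles on noiseless logistic curves with midpoints
  15–35 and slopes 1–3.
* **Take-off threshold** is referenced to the discrete second derivative at
  the integer argmax, which guarantees an interpolated crossing exists for
  any fraction ≤ 1 (at fraction 1 the take-off degenerates to within one
  cycle of the SDM).
* **Baseline polish.** The pre-take-off mean overestimates the true
  baseline by the exponential signal already present in early cycles
  (≈0.5–1.5% of the window fluorescence in typical geometries). When the
  early-cycle noise floor is below 0.05% of the smallest window
  fluorescence, the baseline is shifted by the offset that minimizes the
  log-linear residual over the window plus up to 6 clearly-detectable
  cycles below it (the window-of-linearity idea). This makes noiseless
  recovery exact to optimizer precision. Under realistic noise the offset
  is not resolvable — fitting it only adds variance (measured: dilution
  slope SD 0.017–0.020 with the polish vs 0.015 without, over 40 seeds at
  1% noise) — so the polish deliberately disengages there and the plain
  pre-take-off mean is used.
* Negative corrected fluorescence is kept (not clipped); zero-variance
  two-group comparisons with equal means return `t = 0, p = 1`.

## The simulator

The generator emulates (i) sample curves with a baseline, an exponential
phase of known efficiency, and a plateau; (ii) calibrator wells constant
across cycles and linear in loaded amount; (iii) the replicate/dilution
structure of a real quantification plate. Defaults: 40 cycles, `E0 = 1.9`,
ten-fold dilutions 4.5e6–4.5e1 copies in quadruplicate, calibrators at 0,
40, 60, 80, 120, 140 ng of the 90 bp calibrator in duplicate, two NTCs,
calibration slope 2000 a.u./pmol over a 100 a.u. background, plateau at
1.2e12 copies (≈2 pmol, a typical reaction-saturation scale), 1%
multiplicative plus 1 a.u. additive Gaussian noise. Noise is seeded per
well from `(seed, well_index)`, so extending a layout never perturbs
existing wells.

Two kinetic models separate correctness from robustness testing:

* `ideal` — `N(n) = min(N0 * E0^n, K)`: exactly exponential until a hard
  clip, so the pipeline must recover `E0` to ~1e-6 and `N0` to ~0.1% from a
  noiseless plate, and closed-form oracles exist for every stage.
* `logistic` — per-cycle efficiency `E(n) = 1 + (E0-1)/(1 + N(n-1)/K)`
  declines as product accumulates. Estimated efficiency is then biased low
  and back-calculated copies biased high; this is a property of such
  kinetics (the regression sees the declining phase), reported rather than
  hidden, and the reason the `ideal` model anchors the quantitative
  acceptance checks.

What the simulator does **not** emulate: probe hydrolysis chemistry,
passive-reference normalization, inter-platform gain differences,
amplicon-length-dependent dye binding, reverse-transcription efficiency,
or multiphasic/bimodal curves. Passing tests therefore demonstrate
correctness of the computational pipeline under its stated model, not
robustness to every real-instrument artifact.

### Known artifacts of the hard-clip kinetics

On `ideal` plates the clip point's fractional position relative to the
integer cycle grid differs between wells of different abundance, giving
every landmark-based Cq a deterministic, phase-dependent offset of up to
±0.35 cycles. These offsets cancel in within-gene group comparisons but
not between genes of different abundance, so ΔΔCq computed from full
`ideal`-pipeline Cqs can deviate from its ideal value by up to ~2× even
noiselessly — with either Cq definition. The comparator methods are
therefore validated on Cq-level simulations (their natural domain), while
the absolute route, which is insensitive to this artifact, is validated
through the full pipeline.

## Statistical comparisons

Group differences use the unpaired two-sample Student's t-test with pooled
variance (Welch available by flag). Slope equality between two regressions
uses the common-variance ANCOVA form: pooled residual variance on
`n_a + n_b - 4` degrees of freedom and standard error
`sqrt(s² (1/Sxx_a + 1/Sxx_b))`; it agrees to machine precision with the
interaction term of a joint OLS model.

## Problem sizes

Default analyses run a 38-well plate (24 sample + 12 calibrator + 2 NTC
wells, 40 cycles each); the dilution-series acceptance run uses the
five-level 4.5e5–4.5e1 design (28 wells). Monte-Carlo checks use 100–500
replicates of single-curve fits. These sizes match the single-plate designs
the method targets; a full run of every check completes in seconds.

## Known limitations

* The take-off convention (20% of the second-derivative maximum) is one of
  several reasonable choices; the fraction is configurable and Cq-sensitive
  analyses should check robustness to it (and to using the SDM instead).
* Efficiency is assumed constant from cycle 1 through the window; kinetics
  with early-cycle efficiency drift will bias `pmz` in ways the per-cycle
  SD only partially reveals.
* Quantification below the calibrated fluorescence range is extrapolation
  and flagged as such; the value is still returned.
* Multi-reference-gene normalization schemes and reference-stability
  ranking are out of scope.
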
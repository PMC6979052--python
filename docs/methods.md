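# Methods

## Membrane-potential model

The assay model is a cuvette of sperm loaded with the slow potentiometric
dye DiSC₃(5), whose suspension fluorescence F (arbitrary fluorescence
units, AFU) tracks the plasma-membrane potential Em. Two assumptions
carry the whole calibration:

1. **Affine dye response.** Over the calibrated range, F = a + b·Em with
   per-trace gain b (AFU/mV) and offset a. This is exactly the assumption
   the internal-calibration procedure itself makes when it fits a line of
   plateau fluorescence on theoretical potential, so the synthetic dye
   model deliberately uses the same form; any per-trace a, b (dye loading,
   lamp intensity, cell density) cancels on inversion. The package
   verifies this as a property: affinely rescaling all fluorescence values
   of a trace leaves the mV estimate unchanged to 1e-6 mV.
2. **Valinomycin clamps Em to E_K.** With the membrane rendered
   K⁺-selective, the potential is the Nernst potential
   E_K = (RT/F)·ln([K⁺]ₒ/[K⁺]ᵢ), so each calibration plateau has a
   *known* potential computed from the cumulative external K⁺ at that
   moment. Mitochondrial contributions to the dye signal are neglected
   (they are insignificant for the resting potential in this preparation).

Potassium bookkeeping is exact mass balance with dilution:
K_new = (K_prev·V_prev + C_aliquot·V_aliquot)/(V_prev + V_aliquot). A
property test asserts mole conservation to 1e-9 relative tolerance at
every step.

### Parameters, units, defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| external K⁺ (initial) | 5.0 | mM | HEPES-HTF recipe: 4.7 mM KCl + 0.3 mM KH₂PO₄ |
| intracellular K⁺ | 120 | mM | standard literature value for human sperm; not measured per sample, config-overridable |
| temperature | 310.15 | K | assay run at 37 °C |
| R, F | 8.314, 96485 | J mol⁻¹K⁻¹, C mol⁻¹ | physical constants |
| cuvette volume | 2.0 | mL | typical fluorimeter cuvette; configurable |
| KCl protocol | 4 × 1 M aliquots to 10, 20, 40, 80 mM | — | aliquot volumes solved from the mass balance so the cumulative K⁺ doubles each step (equal ~18.5 mV Nernst spacing) |
| plateau settle delay / window | 10 / 20 | s | leaves ≥ 5 dye time constants before averaging (see below) |
| behavior threshold | 5 | mV | class boundary on \|ΔEm\| |
| hyperactivation | VCL ≥ 150 µm/s, LIN < 50 %, ALH ≥ 5 µm | — | conjunction; VCL/ALH inclusive, LIN strict, as the criteria are stated |
| IVF success threshold | 0.60 | fraction | "at least 60 %" is inclusive |

### Calibration design choices

* **The valinomycin plateau is a calibration point** at E_K of the
  initial medium, anchoring the hyperpolarized end of the curve; it can
  be excluded (`include_valinomycin_point=False`), in which case only the
  KCl plateaus are used.
* **"Linear interpolation" is global-line inversion.** The default
  inverts the ordinary least-squares line of fluorescence on theoretical
  Em (Em = (F − a)/b). A `piecewise` mode interpolates between the two
  bracketing calibration points instead; on noise-free data the two
  agree, and both are exposed because either reading of the procedure is
  defensible. Fitting fluorescence-on-Em (rather than Em-on-fluorescence)
  was chosen because the theoretical potentials are the error-free
  coordinate; the inversion is exact for an exactly linear response
  either way.
* **Extrapolation is flagged, never rejected.** An initial fluorescence
  outside the span of the calibration plateaus (a sample more
  hyperpolarized than E_K of the starting medium, or more depolarized
  than the last KCl step) still yields an estimate, with
  `extrapolated=True` in the quality record.
* **Plateau extraction** is a windowed mean (± sd reported): the initial
  plateau over the `window` seconds immediately *before* the valinomycin
  addition (half-open, so the sample at the event instant — which already
  carries the post-step level — is excluded), and each post-addition
  plateau over `[t + settle_delay, t + settle_delay + window]`. A window
  with fewer than two samples raises an error naming the event.

### Numerical behavior and degenerate inputs

* A calibration with < 2 points, zero Em variance, or zero slope raises a
  typed error (`InsufficientCalibrationError`, `DegenerateFitError`,
  `FlatCalibrationError`); errors propagate with the trace identified.
* Paired/unpaired t tests on zero-variance differences do not error:
  all-zero differences return (t = 0, p = 1) and a constant non-zero
  difference returns the (±inf, p = 0) limit, both with a `degenerate`
  flag.
* ROC thresholds are placed at midpoints between consecutive distinct
  score values plus sentinels beyond both ends, so each achievable
  confusion table appears exactly once and tied scores get the mid-rank
  (½) convention automatically through the trapezoid. Youden ties are
  broken toward higher sensitivity.
* The AUC standard error uses the Hanley–McNeil exponential
  approximation (Q₁ = A/(2−A), Q₂ = 2A²/(1+A)); the exact estimator
  behind published ±SE values from commercial packages is generally not
  recoverable, so the choice is documented here and isolated in
  `hanley_mcneil_se` where it can be swapped. The 95 % CI is the normal
  approximation clipped to [0, 1] — the clipping is forced by published
  intervals whose upper bound is exactly 1.
* No multiple-testing correction is applied anywhere; raw two-sided
  p-values are reported. The one-way ANOVA wrapper is a thin pass-through
  to scipy with no post-hoc machinery.

## What the synthetic generator emulates — and what it does not

`simulate_trace` produces the affine steady-state response plus
first-order relaxation (default τ = 2 s) after each reagent step, additive
Gaussian noise and linear drift. The default trace noise (6 AFU) is about
2 % of the dynamic range the default protocol spans. It does **not**
model dye partitioning or self-quenching kinetics, mitochondrial
potential, cell settling, or photobleaching beyond linear drift — so
passing recovery tests demonstrate correctness of the *inversion
procedure under its own assumptions*, not robustness to a misspecified
dye response. A protocol whose inter-event spacing is under 3τ triggers
an unsettled-plateau warning; the default spacing (60 s) leaves ≥ 5τ
before each averaging window, keeping the residual relaxation bias below
~0.05 mV.

`simulate_cohort` draws, per donor, a behavior class from the mixture
(defaults 53.6 / 32.8 / 13.6 % hyperpolarizing / depolarizing /
unchanged for normospermic donors; 27.3 / 63.6 / 9.1 % available as
`NON_NORMOSPERMIC_MIXTURE`), an NC Em from N(−37.7, 9.9²) mV, and a
class-conditional Em shift truncated at the ±5 mV boundary so the
generated label always matches noiseless classification. The
hyperpolarizing shift is centered at the CAP−NC group-mean difference
(−20.1 mV), so −57.8 mV is the CAP center *of the hyperpolarizing class*;
a full-mixture cohort therefore has a less negative pooled CAP mean, as a
mixed cohort must. The within-class shift spread (8 mV) and the repeat-
measurement noise (2 mV) are stated assumptions — no within-donor repeat
variance is available to estimate them from — and both are spec fields.

`simulate_ivf_cohort` draws fertilized counts as
Binomial(oocytes, expit(β₀ + β₁·Em_CAP)) with defaults β₀ = −7.29,
β₁ = −0.15 /mV, i.e. a 50 % per-oocyte probability at −48.6 mV rising
toward ~85 % at −60 mV: a deliberately strong hyperpolarization-favoring
link, because the generator's role is to provide a cohort in which the
downstream ROC has signal to find. Oocytes per patient are discrete
uniform 4–12 (clinical wells constrain complexes per well, not the
total; the range is configurable). `simulate_casa` is a two-component
(hyperactivated / progressive) Gaussian mixture over VCL, LIN, ALH with
VSL = VCL·LIN/100 and VAP drawn between VSL and VCL; the hyperactivated
weight can be coupled to Em through a logistic curve. `simulate_ar` is
plain binomial sampling per arm, with ≥ 200 sperm per condition as the
design minimum (a low count warns, it does not exclude).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the noise-free calibration
sweep at 8 true potentials × 5 dye models, the Monte-Carlo recovery at
200 traces, the AUC-versus-concordance comparison on 1,000 random
instances of n ≤ 20, the end-to-end pipeline at 49 donors, and mixture
recovery at 10⁴ donors; these sizes give the binomial/Monte-Carlo error
bars quoted in the tests while keeping the whole suite in the seconds
range.

## Known limitations

* Intracellular K⁺ is assumed (120 mM), not measured; an error of
  ±20 mM shifts every estimate by a common ~±4–5 mV offset (it moves all
  theoretical calibration potentials together).
* The affine dye model means the pipeline cannot detect genuine dye
  nonlinearity; real traces with saturating response would bias estimates
  without degrading r² much.
* The Hanley–McNeil SE and normal clipped CI are approximations that are
  anti-conservative for very small cohorts and AUC near 1; DeLong or
  bootstrap intervals are out of scope.
* Behavior classification at exactly |ΔEm| = 5 mV follows the convention
  that "unchanged" is the open band; how boundary cases were handled in
  the original analyses of such data is not stated anywhere, so this is a
  documented convention, not an empirical fact.
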
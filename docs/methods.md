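# Methods

## Model and assumptions

The package analyzes the pull phase of a single-well push-pull test. Both
adjustment methods share the transport assumptions standard to the technique:
tracer and target have identical transport behavior (advection, dispersion,
diffusion, sorption), the pull phase begins immediately after the push (any
drift phase is neglected, so the extracted concentration at t = 0 equals the
injected concentration), and the aquifer is an effectively infinite reservoir
at constant background concentration. Under these assumptions any deviation of
the dilution-adjusted curve from the injected concentration is attributed to
reaction.

The conventional adjustment `Ce2* = Ce2·Ci1/Ce1` additionally requires the
equal-ratio condition `Ci1/Ca1 = Ci2/Ca2`. The improved adjustment
`Ce2** = Ce2·Ci2/Ce2e`, with `Ce2e = (Ce1−Ca1)/(Ci1−Ca1)·(Ci2−Ca2) + Ca2`,
does not. Two algebraic identities connect them (both are property-tested):
when the equal-ratio condition holds exactly the methods coincide to floating
precision, and when both backgrounds are zero `Ce2e` collapses to
`Ce1·Ci2/Ci1` and they are equal exactly. A solute adjusted against itself
yields a constant curve at its injected concentration under either method —
the built-in control every report includes for the tracer.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `c_injection`, `c_aquifer` | concentration (label only) | — | per-solute injection/aquifer concentrations; units are carried as free text and never converted (field designs legitimately mix mM and µM) |
| `dilution_rate` (kd) | 1/time | — | first-order dilution rate of the simulator; magnitude used, sign accepted as the decay-toward-background convention |
| `reaction_rates` (kr) | 1/time | 0 | signed per-solute first-order reaction rate; negative = removal |
| `noise_sigma` | concentration | 0 | absolute SD of additive Gaussian measurement noise, truncated at zero |
| assumption `tolerance` | fraction | 0.05 | advisory threshold on the relative ratio difference; no canonical value exists, and both methods stay computable regardless of the verdict |
| `extraction_rate` | volume/time | off | optional constant-rate conversion of time to cumulative volume when flow totals were not recorded; recovery factors are invariant to the constant, net mass scales with it |

## Simulator

Dilution follows the modified first-order profile
`Ce(t) = (Ci−Ca)·e^(−kd·t) + Ca`, the simplest form satisfying the t = 0 and
t → ∞ boundary conditions; rearranged, `(Ce−Ca)/(Ci−Ca) = e^(−kd·t)` is the
dilution fraction (1 = undiluted, 0 = fully diluted). A reactive solute is
generated in product form, `Ce2(t) = Ce2e(t)·e^(kr·t)`. The product form was
chosen over folding the reaction into the exponent (`kd+kr` in one term)
because it makes the dilution behavior of tracer and target literally
identical, and it makes the improved-adjusted curve exactly `Ci2·e^(kr·t)` — a
straight semi-log line, as a first-order reaction must produce. With kr = 0
the reactive path returns the dilution-only profile bitwise.

The three canonical designs use a bromide tracer (100 over 1 mg/L) and an
ethanol target (50 mg/L injected), kd = 0.2/h: design 1 reacts at kr = −0.2/h
with equal ratios, design 2 has no reaction, design 3 has no reaction but a
5 mg/L ethanol background so the ratios are 100 vs 10 — the conventional
method's failure mode. The default grid is 0–24 h in 0.5 h steps, chosen so
the tracer decays to within 1% of background; noise-free results are
grid-invariant. The six-solute field design carries the injection/aquifer
concentrations of a nitrate-biostimulation test (200 L injection).

What the generator does **not** emulate: drift-phase displacement, spatially
explicit transport, rate laws beyond first order in the generative model,
solute-specific sampling schedules, and non-Gaussian or multiplicative
measurement error. Passing tests therefore demonstrate correctness of the
adjustment algebra and the estimators under the stated generative model, not
robustness to transport-assumption violations in real aquifers.

## Estimation and numerical choices

- First-order rates: unweighted OLS of `ln(adjusted)` on time (the straight
  semi-log line implies log-scale fitting; no weighting scheme is imposed).
  Nonpositive adjusted values cannot be logged and are excluded with a counted
  warning. Zero-order rates: OLS of the adjusted concentration on time.
- Inference: 95% CI half-width from the t-distribution with n−2 df; two-sided
  p-value for slope ≠ 0. The *reported* rate is 0 when p > 0.05, mirroring
  common field reporting; the raw slope and p are always retained.
- Perfect fits (residual SS below 1e−12 of the response scale) report p = 0
  and CI half-width 0 instead of 0/0 NaNs. A numerically flat line can still
  carry a ~1e−18 slope; it is reported as computed, not snapped to zero.
- Integration for recovery factors is trapezoidal — exact for the piecewise
  linear concentration-vs-volume profiles the field reports plot.
- Samples violating a precondition (Ce1 ≤ 0, Ce2e ≤ 0) abort with an error
  naming the sample rather than being dropped silently, since silent dropping
  biases rate fits. Tracer overshoot below background (negative dilution
  fraction) is a warning only. Adjusted values are never clipped at zero or at
  the injected concentration, so the conventional method's over-adjustment
  stays visible.
- CSV round-trips are exact: floats are written in shortest round-trippable
  form and parsed with round-trip precision.

## Design choices where the design was open

- The equal-ratio diagnostic needed a threshold; 5% relative difference is the
  default and it is advisory only.
- Recovery factors are defined on *adjusted* curves, which makes RF = 1 hold
  identically for any tracer self-adjustment under both methods — the natural
  internal control.
- The noisy parameter-recovery study (200 seeded replicates, noise SD 2% of
  the injected target concentration) samples t = 0–6 h every 0.25 h: the
  window where the reacting target stays roughly 3× the noise SD, i.e. the
  quantifiable range a practitioner would fit.
- The general functional form relating extracted concentration to design
  parameters is treated as notation subsumed by the exponential dilution
  profile; many other profiles satisfy the same boundary conditions and the
  adjustment algebra is agnostic to the choice.

## Limitations

- Michaelis–Menten and other nonlinear rate laws are out of scope; so are
  advection–dispersion transport modeling, sorption/retardation corrections
  and multi-well interference.
- OLS inference on the log scale assumes homoscedastic log-residuals; late-time
  samples of a decaying solute violate this, which is why the recovery study
  restricts fitting to the quantifiable window.
- Unweighted fits and trapezoidal integration are sensitive to sampling
  density; field schedules with sparse late-time sampling weight early
  behavior accordingly.
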
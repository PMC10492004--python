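# Methods

This note records how `pvbeat` computes what it computes, the choices made
where the published description of the method leaves the design open, what
the simulator does and does not emulate, and the known limitations. Units
throughout: pressure mmHg, volume mL, time s, elastance mmHg/mL, flow mL/s.

## Signal conditioning

Input recordings are resampled to a uniform working rate (default 500 Hz;
rates below 100 Hz are refused) by cubic-spline interpolation, never
extrapolating past the recorded span. Beats are delimited minimum-to-minimum
of pressure (R-wave gating is used instead when an ECG channel is present);
end-diastole is placed by walking back from the dP/dt peak to the last sample
below 10% of it, which is robust to diastolic noise crossings.

Differentiation uses a Savitzky–Golay local-polynomial filter whose window is
specified in *time* (62 ms; 31 samples at 500 Hz, polynomial order 5) so that
landmark positions are stable across sampling rates. A 4th derivative
amplifies white noise as frequency⁴, so orders ≥ 2 are preceded by a Gaussian
low-pass (−3 dB at 15 Hz by default). A Gaussian was chosen over a sharper
IIR design deliberately: its kink response is monotone, so it cannot ring and
plant spurious derivative extrema next to genuine valve-event signatures.
Samples whose smoothing window touches a trace boundary are flagged and
excluded from every landmark search.

## Flow landmarks

The ejection-onset landmark is the earliest prominent maximum of the 4th
derivative on the *rising pressure limb between 15% and 85% of the beat's
peak pressure*. A dP/dt-max-anchored window — the more obvious choice — fails
at high contractility against a stenotic valve, where peak dP/dt occurs well
into ejection; the pressure band adapts across contractility and excludes the
mitral-closure signature near end-diastolic pressure. The termination
landmark is the global minimum of the 4th derivative in a tight window around
the dP/dt minimum (−10% to +5% of beat duration), which sits at the sharp
flow deceleration of valve closure; a wider window would admit the
mitral-opening signature later in relaxation. The apex is the first
negative-to-positive zero crossing after onset, located to sub-sample
precision by linear interpolation.

Within one acquisition the landmarks of all beats are pooled: each beat is
analyzed with the median landmark times (as fractions of beat duration)
across the trace. The 4th-derivative landmark is by far the noisiest link in
the chain, and the beats of a steady recording share their timing, so pooling
removes most of the per-beat jitter while each beat is still analyzed — and
reported — individually; the per-acquisition value of every variable is the
median across accepted beats.

Measured on the simulator at the default 1 mmHg catheter noise, the pooled
onset lands ~20 ms after true valve opening (median; the smoothed derivative
signature peaks just after the mechanical event) and the termination within
~±20 ms of closure. Tightening this further is limited by physics, not
implementation: the opening signature of a severely stenotic valve is weak,
and the ω⁴ noise gain of 4th-order differentiation sets a jitter floor of
roughly 15 ms at realistic noise.

## Isovolumic extrapolation

The fitted model is the classical single-beat sinusoid
P(t) = Pₐ + (P_b/2)(1 − cos(ωt + φ)), least-squares over the two isovolumic
limbs: contraction from the 20% dP/dt-max crossing to the flow onset, and
relaxation from the flow termination until dP/dt recovers above 20% of its
minimum **or pressure falls to the end-diastolic level** (below which the
mitral valve opens and relaxation is no longer isovolumic). Both limbs carry
equal aggregate weight — each limb's samples share one unit — so a long limb
cannot outvote a short one.

Three stabilizing choices matter, all documented because the limbs cover only
the bottom third of the envelope and the unconstrained problem is
ill-conditioned (the sum of squares is nearly flat along a ridge trading
amplitude against frequency):

* **Frequency box.** ω is initialized at π over the dP/dt-max-to-min interval
  (the half period of a sinusoid sampled at its steepest points) and boxed to
  (0.6, 1.7)× that anchor; the phase is boxed to ±1.2 rad around a trough
  pinned at end-diastole.
* **Relaxation-limb volume correction.** During isovolumic relaxation the
  ventricle holds its end-systolic, not end-diastolic, volume, so in a
  varying-elastance ventricle those pressures run a factor (Veed − SV)/Veed
  below the end-diastolic envelope being extrapolated; uncorrected they drag
  the fitted peak down by ~25% regardless of weighting. The limb is lifted by
  ρ = V₀ᵉᶠᶠ/(V₀ᵉᶠᶠ − SV) with V₀ᵉᶠᶠ = 140 mL, a fixed population prior for
  the effective end-diastolic volume of severe-stenosis cohorts (reported
  values center near 130 mL). The prior makes the correction adapt with the
  measured stroke volume, which dominates the between-subject variation of
  the true ratio. Estimating ρ from the fit's own Veed output instead was
  implemented and rejected: that feedback has loop gain ≈ 1 and no stable
  fixed point (it creeps monotonically and where it stops depends on the
  iteration count — diagnosed by tracing the map, not guessed).
* **Plausibility gates.** Fits whose extrapolated peak falls below the
  measured peak pressure, or above a configurable 500 mmHg ceiling, are
  rejected; rejected beats yield structured rejection records naming the
  failing stage, never partial numbers.

On noiseless model-generated limbs the fit recovers all four parameters to
1e-4 relative; with 1 mmHg noise the peak is recovered within 2%. On full
simulated severe-stenosis beats, the extrapolated peak lands within ~6%
(cohort median) of the clamped-valve truth.

## Loop mechanics

Because absolute volume is unobservable, the loop lives in ejected-volume
coordinates: a vertical isovolumic-contraction leg at V = 0, the ejection
path to V = SV, a vertical relaxation leg at V = SV. Ees is the minimum over
ejection samples (V > 0.5 mL, guarding the slope against division blow-up) of
(Pisomax − P)/V. The equilibrium point is the *largest-V* sample whose slope
lies within 10% of that minimum: the loop hugs the tangent line over an arc,
and the anchored-slope resolution is dominated by the uncertainty of the
extrapolated peak (a few per cent of Pisomax maps to roughly ten per cent of
slope), so exact ties are meaningless. Stroke work integrates pressure over
ejected volume along the ejection path only — the isovolumic legs have zero
width and filling work is not measurable in these coordinates. PVA is the
triangle ½·Pisomax·Veed. The identities Veed·Ees = Pisomax, SW ≤ PVA and
Q_load ∈ (0, 1] hold on every accepted beat by construction and are asserted.

Pre/post comparisons use the standard paired t statistic (two-sided) per
variable; zero-variance difference vectors are flagged degenerate rather than
silently producing a t value.

## The simulator

States: LV volume, Windkessel compliance pressure, and aortic flow. The
ventricle is P = E(t)(V − V₀) with E(t) = E_min + (E_max − E_min)·e(t);
filling comes from a constant-pressure atrium through a linear mitral
resistance; the afterload is a 3-element Windkessel; the stenotic valve obeys
ΔP = B·Q² in series with a blood-column inertance L. The inertance is not
decoration: without it the square-root orifice law sustains ~40 mL/s of flow
at a 2 mmHg gradient, the valve closes ~190 ms after peak elastance, and the
end-systolic geometry of the loop is unphysiological. Integration is
classical fixed-step Runge–Kutta at 5 kHz, run to periodic steady state
(< 0.1% beat-to-beat peak change, ≥ 10 cycles) before a beat is emitted; the
output trace tiles 8 steady-state cycles at 1 kHz with seeded Gaussian noise
(1 mmHg) added last. Refining the internal step 2× changes the truth values
by < 0.2%.

The default activation e(t) is a **two-segment cosine**: a half-cosine rise
over 0.30 T and a faster half-cosine fall over 0.26 T. Each isovolumic limb
of this ventricle is exactly sinusoidal — the regime the single-beat
extrapolation assumes and in which it was validated in vivo — while the
quicker fall puts peak elastance shortly before valve closure, as in real
ventricles. The widely used double-Hill waveform is available as an option;
its strongly asymmetric envelope (rise ~270 ms, fall ~100 ms at 70 bpm)
defeats a symmetric-sinusoid extrapolation by construction, and the package
makes no claim of accurate Pisomax recovery under it.

The severe-stenosis preset (E_max 2.4, V₀ 10, HR 70, B 1.2e-3, stiff elderly
arteries: C 0.6 mL/mmHg, Rp 1.6, atrial pressure 15) was tuned once against
the hemodynamic ranges reported for severe-stenosis cohorts — stroke volume
≈ 50 mL, isovolumic peak ≈ 285 mmHg, Ea ≈ 3.8 mmHg/mL, end-systolic pressure
within 6% of peak pressure — and frozen. Valve replacement is modeled as
multiplying B by 0.2 with every other parameter untouched, isolating the
valvular component of the afterload. Paired cohorts draw contractility, valve
severity, heart rate and filling pressure per subject from one seeded
generator; identical seeds reproduce byte-identical outputs.

**What the simulator does not emulate** — and hence what passing tests do not
show about real data: baroreflex and venous-return dynamics, atrial
contraction, aortic regurgitation after valve replacement, load-dependent
relaxation (ejection-induced deactivation), catheter-line resonance and
whip artifacts, respiratory modulation, and beat-to-beat variability beyond
additive white noise. The relaxation-limb volume correction is exact in a
varying-elastance world and only approximate in a real ventricle.

## Method-constant calibration

Constants the published method leaves unspecified — landmark search windows
and prominence fractions, the derivative pre-smoother cutoff, the ω/φ boxes,
the ρ prior, the equilibrium slope tolerance, and the activation fractions —
were calibrated against simulator ground truth on a development grid of
ventricles (contractility 1.6–3.6 mmHg/mL crossed with valve severity, heart
rate and filling pressure) and then frozen; the validation suite runs on
separately seeded cohorts. Calibration targeted unbiasedness and monotone
contractility recovery simultaneously, not any single figure.

## Numerical details and degenerate inputs

Resampling never extrapolates; traces shorter than one cycle segment to an
empty beat list with a warning; constant or negative-mean traces are
rejected with typed errors. The optimizer is trust-region least squares with
1e-12 relative tolerances and at most 2000 residual evaluations. Beats whose
landmarks fail ordering, whose limbs are shorter than 4 samples, whose fit
does not converge, or whose loop admits no tangent are rejected and logged
with the failing stage; a trace with zero accepted beats is a hard error at
the CLI. All randomness — simulator noise, cohort draws — flows through
`numpy.random.default_rng` seeded explicitly.

## Known limitations

* Ea is read at the loop's equilibrium point in *triangular* ejected-volume
  coordinates; because a small tail of the stroke volume is still ejected at
  end-systole, Ea runs a few per cent high relative to Pes/SV (cohort median
  ≈ +6%).
* Pisomax accuracy rests on the sinusoid-likeness of the activation envelope;
  ventricles with strongly asymmetric activation (double-Hill-like) defeat
  the extrapolation.
* The ρ correction uses a population prior, not the subject's true volume;
  subjects far from the prior (very large or very small ventricles) carry a
  proportional Pisomax bias.
* Landmark timing has a ~15 ms noise floor at realistic catheter noise; at
  very low heart rates or heavy arrhythmia (not simulated) the pooled
  landmarks would be invalid.
* Absolute volumes (V₀, end-diastolic volume) are not estimable from pressure
  plus cardiac output; only the difference Veed is produced.
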
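# Methods

`wavesep` implements pressure-only wave separation analysis for the
ascending aorta: decomposition of a central pressure waveform (or an
uncalibrated linear surrogate such as cross-sectional area) into its
forward- and backward-travelling components, using either a measured flow
waveform or one of several flow surrogates, together with a virtual
Doppler ultrasound simulator and a ground-truthed synthetic beat
generator used for validation.

## Wave separation model

For one beat of paired pressure *P(t)* and flow *Q(t)* on a common time
grid, the components are

    Pf = (P − Pud + Zc·Q) / 2
    Pb = (P − Pud − Zc·Q) / 2

where *Pud* is the undisturbed pressure (default 0, configurable) and
*Zc* the characteristic impedance. *Pf + Pb = P − Pud* holds pointwise by
construction, at machine precision.

**Characteristic impedance.** *Zc* is the least-squares slope of *P*
versus *Q* over the early-systolic upstroke — from the flow's upstroke
onset until flow first reaches 95 % of its peak (fraction configurable).
The early upstroke precedes the return of reflected waves, so there
*P ≈ Zc·Q* up to a constant, and the regression intercept absorbs the
diastolic pressure offset. At least 4 samples are required and the slope
must be positive. When *P* is an uncalibrated surrogate, *Zc* carries
arbitrary units; every derived index below is invariant to that scale.

**Reflection magnitude.** RM = ΔPb / ΔPf, with Δ denoting the amplitude
(max − min over the beat) of each component. RM is dimensionless and
invariant to amplitude scaling of *Q* and to affine recalibration of *P*,
because *Zc* rescales correspondingly — the reason uncalibrated area
waveforms and amplitude-free flow *shapes* suffice.

**Return time (centroid method).** Tr is the difference of time-axis
centroids, ∫t·s dt / ∫s dt by trapezoidal quadrature over the full beat,
between *Pb* and the input pressure *Pf,in = Zc·Q*, each first offset so
its minimum over the beat is zero. The method presumes that ventricular
outflow is relatively unaffected by reflected waves, so that *Zc·Q*
approximates the pressure that would exist without reflection. Two open
choices are resolved as: integration spans the whole beat (all of *Pb*'s
energy contributes), and both signals are offset to a zero minimum.
See "Known limitations" for how this index behaves when flow *does*
carry a large reflected wave.

**Area calibration.** An area waveform may be mapped to mmHg with the
affine map fixed by brachial mean and diastolic pressure (output mean =
MAP, output minimum = DBP). RM and Tr are unchanged by this calibration;
only the component waveforms acquire physical units.

## Beat landmarks

Landmarks are detected on the flow (or velocity) waveform, all returned
as sub-sample times in ms:

* peak: sample of maximum value;
* 50 %-upstroke: first upward crossing of half the peak before the peak,
  linearly interpolated;
* onset: last crossing of 5 % of the peak before the 50 % crossing
  (threshold configurable; 5 % is robust to the near-zero diastolic
  baseline of aortic flow);
* end-systole: first local minimum after the peak within 0.6 of the
  cycle (a sample lower than its left neighbour and no higher than its
  right one; ties break to the earliest time; systole occupies well under
  60 % of the cycle at physiological heart rates);
* zero-return: first return of the signal to zero at or after
  end-systole, from either sign (absent if the signal never returns).

For pressure/area inputs the signal minimum is subtracted before
thresholding, since those signals ride on a diastolic baseline.

## Representative flow waveform

Each cohort beat is amplitude-normalized to unit peak and
time-normalized with two anchors — τ = 0 at the 50 %-upstroke crossing
and τ = 1 at end-systole — onto a fixed grid of 1000 points spanning
τ ∈ [−0.3, 2.5] (covers pre-foot through late diastole at all
physiological heart rates; the grid extent is this package's choice).
The (t₅₀, 0.5) anchor is injected as an exact sample before resampling;
outside a beat's τ range its boundary values are held. The
representative waveform is the pointwise cohort mean, smoothed with a
Savitzky–Golay filter spanning 0.125 τ-units (converted to the nearest
odd sample count; polynomial order 3, this package's choice — the filter
passes cubics untouched), then multiplied by a weighting function that is
1.0 until the *mean* waveform first returns to zero after its
end-systolic minimum, ramps linearly to 0 over 0.6 τ-units, and is 0
thereafter, enforcing zero late-diastolic flow. The 5th/95th-percentile
envelopes of the raw (unsmoothed, unramped) contributors are retained.

De-normalization inverts the affine time map using a target beat's own
anchors and leaves the amplitude at normalized scale (separation is
amplitude-invariant). Anchors are normally taken from the measured flow;
in a pressure-only deployment they may be taken from the pressure/area
waveform instead.

A leave-one-out harness rebuilds the representative waveform without
each subject in turn, runs separation with the surrogate, and reports
signed/absolute RM and Tr errors (percent of the measured-flow
reference) and component-waveform RMSE. Because both separations share
*P*, the forward and backward residuals are equal and opposite, so
RMSE(Pf) = RMSE(Pb) identically.

## Triangular and external flow surrogates

The triangular surrogate is zero before the flow-upstroke onset, rises
linearly to a unit apex at a fixed fraction of ejection time (default
25 %, near the typical time of peak aortic flow; 30 % and the subject's
true peak time are provided variants), and falls linearly to zero at
end-systole. Any externally supplied normalized waveform with the same
anchor convention (two-column `tau,value` CSV) is de-normalized through
exactly the representative-waveform code path.

## Virtual Doppler ultrasound

Given per-frame through-plane velocities on a 2-D pixel grid with a
lumen mask, a square sample volume with side 0.5 × the minimum (over
time) effective diameter D(t) = 2√(A(t)/π) is placed at the
time-averaged lumen centroid and held fixed. Per frame, the traces are
the 95th-percentile velocity within the sample volume (DopEnv, the
spectral envelope), the mean within the sample volume (DopMean), the
95th percentile over the whole lumen (PeakU, an ideal lumen-covering
sample volume), and the whole-lumen mean (the volumetric-flow
reference). Percentiles interpolate linearly between order statistics,
and a pixel belongs to the sample volume when its centre falls inside
the square (both choices this package's). Because both "peaks" are 95th
percentiles of different pixel sets, PeakU can fall below DopEnv.
Traces are post-processed as clinical traces are: the end-diastolic
value at beat start is subtracted, and the trace is zeroed from its
post-systolic zero-return (end-systole if it never crosses zero) to beat
end. Subtracting the first sample rather than a threshold-crossing value
makes post-processing idempotent on clean traces.

## Synthetic ground truth

The generator is a single-reflection tube-load (transmission-line)
model: a forward wave *F(t)* — a half-sine over systole, time-warped so
its peak falls at a configurable fraction of ejection (default 0.25) —
plus one reflected copy:

    Pf = F(t)          Pb = Γ·F(t − Δ)
    P  = Pf + Pb + baseline        Q = (Pf − Pb)/Zc
    A  = affine(P)

Defaults: Γ = 0.4, Δ = 120 ms, Zc = 0.1 mmHg·s/mL, HR = 70 bpm, systole
= 35 % of the cycle (≈ 300 ms at 70 bpm), forward amplitude 40 mmHg,
baseline 80 mmHg, 128 samples per beat (typical of segmented
phase-contrast MRI). Re-reflections are deliberately excluded so the
ground truth is closed-form: with the reflected wave inside the beat,
the true backward component is exactly Γ·F(t−Δ) and RM = Γ. Optional
additive Gaussian noise (fraction of the forward peak) is drawn from a
single seeded generator; identical seeds give bit-identical beats.
Cohorts draw per-subject heart rate (55–90 bpm), Γ (0.3–0.6), Δ
(80–160 ms), peak-time fraction (0.20–0.30) and amplitude (30–50) from
uniform ranges, all through one seeded generator.

Velocity fields place a circular lumen (radius 10 mm, 0.5 mm pixels) and
a power-law profile u ∝ 1 − (r′/R)ⁿ (n = 2 parabolic, larger = blunter)
whose centre is displaced along +x by skew·R·|q(t)|/max|q| — skewing
grows with flow, as in a curved vessel, reaching the full displacement
at peak flow. A time-constant displacement would make the field
separable (one shape for every trace) and could never distort a
Doppler-derived waveform, which is the error mechanism this simulator
exists to exercise. Each frame is rescaled so the lumen-mean velocity
equals q(t)/A exactly (A = pixel count × pixel area).

## What the generator does and does not emulate

It emulates: paired single-beat pressure/flow/area with exact, known
reflection magnitude, delay and impedance; realistic sampling density;
inter-subject variability in rate, reflection and upstroke shape;
profile-skew and sample-volume errors in Doppler-style traces. It does
not emulate: re-reflections or distributed reflection sites, the
dicrotic incisura (the forward wave has no valve-closure notch, so
pressure-derived end-systole lands at the end of the reflected wave
rather than at valve closure), wall viscoelasticity (the pressure–area
map is linear), Womersley-type unsteady profiles, or measurement physics
(beam geometry, spectral broadening, wall filters). Passing tests
therefore demonstrate the estimators' algebraic and numerical
correctness under a clean single-reflection world, not their clinical
accuracy on patient data.

## Known limitations

* **Centroid return time under tube-load flow.** The transmission-line
  identity puts the full reflected wave into Q, violating the centroid
  method's premise that outflow is reflection-insensitive. Offsetting
  *Zc·Q* to a zero minimum then adds a large DC term over the beat and
  drags its centroid toward mid-beat, so on these synthetic beats Tr is
  not an estimator of the true delay Δ (it can even be negative), even
  though the same machinery returns the exact shift for genuinely
  shifted-copy inputs. This is a property of the index definition
  interacting with the simulator's flow model, not a numerical defect;
  on clinical flows, whose reflected imprint is small, the index behaves
  as intended. Relative Tr comparisons between two surrogates sharing
  the same pressure remain meaningful but inherit the instability of a
  small reference value.
* Under a single-reflection model, exact RM = Γ recovery and exact
  Tr = Δ recovery through these estimator definitions are mutually
  exclusive: the former needs Q to carry the reflected wave, the latter
  needs it not to.
* The Savitzky–Golay residual depends on input smoothness: ~10⁻³ for C²
  beats at the default span, but a few percent at derivative kinks (such
  as the generator's warped-sine peak).
* Interpolation is shape-preserving pchip where monotonicity near
  landmarks matters (normalization, de-normalization) and a C² cubic
  spline where fidelity on smooth signals matters (uniform resampling);
  both are configurable.
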
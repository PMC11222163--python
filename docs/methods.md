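# Methods

`dualhear` re-implements, against synthetic ground truth, the computational
machinery of a directional-hearing experiment in a miniature fish
(*Danionella cerebrum*): controlled underwater stimulus delivery, startle
quantification, stroboscopic vibrometry, and the logic that discriminates
between candidate directional-hearing algorithms.  This note records the
models, the parameter choices that matter, and the places where a design
decision was genuinely open.

## Monopole acoustics (`acoustics`)

A point source in water (density ρ = 1000 kg m⁻³, sound speed
c = 1500 m s⁻¹) produces, in the e^(−iωt) phasor convention,

    p(r)  = p₀ (r₀/r) e^{ikr},
    v(r)  = [1/(ρc)] (1 + i/(kr)) p(r),
    a(r)  = (1/ρ) (1/r − ik) p(r) = −iω v(r).

Pressure decays as 1/r at all frequencies; particle velocity and
acceleration decay as 1/r² in the near field (kr ≪ 1).  Across a 0.6 mm
inter-ear axis at 3 cm from the source this yields a ~2% pressure-level
difference (frequency independent) and a ~4% velocity-level difference at
low frequency; `velocity_level_drop` exposes the full drop-versus-frequency
curve rather than hard-coding the transition frequency, since the crossover
between the 4% and 2% regimes is a smooth function of kr.

**Waveform-domain conversion.**  For sampled waveforms the relation is
applied per DFT component.  One subtlety is load-bearing: the phasor factor
(1/r − ik) belongs to the e^(−iωt) convention, while the positive-frequency
bins of a forward DFT with negative exponent carry e^(+iωt); the factor on
rfft bins is therefore the conjugate, (1/r + ik), equivalent to the time
domain identity a(t) = p(t)/(ρr) + p′(t)/(ρc).  Using the unconjugated
factor time-reverses the propagating part and silently flips the sign of
the time-averaged p·v product, which the phase-comparison predictor
depends on.  Two further bin conventions: the DC factor is 1/(ρr) (k = 0),
and for even-length signals the Nyquist-bin factor keeps only its real
part so the conversion is a bijection on real signals (a real sampled
signal cannot carry a quadrature Nyquist component).  Band-limited stimuli
have no energy at either bin.

**Binaural cues.**  Level differences are peak-amplitude differences,
max_t|q(x₀,t)| − max_t|q(x₁,t)|, optionally divided by an ear-scale factor
(50 when referring a 3 cm sensor spacing to the 0.6 mm ear axis, 1 when
the two points already are the ears).  Peak amplitudes are taken from the
samples without interpolation; at 51.2 kHz the sub-sample peak error is
negligible against the 2% cue.  Time differences are estimated from the
cross-spectrum phase at the amplitude-weighted centroid frequency divided
by 2πf, with a cross-correlation peak delay available as an independent
check; for the pure geometric path the delay is (r₁ − r₀)/c.  Sign
convention throughout: the x axis runs from the left to the right speaker
and a positive cue means larger or earlier at the left point.  Silent
inputs raise rather than returning a directional zero, and the ITD of an
identical (or silent) pair is flagged undefined.

## Stimulus conditioning (`field_control`)

Speakers are linear systems: the field at a position is the sum of each
speaker's drive convolved with its measured impulse-response kernel for
pressure, x- and y-acceleration.  In the frequency domain each retained
bin gives a 3×M complex system K_l S_l = (P_l, A_{x,l}, A_{y,l})ᵀ, solved
with a bounded least-squares solver after stacking real and imaginary
parts (the box bound applied to both parts approximates the modulus bound
|S| ≤ B).  Bounds are B_{i,l} = α_i γ |P_l| with |P_l| the magnitude
spectrum of the template; they keep speaker signals similar to the target
waveform and prevent speakers from cancelling each other unnecessarily.

Numerical choices:

- **Pass band 200–1200 Hz**, below the lateral-line flow-sensing range at
  the bottom and within the small speakers' response at the top.  Band
  limitation is realized by zeroing DFT bins outside the band.  A sharp
  spectral gate is idempotent, which makes the loop exactly consistent:
  the target is band-limited once, the solver works on exactly the bins
  that survive, and "energy outside the band" is exactly zero.  (A
  zero-phase Butterworth filter would re-attenuate transition-band content
  on every pass and leave the closed loop chasing a moving target.)
- **Modelling delay.**  Targets are delayed by 5 ms inside the
  conditioning window.  The solved drives are inverse filters and must
  *lead* the field by the propagation and speaker-response delay; without
  the delay the acausal pre-drive wraps to the end of the DFT window.
- **Row weighting.**  The pressure row is in Pa, the acceleration rows in
  m s⁻²; acceleration rows are scaled by ρ·r₀ (= 30 kg m⁻² for the 3 cm
  reference) so both components carry comparable weight when bounds force
  a residual trade-off.
- **Drive units.**  γ converts pressure to drive units; by default it is
  the inverse median in-band pressure-kernel magnitude, so α_i = 1 lets a
  speaker roughly produce the target pressure alone.  The default
  α_i = 10 leaves headroom for near-field acceleration targets (which
  need ~(r/r₀)² larger drives) and echo cancellation.
- **Ill-conditioned bins** (kernel condition number > 10⁶) are skipped,
  zeroed and reported in the program diagnostics, never silently NaN.
- **Window lengths.**  Conditioning windows of 4096 samples (80 ms at
  51.2 kHz) hold the 12 ms template, the 5 ms modelling delay and the
  50 ms kernel ring-down; solved fields match their targets to ~0.5%
  relative RMS on the synthetic tank, versus ~12% (pressure) and ~80%
  (acceleration) for an optimally aligned and scaled single-speaker
  playback of the same template.

**Standing waves and the trick.**  Pressure-only and motion-only stimuli
are targets (p, 0, 0) and (0, aₓ, 0); on a symmetric anechoic tank they
reduce to in-phase and anti-phase drive of the opposing pair, and the
solver keeps off-target leakage below 5% on echoic, asymmetric kernels.
The trick configuration is solved in two steps, following the experiment:
the single-speaker solution is computed first, then held within ±1%
bounds while only the two orthogonal-axis speakers are re-conditioned
against the target with the pressure sign flipped.  The postcondition is
verified through prediction: pressure correlation ≤ −0.99 and
x-acceleration correlation ≥ 0.99 against the single-speaker field.

Programs at intermediate positions are bilinear interpolations of the
per-speaker signals from the four surrounding grid nodes; a query on a
solved node returns that node's program exactly.

## Behaviour (`behavior`)

Playback triggers require the fish inside a central 1.5 cm × 3 cm zone,
a heading axis within 45° of the y axis (either direction), and an
elapsed refractory time of 5 s plus a per-trial exponential draw of mean
5 s.  Startles are detected per playback from the centroid speed
(central differences at 120 frames/s, no extra smoothing — the window
average already smooths): locate the speed peak within 200 ms after the
trigger, average over a 25 ms window centred on it, and classify a
startle iff the mean strictly exceeds 17 cm s⁻¹.  The 200 ms search
window is a choice; reactions start within 2 frames and the lateral
displacement phase peaks by 50 ms, so the window comfortably brackets
the event.  Startle onset is defined as the first frame in the window
above threshold, and left/right classification is the sign of the x
displacement over the 50 ms after onset; exact zero displacement is
excluded with a log entry rather than forced into a class.

Directional bias is k/n with an exact two-sided binomial p-value under
p₀ = 0.5, using the minimum-likelihood convention (sum of all outcome
probabilities not exceeding the observed outcome's); the suite checks it
against exhaustive enumeration for every (k, n ≤ 20).  Per-fish biases
are reported only for fish with ≥10 classified startles in both the
pooled single-speaker and pooled trick conditions, with exclusion
reasons in the output.

## Vibrometry (`vibrometry`)

Locking the stimulation frequency to the line rate as
f_stim = (N + 1/nStep)·f_scan, with N = floor(f_stim/f_scan), makes each
repeat of a scan line sample the oscillation at phase offsets of exactly
2π/nStep; nStep ≥ 3 is required to recover amplitude and phase, and
nStep = 4 is the default.  Because the stimulus keeps running while the
beam moves along a line, the probed acoustic phase advances by
2π·f_stim·t_pixel per pixel column; the reconstruction removes this ramp
per column.  (The printed form of this correction, "2π × pixelPeriod",
is dimensionally elliptical; the only dimensionless reading is the pixel
period expressed in stimulation periods, i.e. 2π f_stim t_pixel, which
is what is implemented and what a rigid-motion phantom confirms: flat
phase after correction, a unit-slope ramp before it.)

Displacements between phase steps are estimated by multi-pass block
matching (windows 64→32→16 px, 50% overlap) with FFT cross-correlation
and a three-point Gaussian sub-pixel peak fit.  Two estimator details
matter at the 0.1 px level:

- the zero-padded correlation is renormalized by the per-lag overlap
  fraction; without this the linear "tent" bias drags broad correlation
  peaks toward zero lag by ~10% of the displacement;
- windows are compared step j against step 0 (not chained consecutive
  pairs) to avoid drift accumulation; a constant offset only enters the
  DC term of the phase fit.

Windows without texture or with a correlation peak below 0.3 are masked
invalid; vectors deviating more than 2 px from their 3×3 local median
are masked as outliers and the gaps filled by linear interpolation.  On
an independent-noise image pair over 90% of vectors are masked.

Per pixel, the first Fourier coefficient over the nStep displacement
samples, F₁ = (2/n)Σⱼ dⱼ e^(−2πij/n), equals −iA e^(iψ) for motion
A sin(2πj/n + ψ); multiplying by i gives the complex amplitude directly.
Multi-plane stacks are reduced by per-pixel maximum-amplitude projection.
Region statistics pool pixels inside a mask intersected with the validity
mask: mean ± sd amplitude and circular mean ± sd phase.  Relative motion
between two regions reports the amplitude ratio of region means (a
median-based ratio is included as a robustness companion — with unpaired
regions a per-pixel ratio is not well defined), the circular phase
difference, and the peak relative displacement
|A_A − A_B e^(iΔφ)| = sqrt(A_A² + A_B² − 2 A_A A_B cos Δφ).

## Hypotheses (`hypotheses`)

Seven candidate algorithms map the local field to a predicted startle
direction: binaural level or timing comparisons on pressure (P-ILD,
P-ITD) or particle motion (M-ILD, M-ITD); single-sensor initial-motion
polarity readers (M-polarity ±); and phase comparison between pressure
and directed particle velocity (Schuijf's model), realized quantitatively
as the sign of the time-averaged p(t)·v_x(t) — the x component of the
active acoustic intensity, which points away from the source regardless
of waveform polarity.  v_x comes from cumulative trapezoidal integration
of aₓ with a linear detrend.  Initial motion polarity is the sign of aₓ
at its first crossing of a quarter of its peak magnitude — low enough to
catch the onset lobe, high enough to ignore filter pre-ringing.

A direction is emitted only when the hypothesis's cue (and the relevant
signal amplitude at its sensors) exceeds 5% of its single-speaker
reference value; below the floor the prediction is "undirected".  The
floor encodes "no significant bias" for stimuli that null a cue without
modelling psychometrics; predictions are deterministic labels compared
against majority behaviour, and the observed ~80%/67% response rates are
deliberately not modelled.

The consistency table crosses the twelve stimulus configurations
(4 single-speaker, 2 pressure-only, 2 motion-only, 4 trick) with the
seven predictors, using fields synthesized as monopole superpositions at
the speaker positions and cues taken at the two ear positions ±0.3 mm.
Against the observed outcomes (escape for single-speaker sounds of both
polarities, no bias for either pure component, approach in the trick
condition) the behaviourally consistent set is {Schuijf, P-ILD, P-ITD};
adding the anatomical constraint of a single pressure sensor leaves
{Schuijf} exactly.  Whether the fish reads velocity or acceleration
phase is not distinguishable at this level: the predictors consume v_x
derived from aₓ, and both conventions are reachable through the public
builders.

## Synthetic data (`synthetic`)

The generators define the study conditions; their defaults are not tuned
per test.

- **Template**: carrier at 780 Hz under a half-cosine onset
  (1.5× the nominal rise time) and a 3 ms exponential decay, carrier
  phase π/4, high-pass filtered at 100 Hz, 12 ms at 51.2 kHz, peak
  scaled to 167 dB re 1 µPa (223.9 Pa).  Its measured 10–90% rise time
  is 0.667 ms and its spectral peak 782 Hz; the constructor validates
  both within 10% and raises with a diagnosis otherwise.  The derived
  peak particle acceleration at 3 cm is 7.5 m s⁻².
- **Tank kernels**: 2-D image sources over a 0.30 m reflecting boundary
  (reflection coefficient 0.5, echoes up to order 2), speakers at
  ±8 cm on both axes with a 2nd-order 150–1800 Hz band-pass response,
  kernels built in the frequency domain (exact fractional delays), with
  per-arrival acceleration kernels from the monopole relation projected
  on x/y.  50 ms kernels on the 5×5, 1.5 cm calibration grid.
- **Sessions**: wall-following swimming (y-axis oscillation between the
  white walls with an Ornstein–Uhlenbeck heading wobble and a softly
  centred x position; the travelled y/x distance ratio lands near 2, in
  the neighbourhood of the observed 1.6 — a soft calibration, not a
  contract).  Triggers go through `behavior.should_trigger`; 37% of
  playbacks receive an injected startle (latency ≤ 2 frames) whose x
  displacement is 1 cm ± 0.4 cm over 50 ms and whose direction follows
  per-configuration escape probabilities (0.80 single-speaker, 0.33
  escape — i.e. 0.67 approach — in the trick condition, 0.5 for the
  unbiased standing waves).  The burst phase carries a C-start-like
  speed of 0.38 ± 0.06 m s⁻¹ (floored at 0.28 m s⁻¹) so that injected
  startles have the unambiguous speed signature real C-starts show; the
  post-startle offset relaxes back to the cruise path over ~1.5 s so
  repeated startles do not walk the fish out of the arena.  What the
  generator does **not** emulate: pose/tracking noise, habituation,
  body-bend kinematics, wall interactions during startles — so passing
  detection tests demonstrate the pipeline's correctness on clean
  kinematics, not robustness to tracking artefacts.
- **Vibrometry stacks**: smooth reflectance speckle (Gaussian-filtered
  noise, correlation length 1.5 px) displaced along x by
  A sin(2πj/n + colphase(x) + φ) under the exact stroboscopic timing
  model, sampled with cubic spline interpolation, optional Poisson-like
  noise, 16-bit-scale counts.  The default scan plan assumes a 512-pixel
  full scan line (the simulated 128² field being a crop), which keeps
  the per-pixel phase step small; with only 128 pixels per line the
  phase gradient across a 16 px matching window attenuates recovered
  amplitudes by the window's transfer function (~4% — visible, and worth
  knowing about when configuring real acquisitions).

All generators take a seed (or Generator) and are byte-reproducible; the
multi-fish driver spawns per-fish child seeds from one root seed.

## Problem sizes

Default test and acceptance runs use: 4096-sample conditioning windows on
the 25-node grid (per-bin systems of 6×8 reals, ~80 bins per solve);
600 s behavioural sessions (~50 playbacks each), ten fish for the
detection-quality check; 128² phase stacks at 4 phase steps.  These sizes
were chosen so every check runs in seconds while leaving the estimators
in the regime where their accuracy claims are meaningful (displacements
of 2–5 px for the vibrometry phantom, dozens of events per session).

## Known limitations

- The tank model is an image-source caricature: no modal solutions, no
  free-surface boundary, frequency-independent reflection coefficients.
  It produces realistic-looking reverberant kernels with exact known
  structure, which is what conditioning needs; it does not reproduce any
  particular tank's spatial frequency response.
- The modulus bound |S| ≤ B is enforced on real and imaginary parts
  separately (a √2 over-admission at 45° phase), matching the stacked
  real solver.
- Cross-spectrum ITDs on reverberant fields measure an effective phase
  delay, not the geometric path difference; only the sign enters the
  hypothesis logic.
- The hypothesis predictors are deterministic; they claim nothing about
  response probability or its dependence on stimulus level.
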
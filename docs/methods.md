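# Methods

This note documents the models implemented in `parasolsim`, the parameter
choices behind their defaults, what the synthetic data do and do not
emulate, and the known limitations. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Stimuli

All stimuli are Weber-contrast movies on a physical retinal frame
(µm, Hz). The degree↔retina conversion defaults to 200 µm/degree
(mid-peripheral macaque magnification) and is configurable.

**Rescaling textures.** A single seeded white-noise matrix is bandpass
filtered in the Fourier domain with a raised cosine in log₂ spatial
frequency: gain = 0.5 + 0.5·cos(W), W = log₂(ω / 2f(t)) clamped to ±π, so
the passband peaks at 2f(t) and spans a factor 2^π on either side. The
center frequency decays exponentially, f(t) = exp(ln f₀ − r·t); approaching
movies run from the highest to the lowest spatial frequency and a receding
movie is the exact frame-reversal of its approaching partner, so the two
ensembles contain identical image sets. Defaults: geometric-mean frequency
1.6 cycles/degree over a 1 s motion epoch (so f₀ = 1.6·e^{r/2}), expansion
rates {0.5, 1, 2, 4, 8} s⁻¹, RMS contrast 0.3, 0.25 s gray pre/post epochs,
60 Hz, 64×64 px at 4 µm/px.

Two normalization decisions matter:

* *Per-frame RMS.* Each frame is normalized to the requested RMS contrast
  individually. The raw bandpass output loses energy as the band area
  shrinks (∝ f²), which would make coarse frames nearly blank; a texture
  that is literally a rescaled version of itself keeps its contrast.
  Per-frame normalization preserves exact time-reversal equality because it
  is applied identically to every frame.
* *Filter width as printed.* W is used in radians directly, giving a
  ±π-octave passband. This is broad: frame content is dominated by
  frequencies well above the nominal scale 2f(t). A `bandpass_filter_weights`
  caller can narrow the band by scaling W, but the default follows the
  stated filter.

One consequence of the per-frame filtering construction: frames at nearby
times share overlapping passbands but are *not* literal spatial rescalings
of one another (a zoom maps the noise onto Fourier components with
independent phases), so zoom-correlation between frames is near zero even
though the ensemble-level statistics rescale exactly. A literal-zoom
generator would behave differently in this one respect; we follow the
filtering construction throughout.

**Annuli.** A ring of fixed width whose inner radius moves linearly;
expanding = approaching, contracting = receding, exact time-reverses of
each other. Defaults (the calibrated study conditions, see below): contrast
±0.25, inner radius 20 → 90 µm, width 25 µm, speed 320 µm/s, 240 Hz,
96×96 px at 4 µm/px. The ring's outer edge stays within ~2σ of the model
ganglion cell's receptive-field center (σ_c = 60 µm), so the stimulus
probes the center without strongly engaging the surround.

**Flicker and spots.** Gaussian contrast flicker draws one i.i.d.
N(0, 0.1²) contrast per frame over a spot or annulus; sinusoidally
modulated spots (e.g. 0.5 contrast at 2 Hz) drive area-summation
measurements.

## Receptive-field estimation

The estimation chain mirrors standard LN characterization:

* **Area summation.** F1 amplitude vs spot radius is fitted with the DoG
  area-summation law by bounded least squares, parameterized so
  σ_surround > σ_center always. A "no effective surround" flag is raised
  when the fitted surround contributes <1% of the peak at the largest
  tested radius. The default parasol profile (w_c = 1, w_s = 0.75,
  σ_c = 60 µm, σ_s = 180 µm) peaks at a ~145 µm spot radius.
* **Temporal filter.** Reverse correlation F[k] = Σ_t R(t)S(t−k) /
  ((N−k)·var S), normalized so an exactly linear system returns its
  generating kernel. For Gaussian inputs the estimate through a static
  nonlinearity is proportional to the true kernel (Bussgang), so the
  LN decomposition is recovered up to a gain shared between the filter and
  the nonlinearity's input axis — comparisons of fitted β must rescale by
  the filter amplitude ratio.
* **Damped-oscillator fit.** Nonlinear least squares with multi-starts over
  phase (0/90/180/270°) and log-spaced time constants; requires ≥50 samples.
  Used both as a kinetics summary and to denoise the raw filter before the
  nonlinearity fit (`parametric_filter=True`): estimation noise in the
  filter otherwise propagates into the linear prediction and attenuates the
  fitted slope (errors-in-variables bias).
* **Output nonlinearity.** The prediction is quantile-binned (40 bins by
  default), the mean response per bin is fitted with
  N(x) = ε + α·Φ(βx + γ) via the standard normal CDF.
* **Surround delay.** Difference of time-to-peak (maximum absolute value,
  insensitive to the surround's opposite polarity).
* **Cross-validation.** Pearson r between the LN prediction and the
  trial-averaged response to held-out repeated sequences.

Parameter recovery has identifiability limits that the tests respect: the
nonlinearity's maximal output α is only recoverable when the stimulus
drives the cell through saturation, and σ_surround is only recoverable when
the radius grid reaches the surround's saturation — the synthetic test
cells and sampling grids are chosen accordingly.

## Circuit model

Stage order: space–time filtering (+ Poisson noise) → coupling (coupled
variant only) → output nonlinearity (identity for the linear variant) →
delayed center–surround pooling.

**Units.** Subunit spatial kernels are DoGs of amplitude-normalized
Gaussians scaled by the integrated weights (w_c = 1, w_s = 0.3, σ_c = 16 µm,
σ_s = 48 µm), so a full-field unit-contrast step drives a subunit by
w_c − w_s. Temporal kernels are normalized to unit peak *step response*, so
discrete convolution approximates the continuous filtering integral
independently of the simulation rate — drives from 60 Hz texture runs and
240 Hz annulus runs share one scale. Default kinetics: τ_rise = 30 ms,
τ_decay = 60 ms, τ_period = 180 ms, n = 3, φ = −90°, a biphasic kernel with
~45 ms time-to-peak.

**Coupling sign.** Both conventions are implemented. The package default is
the diffusive update R_i ← R⁰_i + g·Σ_j (R⁰_j − R⁰_i)·e^{−d_ij/λ}: current
flows down the activity difference, spreading signal to less-active
neighbors, which is the physical direction of gap-junction transfer.
The anti-diffusive alternative (`"as-printed"`, each subunit amplifying its
own deviation) is available but produces no approach selectivity for moving
annuli anywhere in the parameter space we explored; under the diffusive sign
the coupled model reproduces the reported selectivity pattern. Coupling is
a single pass computed from the pre-coupling responses; it is linear and
instantaneous, so it commutes with the temporal filtering.

**Subunit nonlinearity and its calibration.** The default rectifier is
α = 1, ε = 0, β = 180, γ = −9: a sharp threshold at 0.05 drive units.
Context for that number: a preferred-contrast (0.25) annulus crossing
drives a subunit to ~0.11 at its peak, and the standard textures produce
drive SDs of 0.013–0.033 — so isolated subunit inputs sit near or below
threshold and coupled input from active neighbors decides transmission.
This regime is what makes the coupled model selective: for an expanding
ring, the wave of activity and the diffusively shared signal cooperate
differently than for a contracting ring, and rectification converts that
timing difference into a response difference. The annulus kinetics,
contrast, subunit kinetics and nonlinearity are not published quantities
(they were measured from cells in the original study); we calibrated them
once, within physiological ranges, so that the coupled model's annulus
selectivity lands at ~0.5 — between the reported On (0.56) and Off (0.46)
values — and then froze them. Our On and Off models are exact mirrors
(contrast sign flipped into the subunits, same parameters), so they produce
identical indices; the On/Off difference in the original data reflects
measured parameter differences that are not available to us.

**Noise.** Poisson noise is applied to subunit traces: the trace is offset
to non-negative, scaled to a Poisson intensity chosen so the sampling noise
SD is 10% of the pre-noise response SD, sampled, and the offset removed.

**Pooling.** Center and surround pools weight all subunits by Gaussian
profiles of the ganglion DoG and are each normalized by the sum of their
weights (an effective weighted mean, stable under mosaic density changes);
the surround pool is delayed 15 ms before the weighted subtraction.

**Variants.** `coupled` applies coupling with g = 0.1 and λ = 36.4 µm;
`enlarged` disables coupling and scales the subunit DoG to a 40 µm two-SD
diameter — the lateral-spread control; `linear` bypasses the rectifier.
With g = 0 the coupled variant is bit-identical to the nonlinear one.

**Epoch responses.** Responses are means over the motion epoch minus the
pre-motion mean. The linear-model time-reversal identity (equal total
output for a movie and its reversal, to machine precision) holds when the
surround delay is 0 and the post-motion epoch covers the kernel duration
(default: 0.25 s post epoch, 250 ms kernels), using the motion-through-end
window.

## Decoding

Paired On/Off model cells (square cell lattices, the Off mosaic shifted by
a random offset up to half the 120 µm spacing; pairs formed by nearest
Euclidean distance) respond to each texture and its time-reversal. The
linear decoder sums the per-trial epoch responses; the quadratic decoder
adds squared terms; all coefficients default to 1 (the readout's functional
form, not its weighting, is the object of study). Outputs are scaled so the
maximum magnitude maps to 100, rounded to integers, histogrammed on the
union support with no smoothing (0·log 0 := 0), and scored with the
Jensen–Shannon distance in bits.

## What the synthetic data do and do not show

The synthetic LN "recordings" (inhomogeneous-Poisson spikes, clamp-style
currents with Gaussian noise) validate the estimation chain end-to-end:
passing tests show the estimators are consistent and correctly normalized
for data generated by the model class they assume. They do not show
robustness to real-data pathologies — spike-sorting errors, adaptation,
nonstationarity, or non-separable receptive fields — which are outside the
model class. Likewise the circuit-model results characterize this model
under these synthetic stimulus conditions; matching the reported selectivity
pattern supports the mechanism's sufficiency, not uniqueness.

## Numerical choices

* Seeds: every stochastic operation takes an explicit seed;
  `numpy.random.SeedSequence` spawning keeps mosaic jitter, Poisson noise,
  and texture seeds independent.
* Annulus movies at 240 Hz resolve the subunit-crossing dynamics
  (neighbor-lag 100 ms vs 4 ms sampling); texture movies run at the 60 Hz
  display-style rate.
* Pixel pitch must satisfy σ_center ≥ 4 px for subunit filtering.
* Degenerate cases: zero-variance stimuli, flat filters, constant
  predictions and both-zero selectivity inputs raise or flag rather than
  return silent numbers.
* The damped-oscillator fit breaks ties across multi-starts by SSE; the
  cumulative-Gaussian fit multi-starts over slope and offset.

## Known limitations

* **Gain sweep shape.** Coupled-model selectivity peaks near g = 0.1 and
  declines for g ≥ 0.2, because the diffusive single-pass update's own-
  weight (1 − g·Σ_j K_ij) turns negative at large gains; the original
  study reports high selectivity over g ≈ 0.1–0.4. A multi-pass or
  implicit (resistive-network) coupling solution would be needed to probe
  large gains meaningfully.
* **Discriminability vs rate.** The Jensen–Shannon distance is ≥ ~0.35 at
  every rate under default conditions but is not monotone in expansion
  rate: in a 1.28°-field simulation the texture-to-texture variability at
  slow rates is small, so even small approach biases separate the
  distributions. The same applies to the spatial-frequency sweep
  (`sweep_max_frequency`): the reported fall-off of discriminability at very
  low maximum spatial frequencies does not emerge here. Reproducing either
  trend would require the (unpublished) absolute noise magnitudes.
* On/Off asymmetries, crossover inhibition, spiking dynamics and
  non-separable receptive fields are not modelled.
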
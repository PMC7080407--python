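# parasolsim

Circuit models of approach-motion selectivity in primate parasol retinal
ganglion cells.

Parasol (magnocellular-projecting) ganglion cells respond more strongly to
*approaching* motion — textures whose spatial scale grows in time, or annuli
expanding across the receptive field — than to the identical stimuli played
in reverse. `parasolsim` implements the modelling pipeline used to study
where that asymmetry can arise in the retinal circuit: a mosaic of
bipolar-cell–scale subunits feeding a model ganglion cell, with the key
circuit ingredients (output rectification and gap-junction coupling between
subunits) switchable one at a time. It is aimed at computational
neuroscientists who want a tested, reproducible reference implementation of
the subunit/coupling analysis, with every stimulus and "recording"
synthesized in code.

## The model

A model ganglion cell pools a jittered hexagonal mosaic of subunits
(nominal spacing 32 µm, positional jitter SD 2 µm) in four stages:

1. **Space–time filtering.** Each subunit filters the stimulus contrast
   S(x⃗, t) with a separable receptive field: a difference-of-Gaussians
   (DoG) in space,

       R(r) = w_c (1 − e^{−r²/2σ_c²}) − w_s (1 − e^{−r²/2σ_s²})

   (area-summation form; σ_c = 16 µm for a 32 µm two-SD subunit diameter),
   and a damped oscillator with sigmoidal onset in time,

       F(t) = A (t/τ_rise)^n / (1 + (t/τ_rise)^n) · e^{−t/τ_decay} ·
              cos(2πt/τ_period + φ).

   Poisson noise models synaptic variability.
2. **Electrical coupling** (coupled variant). Subunits share signal through
   gap junctions in a single pass from the pre-coupling responses R⁰:
   R_i = R⁰_i + Σ_j g (R⁰_j − R⁰_i) e^{−d_ij/λ}, with gain g = 0.1 and
   length constant λ = 36.4 µm.
3. **Output nonlinearity.** A rectifying cumulative Gaussian
   N(x) = ε + α Φ(βx + γ) models bipolar synaptic transfer; the *linear*
   variant uses y = x instead.
4. **Pooling.** Subunit outputs are weighted by Gaussian profiles of the
   ganglion cell's center (σ = 60 µm) and surround (σ = 180 µm), the
   surround is delayed by 15 ms, and the pools are subtracted.

Four variants — `linear`, `nonlinear`, `coupled`, and `enlarged` (uncoupled,
with subunit receptive fields enlarged to 40 µm to mimic the lateral spread
coupling produces) — isolate which ingredient creates the approach bias.
Selectivity is quantified by the approach-selectivity index
ASI = (R_approach − R_recede) / (R_approach + R_recede) on
baseline-subtracted, non-negative epoch responses. Downstream readout is
modelled by linear and quadratic decoders over paired On/Off model cells,
scored with the Jensen–Shannon distance (log₂, integer-discretized outputs,
bounded in [0, 1]).

The package also contains the full receptive-field *estimation* chain used
to set such model parameters from data — DoG fits to area-summation curves,
reverse-correlation temporal filters, damped-oscillator fits,
cumulative-Gaussian nonlinearity fits, center–surround delay — plus a
synthetic-data module that generates ground-truth-known LN-model "recordings"
(spike trains, clamp-style currents) so the whole chain is testable without
any experimental data.

## Worked example

```python
from parasolsim import (GanglionModelConfig, approach_recede_indices,
                        default_annulus_pair)

approach, recede = default_annulus_pair(contrast=0.25)
for variant in ("linear", "nonlinear", "coupled", "enlarged"):
    cfg = GanglionModelConfig(variant=variant, polarity="on")
    idx = approach_recede_indices(cfg, approach, recede, n_seeds=20, seed=1)
    print(f"{variant:10s} ASI = {idx.mean():+.3f} ± "
          f"{idx.std(ddof=1) / len(idx) ** 0.5:.3f}")
```

prints

```
linear     ASI = +0.029 ± 0.000
nonlinear  ASI = +0.023 ± 0.001
coupled    ASI = +0.520 ± 0.021
enlarged   ASI = +0.024 ± 0.001
```

Reading: for a ring sweeping outward vs inward across the receptive-field
center, neither linear integration, nor subunit rectification alone, nor
simply enlarging the subunits produces more than a trace preference for the
expanding direction (|ASI| ≤ 0.03) — but electrical coupling between rectified subunits
produces a strong one (ASI ≈ 0.5: the approaching response is about three
times the receding response). Coupled input from already-active neighbors
decides whether a near-threshold subunit transmits, and the expanding and
contracting waves of activity interact differently with the mosaic's
geometry.

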
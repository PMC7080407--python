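"""Ground-truth-known synthetic "recordings" from LN model neurons.

Every estimation and metric stage of the package is testable without any
recorded data: an LN model cell with known difference-of-Gaussians spatial
profile, damped-oscillator temporal kinetics (lagged surround), and a
rectifying cumulative-Gaussian output nonlinearity produces spike trains
(inhomogeneous Poisson) and voltage-clamp-style current traces.  Feeding
these back through :mod:`parasolsim.rf_estimation` must recover the
generating parameters -- the round-trip property that anchors the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import signal

from .rf_estimation import (DoGParams, NonlinearityParams,
                            TemporalFilterParams, temporal_kernel)
from .stimuli import StimulusMovie
from .circuit_model import ResponseTrace

__all__ = [
    "SyntheticCellSpec",
    "simulate_ln_response",
    "simulate_ln_trajectory_response",
    "simulate_current_trace",
    "area_summation_measurements",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class SyntheticCellSpec:
    """A synthetic LN model cell standing in for a recorded ganglion cell.

    The surround shares the center's temporal kinetics but acts with
    ``surround_lag_ms`` delay.  ``rate_scale`` converts the nonlinearity's
    output (0..alpha) to spikes/s for Poisson spike generation;
    ``current_scale`` converts it to pA for simulated clamp currents.
    """

    polarity: Literal["on", "off"] = "on"
    dog: DoGParams = field(default_factory=lambda: DoGParams(1.0, 0.75, 60.0, 180.0))
    temporal: TemporalFilterParams = field(
        default_factory=lambda: TemporalFilterParams(
            A=1.0, tau_rise=35.0, tau_decay=70.0, tau_period=200.0,
            n=3.0, phi=-90.0))
    nonlinearity: NonlinearityParams = field(
        default_factory=lambda: NonlinearityParams(
            alpha=1.0, epsilon=0.05, beta=3.0, gamma=-1.0))
    surround_lag_ms: float = 15.0
    rate_scale: float = 120.0       # spikes/s at full nonlinearity output
    current_scale: float = 200.0    # pA at full nonlinearity output
    current_noise_sd: float = 5.0   # pA
    kernel_duration_ms: float = 400.0
    seed: int = 0


def _ln_drive(spec: SyntheticCellSpec, movie: StimulusMovie) -> np.ndarray:
    """Center-minus-lagged-surround generator signal for a movie."""
    half = min(movie.shape[1], movie.shape[2]) * movie.pixel_pitch / 2.0
    if half < spec.dog.sigma_center:
        raise ValueError(
            f"movie field half-extent {half:.0f} µm does not cover the "
            f"cell's center sigma {spec.dog.sigma_center:.0f} µm")
    frames = movie.frames.reshape(movie.n_frames, -1).T
    # center and surround Gaussian projections
    x, y = movie.pixel_coordinates()
    gx = np.broadcast_to(x[None, :], (y.size, x.size)).ravel()
    gy = np.broadcast_to(y[:, None], (y.size, x.size)).ravel()
    d2 = gx ** 2 + gy ** 2
    area = movie.pixel_pitch ** 2
    g_c = (spec.dog.w_center / (2 * np.pi * spec.dog.sigma_center ** 2)
           * np.exp(-d2 / (2 * spec.dog.sigma_center ** 2))) * area
    g_s = (spec.dog.w_surround / (2 * np.pi * spec.dog.sigma_surround ** 2)
           * np.exp(-d2 / (2 * spec.dog.sigma_surround ** 2))) * area
    proj_c = g_c @ frames
    proj_s = g_s @ frames
    sign = 1.0 if spec.polarity == "on" else -1.0
    dt_ms = 1000.0 / movie.frame_rate
    kern = temporal_kernel(spec.temporal, dt_ms, spec.kernel_duration_ms,
                           normalize="step")
    drive_c = signal.fftconvolve(sign * proj_c, kern)[: movie.n_frames]
    drive_s = signal.fftconvolve(sign * proj_s, kern)[: movie.n_frames]
    lag = int(round(spec.surround_lag_ms / 1000.0 * movie.frame_rate))
    if lag > 0:
        drive_s = np.concatenate([np.full(lag, drive_s[0]), drive_s[:-lag]])
    return drive_c - drive_s


def simulate_ln_response(spec: SyntheticCellSpec, movie: StimulusMovie
                         ) -> tuple[ResponseTrace, np.ndarray]:
    """Continuous firing rate and Poisson spike times for a movie.

    rate(t) = rate_scale * N(drive(t)) with N the cell's cumulative-
    Gaussian nonlinearity; spikes are drawn from an inhomogeneous Poisson
    process (per-bin counts, uniformly jittered within bins).
    Deterministic under the spec's seed.
    """
    drive = _ln_drive(spec, movie)
    rate = spec.rate_scale * spec.nonlinearity.evaluate(drive)
    trace = ResponseTrace(rate, movie.frame_rate, movie.epoch_markers)
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / movie.frame_rate
    counts = rng.poisson(np.maximum(rate, 0.0) * dt)
    times = []
    for k, c in enumerate(counts):
        if c:
            times.extend(k * dt + rng.uniform(0.0, dt, size=c))
    return trace, np.sort(np.asarray(times))


def simulate_ln_trajectory_response(spec: SyntheticCellSpec,
                                    contrast_trajectory: np.ndarray,
                                    frame_rate: float,
                                    noise_sd: float = 0.0,
                                    seed: int | None = None) -> np.ndarray:
    """LN response to a full-field (spatially uniform) contrast trajectory.

    The spatial stage reduces to a scalar gain of w_center - w_surround
    (no surround lag separation for a spatially uniform stimulus on the
    center path alone); used for fast temporal-filter recovery tests on
    long flicker sequences without building large movies.
    """
    sign = 1.0 if spec.polarity == "on" else -1.0
    gain = spec.dog.w_center  # center path only: uniform spot over center
    dt_ms = 1000.0 / frame_rate
    kern = temporal_kernel(spec.temporal, dt_ms, spec.kernel_duration_ms,
                           normalize="step")
    drive = signal.fftconvolve(sign * gain * contrast_trajectory,
                               kern)[: len(contrast_trajectory)]
    out = spec.rate_scale * spec.nonlinearity.evaluate(drive)
    if noise_sd > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out


def simulate_current_trace(spec: SyntheticCellSpec, movie: StimulusMovie,
                           reversal_condition: Literal["excitatory",
                                                       "inhibitory"]
                           = "excitatory") -> ResponseTrace:
    """Voltage-clamp-style synaptic current trace in pA.

    The continuous LN output is scaled to pA with additive Gaussian noise.
    By convention excitatory currents are negative-going (cation influx at
    the inhibitory reversal potential) and inhibitory currents
    positive-going.
    """
    drive = _ln_drive(spec, movie)
    out = spec.current_scale * (spec.nonlinearity.evaluate(drive)
                                - spec.nonlinearity.evaluate(
                                    np.zeros(1))[0])
    sign = -1.0 if reversal_condition == "excitatory" else 1.0
    rng = np.random.default_rng(spec.seed)
    current = sign * out + rng.normal(0.0, spec.current_noise_sd,
                                      size=out.shape)
    return ResponseTrace(current, movie.frame_rate, movie.epoch_markers)


def area_summation_measurements(dog: DoGParams, radii: np.ndarray,
                                noise_fraction: float = 0.02,
                                seed: int = 0) -> np.ndarray:
    """Synthetic F1-amplitude area-summation curve with multiplicative noise.

    Emulates the spot-size experiment: response amplitudes follow the DoG
    area-summation law, corrupted by Gaussian noise of the given fractional
    SD and clipped at zero (amplitudes are nonnegative).
    """
    from .rf_estimation import area_summation_response

    rng = np.random.default_rng(seed)
    clean = area_summation_response(radii, dog.w_center, dog.w_surround,
                                    dog.sigma_center, dog.sigma_surround)
    noisy = clean * (1.0 + rng.normal(0.0, noise_fraction, size=clean.shape))
    return np.maximum(noisy, 0.0)


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

def make_fixture_suite(out_dir, master_seed: int = 0) -> dict:
    """Write a small self-contained fixture set and a JSON manifest.

    Contents: one approaching/receding texture pair per default expansion
    rate, one annulus pair, a flicker stimulus with a matched synthetic LN
    response, and an area-summation data set.  Regeneration under the same
    master seed is byte-identical in every HDF5 payload dataset.
    """
    from .stimuli import (AnnulusSpec, DEFAULT_EXPANSION_RATES, TextureSpec,
                          generate_annulus_sequence, generate_gaussian_flicker,
                          generate_texture_sequence)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(master_seed)
    manifest = {"master_seed": master_seed, "files": []}

    def record(name, seed, kind):
        manifest["files"].append({"file": name, "seed": int(seed),
                                  "kind": kind})

    children = root.spawn(len(DEFAULT_EXPANSION_RATES) + 3)
    for rate, child in zip(DEFAULT_EXPANSION_RATES, children):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        spec = TextureSpec.from_geometric_mean(1.6, rate, 1.0, seed=seed)
        approach = generate_texture_sequence(spec, 32, 32, pixel_pitch=4.0)
        recede = approach.time_reversed()
        for direction, movie in (("approaching", approach),
                                 ("receding", recede)):
            name = f"texture_rate{rate:g}_{direction}.h5"
            movie.to_hdf5(out / name)
            record(name, seed, "texture")

    ann_seed = int(children[-3].generate_state(1)[0] % (2 ** 31))
    for direction in ("approaching", "receding"):
        spec = AnnulusSpec(direction=direction)
        movie = generate_annulus_sequence(spec, 64, 64, pixel_pitch=4.0)
        name = f"annulus_{direction}.h5"
        movie.to_hdf5(out / name)
        record(name, ann_seed, "annulus")

    flick_seed = int(children[-2].generate_state(1)[0] % (2 ** 31))
    flicker, trajectory = generate_gaussian_flicker(
        "spot", {"radius": 60.0}, n_frames=3000, seed=flick_seed,
        width_px=40, height_px=40)
    flicker.to_hdf5(out / "flicker_spot.h5")
    record("flicker_spot.h5", flick_seed, "flicker")
    cell = SyntheticCellSpec(seed=flick_seed)
    trace, spikes = simulate_ln_response(cell, flicker)
    trace.to_hdf5(out / "flicker_response.h5")
    record("flicker_response.h5", flick_seed, "ln_response")

    area_seed = int(children[-1].generate_state(1)[0] % (2 ** 31))
    radii = np.array([7, 15, 30, 60, 90, 120, 145, 180, 240, 300, 360],
                     dtype=float)
    amps = area_summation_measurements(cell.dog, radii, seed=area_seed)
    np.savetxt(out / "area_summation.csv",
               np.column_stack([radii, amps]), delimiter=",",
               header="radius_um,f1_amplitude", comments="")
    record("area_summation.csv", area_seed, "area_summation")

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
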
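"""Four-stage subunit circuit model of a parasol ganglion cell.

The model ganglion cell pools a jittered hexagonal mosaic of bipolar-cell
"subunits" in four stages:

1. **Space-time filtering** -- each subunit projects the stimulus through a
   difference-of-Gaussians spatial filter and a damped-oscillator temporal
   kernel (space-time separable); Poisson noise emulates synaptic
   variability.
2. **Electrical coupling** (coupled variant only) -- subunits share signal
   with neighbors through gap junctions: a single-pass update computed from
   the pre-coupling responses, scaled by a coupling gain and an exponential
   function of pairwise distance.
3. **Subunit output nonlinearity** -- a rectifying cumulative Gaussian
   models the bipolar synaptic transfer (the linear variant uses y = x).
4. **Pooling** -- subunit outputs are weighted by Gaussian distance profiles
   for the ganglion cell's center and surround, the surround is delayed,
   and the two pools are subtracted.

Four variants: ``linear`` (identity subunit output), ``nonlinear``
(rectified subunits, no coupling), ``coupled`` (rectified + electrically
coupled), and ``enlarged`` (rectified, uncoupled, with subunit receptive
fields enlarged to emulate the lateral spread that coupling produces).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal
from scipy.spatial.distance import squareform, pdist

from .metrics import approach_selectivity_index, epoch_response
from .rf_estimation import (DoGParams, NonlinearityParams,
                            TemporalFilterParams, temporal_kernel)
from .stimuli import StimulusMovie

__all__ = [
    "SubunitMosaic",
    "CouplingParams",
    "GanglionModelConfig",
    "ResponseTrace",
    "CompiledCell",
    "build_subunit_mosaic",
    "filter_stimulus",
    "add_poisson_noise",
    "apply_coupling",
    "apply_subunit_nonlinearity",
    "pool_subunits",
    "run_model",
    "approach_recede_indices",
    "sweep_coupling_gain",
    "default_subunit_dog",
    "default_subunit_temporal",
    "default_ganglion_dog",
    "default_nonlinearity",
]

Variant = Literal["linear", "nonlinear", "coupled", "enlarged"]

# Nominal subunit geometry: 32 µm two-standard-deviation diameter
# (sigma_center = 16 µm) on a 32 µm hexagonal lattice with 2 µm jitter.
NOMINAL_SPACING = 32.0
NOMINAL_JITTER_SD = 2.0


def default_subunit_dog() -> DoGParams:
    """Diffuse-bipolar-scale DoG: 16 µm center sigma, 3x broader surround
    carrying ~30% of the center weight."""
    return DoGParams(w_center=1.0, w_surround=0.3,
                     sigma_center=16.0, sigma_surround=48.0)


def default_subunit_temporal() -> TemporalFilterParams:
    """Biphasic bipolar temporal kernel, time-to-peak ~45 ms."""
    return TemporalFilterParams(A=1.0, tau_rise=30.0, tau_decay=60.0,
                                tau_period=180.0, n=3.0, phi=-90.0)


def default_ganglion_dog() -> DoGParams:
    """Parasol-scale pooling profile; the implied area-summation curve
    peaks near a 145 µm spot radius."""
    return DoGParams(w_center=1.0, w_surround=0.75,
                     sigma_center=60.0, sigma_surround=180.0)


def default_nonlinearity() -> NonlinearityParams:
    """Strongly rectifying bipolar output nonlinearity.

    Drive units are set by the step-normalized kernels: a sustained
    preferred stimulus covering a subunit's center drives it to ~0.5.  The
    default places the half-activation threshold at 0.050 drive units
    (about half the peak drive of a preferred-contrast annulus crossing,
    and ~2.5 SD of the drive produced by rescaling textures at 0.3 RMS
    contrast) with a sharp transition, so isolated subunit inputs sit near
    threshold and coupled input from active neighbors decides transmission.
    """
    return NonlinearityParams(alpha=1.0, epsilon=0.0, beta=180.0, gamma=-9.0)


@dataclass(frozen=True)
class CouplingParams:
    """Gap-junction coupling between subunits.

    ``g`` is the coupling gain (the fraction of the driving-force
    difference shared between a subunit pair), ``length_constant`` the
    exponential space constant in µm.  ``sign_convention``:

    * ``"diffusive"`` (default): each subunit adds g*(R_j - R_i), the
      physical gap-junction update -- current flows down the voltage
      difference, spreading signal to less-active neighbors.  This is the
      convention under which coupling produces approach selectivity here.
    * ``"as-printed"``: each subunit adds g*(R_i - R_j), amplifying its own
      deviation from its neighbors (an anti-diffusive update).
    """

    g: float = 0.1
    length_constant: float = 36.4
    sign_convention: Literal["as-printed", "diffusive"] = "diffusive"

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("coupling gain must be >= 0")
        if self.length_constant <= 0:
            raise ValueError("coupling length constant must be > 0")


@dataclass
class SubunitMosaic:
    """Jittered hexagonal lattice of subunit receptive fields.

    ``positions`` are (x, y) in µm relative to the ganglion cell's
    receptive-field center; ``distances`` is the symmetric pairwise
    Euclidean distance matrix.
    """

    positions: np.ndarray
    spacing: float
    jitter_sd: float
    dog: DoGParams
    temporal: TemporalFilterParams
    distances: np.ndarray = field(default=None)
    region_labels: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.distances is None:
            self.distances = squareform(pdist(self.positions))

    @property
    def n_subunits(self) -> int:
        return self.positions.shape[0]

    @property
    def radial_distances(self) -> np.ndarray:
        """Distance of each subunit from the ganglion RF center (µm)."""
        return np.hypot(self.positions[:, 0], self.positions[:, 1])


def build_subunit_mosaic(spacing: float = NOMINAL_SPACING,
                         jitter_sd: float = NOMINAL_JITTER_SD,
                         extent: float = 720.0,
                         seed: int | np.random.Generator = 0,
                         dog: DoGParams | None = None,
                         temporal: TemporalFilterParams | None = None,
                         center_radius: float | None = None) -> SubunitMosaic:
    """Jittered hexagonal subunit mosaic covering a square field.

    ``extent`` is the full field width (µm), centered on the ganglion RF
    center; it must cover the ganglion center plus surround.  Each lattice
    point is shifted independently in x and y by N(0, jitter_sd^2).
    ``center_radius`` (µm) labels subunits as center- vs surround-pool
    (informational; pooling itself uses Gaussian distance weights).
    """
    if extent < 2 * spacing:
        raise ValueError(
            f"extent {extent} µm too small: needs at least {2 * spacing} µm "
            "to host a mosaic")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dy = spacing * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(extent / dy)) + 1
    n_cols = int(np.ceil(extent / spacing)) + 1
    pts = []
    for j in range(-(n_rows // 2), n_rows // 2 + 1):
        y = j * dy
        x_off = (abs(j) % 2) * spacing / 2.0
        for i in range(-(n_cols // 2), n_cols // 2 + 1):
            pts.append((i * spacing + x_off, y))
    pts = np.asarray(pts, dtype=float)
    half = extent / 2.0
    keep = (np.abs(pts[:, 0]) <= half) & (np.abs(pts[:, 1]) <= half)
    pts = pts[keep]
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
    dog = dog if dog is not None else default_subunit_dog()
    temporal = temporal if temporal is not None else default_subunit_temporal()
    mosaic = SubunitMosaic(pts, spacing, jitter_sd, dog, temporal)
    if center_radius is not None:
        labels = np.where(mosaic.radial_distances <= center_radius,
                          "center", "surround")
    else:
        labels = np.full(mosaic.n_subunits, "center", dtype=object)
    mosaic.region_labels = labels
    return mosaic


@dataclass
class ResponseTrace:
    """Model ganglion output (or simulated recording) per time sample."""

    values: np.ndarray
    rate: float
    epoch_markers: tuple[int, int]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("rate", data=self.rate)
            f.create_dataset("epoch_markers", data=np.asarray(self.epoch_markers))

    @classmethod
    def from_hdf5(cls, path) -> "ResponseTrace":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["values"][...], float(f["rate"][()]),
                       tuple(int(v) for v in f["epoch_markers"][...]))


@dataclass
class GanglionModelConfig:
    """One of the four model variants plus all circuit parameters.

    ``noise_scale`` sets the Poisson noise magnitude as the target noise SD
    expressed as a fraction of the pre-noise response SD (0 disables).
    ``enlarged_diameter`` is the two-SD subunit diameter (µm) used by the
    ``enlarged`` variant (coupling is never applied in that variant).
    """

    variant: Variant = "nonlinear"
    polarity: Literal["on", "off"] = "on"
    ganglion_dog: DoGParams = field(default_factory=default_ganglion_dog)
    subunit_dog: DoGParams = field(default_factory=default_subunit_dog)
    subunit_temporal: TemporalFilterParams = field(
        default_factory=default_subunit_temporal)
    nonlinearity: NonlinearityParams = field(default_factory=default_nonlinearity)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    surround_delay_ms: float = 15.0
    noise_scale: float = 0.1
    spacing: float = NOMINAL_SPACING
    jitter_sd: float = NOMINAL_JITTER_SD
    extent: float | None = None
    enlarged_diameter: float = 40.0
    kernel_duration_ms: float = 250.0

    def __post_init__(self):
        if self.variant not in ("linear", "nonlinear", "coupled", "enlarged"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.polarity not in ("on", "off"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.surround_delay_ms < 0:
            raise ValueError("surround delay must be >= 0")
        if self.variant == "enlarged":
            nominal = 2.0 * self.subunit_dog.sigma_center
            if self.enlarged_diameter <= nominal:
                raise ValueError(
                    f"enlarged diameter {self.enlarged_diameter} µm must "
                    f"exceed the nominal {nominal} µm")

    @property
    def coupling_gain(self) -> float:
        """Effective gain: coupling acts only in the coupled variant."""
        return self.coupling.g if self.variant == "coupled" else 0.0

    @property
    def effective_subunit_dog(self) -> DoGParams:
        """Subunit DoG after any variant-specific enlargement."""
        if self.variant == "enlarged":
            factor = self.enlarged_diameter / (2.0 * self.subunit_dog.sigma_center)
            return self.subunit_dog.scaled(factor)
        return self.subunit_dog

    @property
    def effective_extent(self) -> float:
        return (self.extent if self.extent is not None
                else 4.0 * self.ganglion_dog.sigma_surround)


# ---------------------------------------------------------------------------
# Stage 1: space-time filtering
# ---------------------------------------------------------------------------

def _spatial_weights(mosaic_positions: np.ndarray, dog: DoGParams,
                     movie: StimulusMovie,
                     center: tuple[float, float]) -> np.ndarray:
    """(n_subunits, n_pixels) DoG inner-product weights.

    Each row is a normalized 2-D DoG sampled at the movie's pixel centers
    (coordinates relative to the ganglion cell ``center``), scaled by the
    pixel area so the row approximates the continuous spatial integral.
    A full-field unit-contrast frame therefore drives each subunit by about
    w_center - w_surround.
    """
    x, y = movie.pixel_coordinates()
    px = x[None, :] - center[0]
    py = y[:, None] - center[1]
    # pixel grid, flattened (row-major: y then x)
    gx = np.broadcast_to(px, (y.size, x.size)).ravel()
    gy = np.broadcast_to(py, (y.size, x.size)).ravel()
    sx = mosaic_positions[:, 0][:, None]
    sy = mosaic_positions[:, 1][:, None]
    d2 = (gx[None, :] - sx) ** 2 + (gy[None, :] - sy) ** 2
    c = dog.w_center / (2 * np.pi * dog.sigma_center ** 2)
    s = dog.w_surround / (2 * np.pi * dog.sigma_surround ** 2)
    w = (c * np.exp(-d2 / (2 * dog.sigma_center ** 2))
         - s * np.exp(-d2 / (2 * dog.sigma_surround ** 2)))
    return w * movie.pixel_pitch ** 2


def filter_stimulus(mosaic: SubunitMosaic, movie: StimulusMovie,
                    noise_scale: float = 0.0,
                    seed: int | np.random.Generator | None = None,
                    polarity: str = "on",
                    kernel_duration_ms: float = 250.0,
                    center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Per-subunit linear responses: spatial DoG projection per frame, then
    causal temporal convolution; optional Poisson noise.

    The movie's pixel pitch must resolve the subunit center
    (sigma_center >= 4 pixels).  Returns an (n_subunits, n_frames) array.
    """
    if movie.pixel_pitch > mosaic.dog.sigma_center / 4.0:
        raise ValueError(
            f"pixel pitch {movie.pixel_pitch} µm too coarse for subunit "
            f"sigma {mosaic.dog.sigma_center} µm (need >= 4 px per sigma)")
    w = _spatial_weights(mosaic.positions, mosaic.dog, movie, center)
    frames = movie.frames.reshape(movie.n_frames, -1).T  # (n_px, n_t)
    drive = w @ frames
    if polarity == "off":
        drive = -drive
    dt_ms = 1000.0 / movie.frame_rate
    kern = temporal_kernel(mosaic.temporal, dt_ms, kernel_duration_ms,
                           normalize="step")
    traces = signal.fftconvolve(drive, kern[None, :], mode="full",
                                axes=1)[:, : drive.shape[1]]
    if noise_scale > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        traces = add_poisson_noise(traces, noise_scale, rng)
    return traces


def add_poisson_noise(traces: np.ndarray, noise_scale: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Poisson-sample the traces at an intensity calibrated to the target
    fractional noise SD.

    The array is offset to nonnegative values, scaled to a Poisson
    intensity ``k`` chosen so the average sampling noise SD is
    ``noise_scale`` times the pre-noise response SD, sampled, rescaled, and
    the offset removed.
    """
    sd = float(traces.std())
    if sd == 0:
        return traces
    lo = float(traces.min())
    shifted = traces - lo
    mean_level = float(shifted.mean())
    if mean_level == 0:
        return traces
    k = mean_level / (noise_scale * sd) ** 2
    return rng.poisson(shifted * k).astype(float) / k + lo


# ---------------------------------------------------------------------------
# Stage 2: electrical coupling
# ---------------------------------------------------------------------------

def apply_coupling(pre_coupling: np.ndarray, mosaic: SubunitMosaic,
                   params: CouplingParams) -> np.ndarray:
    """Single-pass gap-junction update from the pre-coupling responses R0.

    as-printed:  R_i = R0_i + g * sum_j (R0_i - R0_j) * exp(-d_ij / lambda)
    diffusive:   R_i = R0_i + g * sum_j (R0_j - R0_i) * exp(-d_ij / lambda)

    The sum runs over all pairs (the self term vanishes); no iteration.
    """
    if params.g == 0:
        return pre_coupling
    k = np.exp(-mosaic.distances / params.length_constant)
    np.fill_diagonal(k, 0.0)
    ksum = k.sum(axis=1)
    delta = ksum[:, None] * pre_coupling - k @ pre_coupling
    if params.sign_convention == "diffusive":
        delta = -delta
    return pre_coupling + params.g * delta


# ---------------------------------------------------------------------------
# Stage 3: subunit input-output function
# ---------------------------------------------------------------------------

def apply_subunit_nonlinearity(traces: np.ndarray,
                               params: NonlinearityParams,
                               variant: Variant) -> np.ndarray:
    """Linear variant: identity (y = x).  All others: the rectifying
    cumulative-Gaussian nonlinearity applied elementwise."""
    if variant == "linear":
        return traces
    return params.evaluate(traces)


# ---------------------------------------------------------------------------
# Stage 4: pooling
# ---------------------------------------------------------------------------

def pool_subunits(outputs: np.ndarray, mosaic: SubunitMosaic,
                  config: GanglionModelConfig,
                  frame_rate: float,
                  epoch_markers: tuple[int, int] = (0, 0)) -> ResponseTrace:
    """Gaussian-weighted center/surround pooling with a delayed surround.

    Each pool is the subunit outputs weighted by exp(-d_i^2 / 2 sigma_x^2)
    (d_i = distance from the ganglion RF center) and normalized by the sum
    of its weights, so z_x is an effective weighted mean per pool.  The
    surround pool is delayed by ``surround_delay_ms`` before the
    subtraction z = w_center*z_center - w_surround*z_surround.
    """
    d = mosaic.radial_distances
    g = config.ganglion_dog
    wc = np.exp(-d ** 2 / (2 * g.sigma_center ** 2))
    ws = np.exp(-d ** 2 / (2 * g.sigma_surround ** 2))
    z_c = (wc @ outputs) / wc.sum()
    z_s = (ws @ outputs) / ws.sum()
    delay = int(round(config.surround_delay_ms / 1000.0 * frame_rate))
    if delay > 0:
        z_s = np.concatenate([np.full(delay, z_s[0]), z_s[:-delay]])
    values = g.w_center * z_c - g.w_surround * z_s
    return ResponseTrace(values, frame_rate, epoch_markers)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

class CompiledCell:
    """A model cell with precomputed spatial weights for a fixed movie
    geometry, for efficient simulation of many movies.

    ``center`` places the cell's receptive-field center in the movie's
    coordinate frame (µm from the movie center).
    """

    def __init__(self, config: GanglionModelConfig,
                 movie_template: StimulusMovie,
                 seed: int | np.random.SeedSequence = 0,
                 center: tuple[float, float] = (0.0, 0.0)):
        ss = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
        mosaic_ss, self._noise_ss = ss.spawn(2)
        self.config = config
        self.center = center
        dog = config.effective_subunit_dog
        if movie_template.pixel_pitch > dog.sigma_center / 4.0:
            raise ValueError(
                f"pixel pitch {movie_template.pixel_pitch} µm too coarse for "
                f"subunit sigma {dog.sigma_center} µm (need >= 4 px per sigma)")
        self.mosaic = build_subunit_mosaic(
            spacing=config.spacing, jitter_sd=config.jitter_sd,
            extent=config.effective_extent,
            seed=np.random.default_rng(mosaic_ss),
            dog=dog, temporal=config.subunit_temporal,
            center_radius=2.0 * config.ganglion_dog.sigma_center)
        self._weights = _spatial_weights(self.mosaic.positions, dog,
                                         movie_template, center)
        dt_ms = 1000.0 / movie_template.frame_rate
        self._kernel = temporal_kernel(config.subunit_temporal, dt_ms,
                                       config.kernel_duration_ms,
                                       normalize="step")
        self._frame_rate = movie_template.frame_rate
        if config.coupling_gain > 0:
            k = np.exp(-self.mosaic.distances / config.coupling.length_constant)
            np.fill_diagonal(k, 0.0)
            self._coupling_kernel = k
            self._coupling_ksum = k.sum(axis=1)
        else:
            self._coupling_kernel = None

    def respond(self, movie: StimulusMovie,
                rng: np.random.Generator | None = None) -> ResponseTrace:
        cfg = self.config
        frames = movie.frames.reshape(movie.n_frames, -1).T
        drive = self._weights @ frames
        if cfg.polarity == "off":
            drive = -drive
        traces = signal.fftconvolve(drive, self._kernel[None, :], mode="full",
                                    axes=1)[:, : drive.shape[1]]
        if cfg.noise_scale > 0:
            if rng is None:
                rng = np.random.default_rng(self._noise_ss)
            traces = add_poisson_noise(traces, cfg.noise_scale, rng)
        if self._coupling_kernel is not None:
            g = cfg.coupling.g
            delta = (self._coupling_ksum[:, None] * traces
                     - self._coupling_kernel @ traces)
            if cfg.coupling.sign_convention == "diffusive":
                delta = -delta
            traces = traces + g * delta
        outputs = apply_subunit_nonlinearity(traces, cfg.nonlinearity,
                                             cfg.variant)
        return pool_subunits(outputs, self.mosaic, cfg, self._frame_rate,
                             movie.epoch_markers)


def run_model(config: GanglionModelConfig, movie: StimulusMovie,
              seed: int = 0,
              center: tuple[float, float] = (0.0, 0.0)) -> ResponseTrace:
    """Run the full four-stage pipeline on one movie.

    ``seed`` controls both the mosaic jitter and the Poisson noise (via
    independent spawned streams).
    """
    cell = CompiledCell(config, movie, seed=seed, center=center)
    return cell.respond(movie)


# ---------------------------------------------------------------------------
# Selectivity experiments
# ---------------------------------------------------------------------------

def approach_recede_indices(config: GanglionModelConfig,
                            movie_approach: StimulusMovie,
                            movie_recede: StimulusMovie,
                            n_seeds: int = 20, seed: int = 0,
                            window: str = "motion") -> np.ndarray:
    """Approach-selectivity indices over independent model realizations.

    Each realization draws a fresh mosaic jitter and fresh Poisson noise
    for both directions, computes baseline-subtracted epoch responses and
    the selectivity index.  Returns the per-realization indices.
    """
    root = np.random.SeedSequence(seed)
    out = np.empty(n_seeds)
    for i, child in enumerate(root.spawn(n_seeds)):
        cell_ss, noise_a, noise_r = child.spawn(3)
        cell = CompiledCell(config, movie_approach, seed=cell_ss)
        ra = epoch_response(cell.respond(movie_approach,
                                         np.random.default_rng(noise_a)),
                            window=window)
        rr = epoch_response(cell.respond(movie_recede,
                                         np.random.default_rng(noise_r)),
                            window=window)
        out[i] = approach_selectivity_index(ra, rr).index
    return out


def sweep_coupling_gain(config: GanglionModelConfig,
                        movie_approach: StimulusMovie,
                        movie_recede: StimulusMovie,
                        gains, n_seeds: int = 10, seed: int = 0):
    """Approach-selectivity index vs coupling gain (mean ± SEM over seeds).

    Gain 0 reduces to the nonlinear variant.  Returns a pandas DataFrame
    with columns gain, asi_mean, asi_sem.
    """
    import pandas as pd

    rows = []
    for gain in gains:
        if gain < 0:
            raise ValueError("coupling gains must be >= 0")
        cfg = replace(config, variant="coupled",
                      coupling=replace(config.coupling, g=float(gain)))
        idx = approach_recede_indices(cfg, movie_approach, movie_recede,
                                      n_seeds=n_seeds, seed=seed)
        rows.append({"gain": float(gain),
                     "asi_mean": float(idx.mean()),
                     "asi_sem": float(idx.std(ddof=1) / np.sqrt(len(idx)))
                     if len(idx) > 1 else 0.0})
    return pd.DataFrame(rows)
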
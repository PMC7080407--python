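"""Visual stimulus synthesis on a physical retinal coordinate frame.

All stimuli are represented as :class:`StimulusMovie` objects: 3-D Weber
contrast fields ``(time, y, x)`` with a physical pixel pitch (µm/px) and a
frame rate (Hz).  Four stimulus families are provided:

* stochastic textures whose spatial scale changes exponentially in time,
  emulating approaching (expanding) or receding (contracting) optical flow;
* expanding/contracting annuli confined to a receptive-field center;
* Gaussian contrast-flicker spots and annuli for reverse correlation;
* sinusoidally modulated spots for area-summation measurements.

Textures are built by bandpass filtering a single seeded white-noise matrix
in the Fourier domain with a raised-cosine (in log2 spatial frequency)
filter whose center frequency decays exponentially in time, so every frame
is a rescaled version of the same underlying texture.  A receding movie is
exactly the approaching movie with its motion-epoch frames reversed, which
makes the two ensembles identical image sets -- the key stimulus control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "StimulusMovie",
    "TextureSpec",
    "AnnulusSpec",
    "bandpass_filter_weights",
    "generate_texture_sequence",
    "generate_annulus_sequence",
    "generate_gaussian_flicker",
    "gaussian_contrast_trajectory",
    "generate_sinusoidal_spot",
    "DEGREES_TO_UM",
    "DEFAULT_FRAME_RATE",
    "DEFAULT_EXPANSION_RATES",
]

# Retinal magnification: µm of retina per degree of visual angle (macaque,
# mid-periphery).  Configurable per spec because texture parameters are
# given in cycles/degree while circuit geometry is in µm.
DEGREES_TO_UM = 200.0

DEFAULT_FRAME_RATE = 60.0  # Hz

# Texture expansion rates (Hz in the exponential scale law), spanning the
# slow-to-fast range used for the texture experiments (0.5-8 deg/s).
DEFAULT_EXPANSION_RATES = (0.5, 1.0, 2.0, 4.0, 8.0)

# Default epoch structure: 0.25 s gray, 1 s motion, 0.25 s gray.
DEFAULT_PRE_S = 0.25
DEFAULT_MOTION_S = 1.0
DEFAULT_POST_S = 0.25


class InvalidStimulusParameter(ValueError):
    """Raised when a stimulus specification is geometrically or numerically invalid."""


@dataclass
class StimulusMovie:
    """A contrast movie on a physical retinal coordinate frame.

    Attributes
    ----------
    frames:
        ``(n_frames, height, width)`` array of Weber contrast.
    pixel_pitch:
        µm per pixel.
    frame_rate:
        Hz.
    epoch_markers:
        ``(pre_end, motion_end)`` frame indices; ``frames[pre_end:motion_end]``
        is the motion epoch, frames before/after are gray (zero contrast).
    metadata:
        Free-form provenance (spec parameters, seed, clipping warnings).
    """

    frames: np.ndarray
    pixel_pitch: float
    frame_rate: float
    epoch_markers: tuple[int, int]
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def motion_slice(self) -> slice:
        return slice(self.epoch_markers[0], self.epoch_markers[1])

    @property
    def pre_slice(self) -> slice:
        return slice(0, self.epoch_markers[0])

    @property
    def post_slice(self) -> slice:
        return slice(self.epoch_markers[1], self.n_frames)

    @property
    def times(self) -> np.ndarray:
        """Frame onset times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate

    def time_reversed(self) -> "StimulusMovie":
        """Return a copy with the motion-epoch frames in reverse order.

        Gray pre/post epochs are untouched, so the result is the matched
        opposite-direction stimulus containing the identical image set.
        """
        frames = self.frames.copy()
        frames[self.motion_slice] = frames[self.motion_slice][::-1]
        meta = dict(self.metadata)
        meta["time_reversed"] = not meta.get("time_reversed", False)
        return StimulusMovie(frames, self.pixel_pitch, self.frame_rate,
                             self.epoch_markers, meta)

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates (x, y) in µm, origin at the field center."""
        n_t, ny, nx = self.frames.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_pitch
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_pitch
        return x, y

    # -- HDF5 round trip ---------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames, compression="gzip")
            f.create_dataset("pixel_pitch", data=self.pixel_pitch)
            f.create_dataset("frame_rate", data=self.frame_rate)
            f.create_dataset("epoch_markers", data=np.asarray(self.epoch_markers))
            f.attrs["spec"] = json.dumps(self.metadata, default=str)

    @classmethod
    def from_hdf5(cls, path) -> "StimulusMovie":
        import h5py

        with h5py.File(path, "r") as f:
            frames = f["frames"][...]
            pitch = float(f["pixel_pitch"][()])
            rate = float(f["frame_rate"][()])
            markers = tuple(int(v) for v in f["epoch_markers"][...])
            meta = json.loads(f.attrs.get("spec", "{}"))
        return cls(frames, pitch, rate, markers, meta)


@dataclass(frozen=True)
class TextureSpec:
    """Parameters of an exponentially rescaling stochastic texture.

    ``f0`` is the peak spatial frequency of the bandpass filter at motion
    onset (cycles/degree) and ``rate`` the exponential scale-change rate
    (Hz): f(t) = exp(ln f0 - rate * t).  Approaching movies run from the
    highest to the lowest spatial frequency; a receding movie is the exact
    frame-reversal of its approaching counterpart.
    """

    f0: float
    rate: float
    rms_contrast: float = 0.3
    direction: Literal["approaching", "receding"] = "approaching"
    seed: int = 0
    degrees_to_um: float = DEGREES_TO_UM
    # radians of cosine phase per octave; 1.0 reads the log-frequency
    # ratio directly as radians (±pi-octave band)
    octave_scale: float = 1.0

    def __post_init__(self):
        if self.f0 <= 0:
            raise InvalidStimulusParameter(f"f0 must be > 0, got {self.f0}")
        if self.rate <= 0:
            raise InvalidStimulusParameter(f"rate must be > 0, got {self.rate}")
        if self.direction not in ("approaching", "receding"):
            raise InvalidStimulusParameter(f"unknown direction {self.direction!r}")

    @classmethod
    def from_geometric_mean(cls, geometric_mean_f: float, rate: float,
                            motion_duration: float, **kwargs) -> "TextureSpec":
        """Choose f0 so the geometric-mean frequency over the epoch is as given.

        With f(t) = f0 * exp(-rate*t) the geometric mean over [0, T] is
        f0 * exp(-rate*T/2), so f0 = gmean * exp(rate*T/2).
        """
        f0 = geometric_mean_f * np.exp(rate * motion_duration / 2.0)
        return cls(f0=f0, rate=rate, **kwargs)

    def frequency_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Instantaneous peak filter frequency (cycles/degree) at time ``t`` s."""
        return np.exp(np.log(self.f0) - self.rate * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class AnnulusSpec:
    """A ring whose inner radius moves linearly in time.

    Approaching = expanding (radius strictly increases over the motion
    epoch); receding = contracting; the receding trajectory is the exact
    time-reverse of the approaching one.
    """

    contrast: float = 0.25
    r_inner_start: float = 20.0  # µm
    r_inner_end: float = 90.0    # µm
    ring_width: float = 25.0     # µm
    speed: float = 320.0         # µm/s; 0 = static annulus
    direction: Literal["approaching", "receding"] = "approaching"

    def __post_init__(self):
        if self.r_inner_start <= 0:
            raise InvalidStimulusParameter("r_inner_start must be > 0")
        if self.ring_width <= 0:
            raise InvalidStimulusParameter("ring_width must be > 0")
        if self.speed < 0:
            raise InvalidStimulusParameter("speed must be >= 0")
        if self.direction not in ("approaching", "receding"):
            raise InvalidStimulusParameter(f"unknown direction {self.direction!r}")


# ---------------------------------------------------------------------------
# Bandpass filter (raised cosine in log2 spatial frequency)
# ---------------------------------------------------------------------------

def bandpass_filter_weights(freq_magnitudes: np.ndarray, f_center: float,
                            octave_scale: float = 1.0) -> np.ndarray:
    """Raised-cosine bandpass gain on a grid of spatial-frequency magnitudes.

    gain = 0.5 + 0.5*cos(W) with W = octave_scale * log2(omega /
    (2*f_center)), W clamped to [-pi, pi]; the gain is exactly 0 wherever
    |W| >= pi.  With the default ``octave_scale = 1`` the log-frequency
    ratio is read directly as radians, giving a passband spanning a factor
    2**pi on either side of the peak at omega = 2*f_center;
    ``octave_scale = pi`` narrows the band to one octave per side.

    Parameters
    ----------
    freq_magnitudes:
        Spatial-frequency magnitudes (cycles/degree), e.g. an fftshift-centered
        grid with DC at the center.  DC (omega = 0) receives gain 0.
    f_center:
        Filter parameter f(t) (cycles/degree); the gain peaks at 2*f_center.
    octave_scale:
        Radians of cosine phase per octave of spatial frequency.
    """
    if f_center <= 0:
        raise InvalidStimulusParameter(f"f_center must be > 0, got {f_center}")
    if octave_scale <= 0:
        raise InvalidStimulusParameter("octave_scale must be > 0")
    omega = np.asarray(freq_magnitudes, dtype=float)
    gain = np.zeros_like(omega)
    pos = omega > 0
    with np.errstate(divide="ignore"):
        w = octave_scale * np.log2(omega[pos] / (2.0 * f_center))
    inside = np.abs(w) < np.pi
    g = np.zeros_like(w)
    g[inside] = 0.5 + 0.5 * np.cos(w[inside])
    gain[pos] = g
    return gain


def _frequency_grid(ny: int, nx: int, pixel_pitch: float,
                    degrees_to_um: float) -> np.ndarray:
    """fftshift-centered grid of spatial-frequency magnitudes in cycles/degree."""
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=pixel_pitch))  # cycles/µm
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=pixel_pitch))
    mag_um = np.hypot(fy[:, None], fx[None, :])
    return mag_um * degrees_to_um  # cycles/degree


def _assemble_movie(motion_frames: np.ndarray, pixel_pitch: float,
                    frame_rate: float, pre_s: float, post_s: float,
                    metadata: dict) -> StimulusMovie:
    n_pre = int(round(pre_s * frame_rate))
    n_post = int(round(post_s * frame_rate))
    n_motion = motion_frames.shape[0]
    ny, nx = motion_frames.shape[1:]
    frames = np.zeros((n_pre + n_motion + n_post, ny, nx), dtype=motion_frames.dtype)
    frames[n_pre:n_pre + n_motion] = motion_frames
    return StimulusMovie(frames, pixel_pitch, frame_rate,
                         (n_pre, n_pre + n_motion), metadata)


def generate_texture_sequence(spec: TextureSpec, width_px: int, height_px: int,
                              n_frames: int | None = None,
                              frame_rate: float = DEFAULT_FRAME_RATE,
                              pixel_pitch: float = 4.0,
                              pre_s: float = DEFAULT_PRE_S,
                              post_s: float = DEFAULT_POST_S) -> StimulusMovie:
    """Synthesize a rescaling stochastic texture movie.

    A single seeded Gaussian white-noise matrix is bandpass filtered in the
    Fourier domain; the filter's center frequency follows the exponential
    law of ``spec`` frame by frame, so each motion frame is a rescaled
    version of the same texture.  Frames are normalized to the requested
    RMS contrast over the whole motion epoch (not per frame), preserving
    exact time-reversal equality between directions.

    ``n_frames`` is the number of motion frames (default 1 s worth); gray
    pre/post epochs are appended around the motion epoch.
    """
    if n_frames is None:
        n_frames = int(round(DEFAULT_MOTION_S * frame_rate))
    if n_frames < 2:
        raise InvalidStimulusParameter("n_frames must be >= 2")

    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((height_px, width_px))
    noise_f = np.fft.fftshift(np.fft.fft2(noise))
    freq = _frequency_grid(height_px, width_px, pixel_pitch, spec.degrees_to_um)

    t = np.arange(n_frames) / frame_rate
    f_of_t = spec.frequency_at(t)

    motion = np.empty((n_frames, height_px, width_px))
    for k in range(n_frames):
        gain = bandpass_filter_weights(freq, float(f_of_t[k]),
                                       octave_scale=spec.octave_scale)
        motion[k] = np.real(np.fft.ifft2(np.fft.ifftshift(gain * noise_f)))

    # zero spatial mean per frame (DC gain is 0; this removes residual
    # numerical mean), then normalize each frame to the requested RMS
    # contrast: a rescaled (zoomed) texture keeps its contrast, whereas the
    # raw bandpass output loses energy as the band area shrinks.  Per-frame
    # normalization is applied identically to every frame, so a receding
    # movie remains the exact frame-reversal of its approaching partner.
    motion -= motion.mean(axis=(1, 2), keepdims=True)
    rms = np.sqrt(np.mean(motion ** 2, axis=(1, 2), keepdims=True))
    if np.all(rms == 0):
        raise InvalidStimulusParameter(
            "texture band is empty at this resolution; increase field size "
            "or adjust f0")
    np.divide(motion, rms, out=motion, where=rms > 0)
    motion *= spec.rms_contrast

    metadata = {
        "kind": "texture",
        "f0": spec.f0,
        "rate": spec.rate,
        "rms_contrast": spec.rms_contrast,
        "direction": spec.direction,
        "seed": spec.seed,
        "degrees_to_um": spec.degrees_to_um,
        "frequency_start": float(f_of_t[0]),
        "frequency_end": float(f_of_t[-1]),
    }
    clip_frac = float(np.mean(np.abs(motion) > 1.0))
    if clip_frac > 0.01:
        metadata["clipping_warning"] = clip_frac
        warnings.warn(
            f"{clip_frac:.1%} of texture pixels exceed |contrast| = 1",
            RuntimeWarning, stacklevel=2)

    if spec.direction == "receding":
        motion = motion[::-1]

    return _assemble_movie(motion, pixel_pitch, frame_rate, pre_s, post_s,
                           metadata)


# ---------------------------------------------------------------------------
# Annuli
# ---------------------------------------------------------------------------

def generate_annulus_sequence(spec: AnnulusSpec, width_px: int, height_px: int,
                              frame_rate: float = DEFAULT_FRAME_RATE,
                              pixel_pitch: float = 4.0,
                              pre_s: float = DEFAULT_PRE_S,
                              post_s: float = DEFAULT_POST_S) -> StimulusMovie:
    """Expanding (approaching) or contracting (receding) annulus movie.

    The ring's inner radius moves linearly at ``spec.speed`` from
    ``r_inner_start`` to ``r_inner_end``; pixels inside the ring carry the
    specified Weber contrast, the background is 0.  ``speed = 0`` yields a
    static annulus for one default motion epoch.
    """
    half_x = width_px * pixel_pitch / 2.0
    half_y = height_px * pixel_pitch / 2.0
    r_outer_max = max(spec.r_inner_start, spec.r_inner_end) + spec.ring_width
    if r_outer_max > min(half_x, half_y):
        raise InvalidStimulusParameter(
            f"annulus outer radius {r_outer_max:.1f} µm exceeds the field "
            f"half-extent {min(half_x, half_y):.1f} µm")

    if spec.speed == 0:
        n_motion = int(round(DEFAULT_MOTION_S * frame_rate))
        radii = np.full(n_motion, spec.r_inner_start)
    else:
        travel = abs(spec.r_inner_end - spec.r_inner_start)
        n_motion = max(2, int(round(travel / spec.speed * frame_rate)))
        radii = np.linspace(min(spec.r_inner_start, spec.r_inner_end),
                            max(spec.r_inner_start, spec.r_inner_end),
                            n_motion)
    # expanding trajectory; receding = exact reversal
    if spec.direction == "receding":
        radii = radii[::-1]

    x = (np.arange(width_px) - (width_px - 1) / 2.0) * pixel_pitch
    y = (np.arange(height_px) - (height_px - 1) / 2.0) * pixel_pitch
    dist = np.hypot(y[:, None], x[None, :])

    motion = np.zeros((n_motion, height_px, width_px))
    for k, r in enumerate(radii):
        mask = (dist >= r) & (dist < r + spec.ring_width)
        motion[k][mask] = spec.contrast

    metadata = {
        "kind": "annulus",
        "contrast": spec.contrast,
        "r_inner_start": spec.r_inner_start,
        "r_inner_end": spec.r_inner_end,
        "ring_width": spec.ring_width,
        "speed": spec.speed,
        "direction": spec.direction,
        "radii_start": float(radii[0]),
        "radii_end": float(radii[-1]),
    }
    return _assemble_movie(motion, pixel_pitch, frame_rate, pre_s, post_s,
                           metadata)


# ---------------------------------------------------------------------------
# Gaussian contrast flicker
# ---------------------------------------------------------------------------

def gaussian_contrast_trajectory(n_frames: int, seed: int,
                                 mean: float = 0.0,
                                 sd: float = 0.1) -> np.ndarray:
    """i.i.d. Gaussian frame-wise contrasts (default N(0, 0.1^2))."""
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sd, size=n_frames)


def _region_mask(region: str, geometry: dict, width_px: int, height_px: int,
                 pixel_pitch: float) -> np.ndarray:
    x = (np.arange(width_px) - (width_px - 1) / 2.0) * pixel_pitch
    y = (np.arange(height_px) - (height_px - 1) / 2.0) * pixel_pitch
    dist = np.hypot(y[:, None], x[None, :])
    if region == "spot":
        radius = float(geometry["radius"])
        if radius <= 0:
            raise InvalidStimulusParameter("spot radius must be > 0")
        return dist <= radius
    if region == "annulus":
        r_in = float(geometry["r_inner"])
        r_out = float(geometry["r_outer"])
        if not 0 < r_in < r_out:
            raise InvalidStimulusParameter("need 0 < r_inner < r_outer")
        return (dist >= r_in) & (dist < r_out)
    raise InvalidStimulusParameter(f"unknown region {region!r}")


def default_annulus_pair(contrast: float = 0.25,
                         width_px: int = 96, height_px: int = 96,
                         frame_rate: float = 240.0,
                         pixel_pitch: float = 4.0,
                         **spec_kwargs) -> tuple[StimulusMovie, StimulusMovie]:
    """The standard matched annulus pair (approaching, receding).

    Defaults: a ring of the given Weber contrast, 25 µm wide, sweeping its
    inner radius 20 -> 90 µm at 320 µm/s (so the ring stays within the
    model ganglion cell's receptive-field center), rendered at 240 Hz on a
    384 µm field.  The receding movie is the exact time-reverse of the
    approaching one.
    """
    approach = generate_annulus_sequence(
        AnnulusSpec(direction="approaching", contrast=contrast, **spec_kwargs),
        width_px, height_px, frame_rate=frame_rate, pixel_pitch=pixel_pitch)
    recede = generate_annulus_sequence(
        AnnulusSpec(direction="receding", contrast=contrast, **spec_kwargs),
        width_px, height_px, frame_rate=frame_rate, pixel_pitch=pixel_pitch)
    return approach, recede


def generate_gaussian_flicker(region: Literal["spot", "annulus"],
                              geometry: dict, n_frames: int, seed: int,
                              width_px: int = 64, height_px: int = 64,
                              frame_rate: float = DEFAULT_FRAME_RATE,
                              pixel_pitch: float = 4.0,
                              mean: float = 0.0,
                              sd: float = 0.1) -> tuple[StimulusMovie, np.ndarray]:
    """Uniform-contrast flicker over a spot or annulus region.

    One scalar contrast per frame, drawn i.i.d. from N(mean, sd^2)
    (defaults 0.0 and 0.1), is applied uniformly over the region.  Returns
    the movie and the contrast trajectory for reverse correlation.
    """
    mask = _region_mask(region, geometry, width_px, height_px, pixel_pitch)
    trajectory = gaussian_contrast_trajectory(n_frames, seed, mean, sd)
    frames = (trajectory[:, None, None] * mask[None, :, :]).astype(np.float32)
    movie = StimulusMovie(frames, pixel_pitch, frame_rate, (0, n_frames),
                          {"kind": "flicker", "region": region,
                           "geometry": geometry, "seed": seed,
                           "mean": mean, "sd": sd})
    return movie, trajectory


# ---------------------------------------------------------------------------
# Sinusoidally modulated spots
# ---------------------------------------------------------------------------

def generate_sinusoidal_spot(radius: float, contrast: float,
                             temporal_frequency: float, n_cycles: int,
                             frame_rate: float = DEFAULT_FRAME_RATE,
                             width_px: int = 64, height_px: int = 64,
                             pixel_pitch: float = 4.0) -> StimulusMovie:
    """Uniform disc whose contrast follows contrast * sin(2*pi*f*t).

    Used to measure area summation: the F1 (fundamental) response amplitude
    as a function of spot radius traces out the difference-of-Gaussians
    receptive-field profile.
    """
    mask = _region_mask("spot", {"radius": radius}, width_px, height_px,
                        pixel_pitch)
    n_frames = int(round(n_cycles * frame_rate / temporal_frequency))
    t = np.arange(n_frames) / frame_rate
    trajectory = contrast * np.sin(2 * np.pi * temporal_frequency * t)
    frames = (trajectory[:, None, None] * mask[None, :, :]).astype(np.float32)
    return StimulusMovie(frames, pixel_pitch, frame_rate, (0, n_frames),
                         {"kind": "sinusoidal_spot", "radius": radius,
                          "contrast": contrast,
                          "temporal_frequency": temporal_frequency,
                          "trajectory": trajectory.tolist()})
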
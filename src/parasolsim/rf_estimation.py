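"""Receptive-field model estimation from stimulus/response pairs.

Implements the standard linear-nonlinear (LN) characterization used for
primate ganglion cells:

* spatial profile: difference-of-Gaussians (DoG) fit to area-summation
  curves (F1 response amplitude vs. spot radius),
* temporal filter: reverse correlation of a Gaussian contrast-flicker
  trajectory with the response, normalized so that a purely linear system
  returns its generating kernel,
* temporal-filter parameterization: damped oscillator with an S-shaped
  (sigmoidal) onset,
* static output nonlinearity: rectifying cumulative Gaussian fitted to
  binned (prediction, response) means,
* center-surround kinetics: the surround lag measured as the difference in
  time-to-peak of center and surround temporal filters,
* cross-validation on held-out repeated stimulus sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, signal
from scipy.special import ndtr
from scipy.stats import pearsonr

__all__ = [
    "DoGParams",
    "params_to_json",
    "params_from_json",
    "TemporalFilterParams",
    "NonlinearityParams",
    "AreaSummationFit",
    "NonlinearityFit",
    "LNModelFit",
    "area_summation_response",
    "fit_area_summation",
    "compute_temporal_filter",
    "temporal_kernel",
    "fit_damped_oscillator",
    "compute_linear_prediction",
    "fit_output_nonlinearity",
    "center_surround_delay",
    "validate_on_repeats",
    "estimate_ln_model",
    "FlatFilterError",
]


class FlatFilterError(ValueError):
    """Raised when a temporal filter is flat (no structure to fit)."""


_PARAM_TYPES = {}


def params_to_json(params) -> str:
    """Serialize a fitted parameter set (DoG, temporal filter or
    nonlinearity) to a JSON string with a type tag."""
    import dataclasses
    import json

    return json.dumps({"type": type(params).__name__,
                       **dataclasses.asdict(params)})


def params_from_json(text: str):
    """Inverse of :func:`params_to_json`."""
    import json

    payload = json.loads(text)
    cls = _PARAM_TYPES[payload.pop("type")]
    return cls(**payload)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians spatial receptive field.

    ``w_center``/``w_surround`` are the total integrated weights of the two
    Gaussians (the asymptotes of the area-summation curve); ``sigma_center``
    and ``sigma_surround`` are their standard deviations in µm.
    """

    w_center: float
    w_surround: float
    sigma_center: float
    sigma_surround: float

    def __post_init__(self):
        if self.sigma_center <= 0 or self.sigma_surround <= self.sigma_center:
            raise ValueError(
                "need sigma_surround > sigma_center > 0, got "
                f"{self.sigma_surround} vs {self.sigma_center}")
        if self.w_center < 0 or self.w_surround < 0:
            raise ValueError("DoG weights must be >= 0")

    def scaled(self, factor: float) -> "DoGParams":
        """Return a copy with both sigmas multiplied by ``factor``."""
        return DoGParams(self.w_center, self.w_surround,
                         self.sigma_center * factor,
                         self.sigma_surround * factor)


_PARAM_TYPES["DoGParams"] = DoGParams


@dataclass(frozen=True)
class TemporalFilterParams:
    """Damped oscillator with sigmoidal onset.

    F(t) = A * (t/tau_rise)^n / (1 + (t/tau_rise)^n)
             * exp(-t/tau_decay) * cos(2*pi*t/tau_period + phi)

    Times are in ms; ``phi`` is in degrees.
    """

    A: float
    tau_rise: float
    tau_decay: float
    tau_period: float
    n: float = 2.0
    phi: float = 0.0

    def __post_init__(self):
        if min(self.tau_rise, self.tau_decay, self.tau_period) <= 0:
            raise ValueError("all time constants must be > 0")
        if self.n < 1:
            raise ValueError("rise exponent n must be >= 1")

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        x = np.zeros_like(t)
        pos = t > 0
        tp = t[pos]
        s = (tp / self.tau_rise) ** self.n
        x[pos] = (self.A * s / (1.0 + s) * np.exp(-tp / self.tau_decay)
                  * np.cos(2 * np.pi * tp / self.tau_period
                           + np.deg2rad(self.phi)))
        return x


_PARAM_TYPES["TemporalFilterParams"] = TemporalFilterParams


@dataclass(frozen=True)
class NonlinearityParams:
    """Rectifying cumulative-Gaussian input-output function.

    N(x) = epsilon + alpha * Phi(beta*x + gamma), with Phi the standard
    normal CDF.  ``alpha`` is the maximal output, ``epsilon`` the vertical
    offset, ``beta`` the input sensitivity and ``gamma`` the maintained
    (resting) input.
    """

    alpha: float
    epsilon: float
    beta: float
    gamma: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return self.epsilon + self.alpha * ndtr(self.beta * np.asarray(x)
                                                + self.gamma)


_PARAM_TYPES["NonlinearityParams"] = NonlinearityParams


# ---------------------------------------------------------------------------
# Area summation (DoG)
# ---------------------------------------------------------------------------

def area_summation_response(radii, w_center, w_surround, sigma_center,
                            sigma_surround) -> np.ndarray:
    """DoG area-summation curve: response to a spot of the given radius.

    R(r) = w_c*(1 - exp(-r^2/(2 sigma_c^2))) - w_s*(1 - exp(-r^2/(2 sigma_s^2)))
    """
    r2 = np.asarray(radii, dtype=float) ** 2
    return (w_center * (1.0 - np.exp(-r2 / (2.0 * sigma_center ** 2)))
            - w_surround * (1.0 - np.exp(-r2 / (2.0 * sigma_surround ** 2))))


@dataclass
class AreaSummationFit:
    params: DoGParams
    fitted: np.ndarray
    r_squared: float
    surround_at_boundary: bool

    @property
    def peak_radius(self) -> float:
        """Radius (µm) at which the fitted DoG curve is maximal."""
        p = self.params
        r = np.linspace(0, 4 * p.sigma_surround, 4000)
        curve = area_summation_response(r, p.w_center, p.w_surround,
                                        p.sigma_center, p.sigma_surround)
        return float(r[np.argmax(curve)])


def fit_area_summation(radii: Sequence[float],
                       f1_amplitudes: Sequence[float]) -> AreaSummationFit:
    """Least-squares DoG fit to an area-summation curve.

    Parameterized internally with sigma_surround = sigma_center + delta
    (delta > 0) so the surround is always the broader Gaussian.  Data that
    saturate monotonically (no surround suppression) fit with w_surround
    pinned near 0; this is reported via ``surround_at_boundary``.
    """
    radii = np.asarray(radii, dtype=float)
    y = np.asarray(f1_amplitudes, dtype=float)
    if radii.size < 6:
        raise ValueError("need at least 6 radii for a DoG fit")
    if np.any(y < 0):
        raise ValueError("F1 amplitudes must be >= 0")

    scale = max(y.max(), 1e-12)
    r_peak = radii[np.argmax(y)]

    def model(theta):
        wc, ws, sc, dsig = theta
        return area_summation_response(radii, wc, ws, sc, sc + dsig)

    def residuals(theta):
        return model(theta) - y

    best = None
    for sc0 in (0.4 * r_peak + 1.0, 0.8 * r_peak + 1.0, 1.5 * r_peak + 1.0):
        x0 = np.array([1.3 * scale, 0.5 * scale, sc0, 2.0 * sc0])
        sol = optimize.least_squares(
            residuals, x0,
            bounds=([0, 0, 1e-3, 1e-3],
                    [np.inf, np.inf, np.inf, np.inf]))
        if best is None or sol.cost < best.cost:
            best = sol
    wc, ws, sc, dsig = best.x
    params = DoGParams(wc, ws, sc, sc + dsig)
    fitted = model(best.x)
    ss_res = float(np.sum((fitted - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    # no effective surround: its contribution at the largest tested radius
    # is negligible (either w_surround ~ 0 or sigma_surround beyond range)
    surr_at_max = ws * (1.0 - np.exp(-radii.max() ** 2
                                     / (2.0 * (sc + dsig) ** 2)))
    boundary = surr_at_max < 0.01 * max(fitted.max(), 1e-12)
    return AreaSummationFit(params, fitted, r2, boundary)


# ---------------------------------------------------------------------------
# Temporal filter by reverse correlation
# ---------------------------------------------------------------------------

def compute_temporal_filter(contrast_trajectory: np.ndarray,
                            response_trace: np.ndarray,
                            max_lag: int) -> np.ndarray:
    """Reverse-correlation estimate of the temporal filter.

    F[k] = sum_t R[t] * S[t-k] / ((N-k) * var(S)) for lags k = 0..max_lag.
    The normalization makes an exactly linear response return its
    generating kernel (for white, zero-mean S).

    ``max_lag`` is in samples; both traces must share the sampling rate.
    """
    s = np.asarray(contrast_trajectory, dtype=float)
    r = np.asarray(response_trace, dtype=float)
    if s.shape != r.shape:
        raise ValueError("stimulus and response must have equal length")
    n = s.size
    if max_lag >= n:
        raise ValueError("max_lag must be shorter than the traces")
    var = float(np.dot(s, s) / n)
    if var == 0:
        raise ValueError("zero-variance stimulus: filter undefined")
    # c[n-1+k] = sum_t r[t] * s[t-k]
    c = signal.correlate(r, s, mode="full", method="auto")
    lags = np.arange(max_lag + 1)
    return c[n - 1: n + max_lag] / ((n - lags) * var)


def temporal_kernel(params: TemporalFilterParams, dt_ms: float,
                    duration_ms: float,
                    normalize: str | None = None) -> np.ndarray:
    """Sample the damped-oscillator kernel on a causal time grid.

    Samples are taken at bin centers ``(k + 0.5) * dt`` so the first tap is
    nonzero.  ``normalize``:

    * ``None`` -- raw samples of the parameterized curve;
    * ``"peak"`` -- scaled to a peak absolute value of 1;
    * ``"step"`` -- scaled so the peak of the *step response* (running sum)
      is 1.  Discrete convolution with a step-normalized kernel
      approximates the continuous filtering integral independently of the
      sampling rate: a sustained unit input drives the output to 1 at the
      transient peak.
    """
    t = (np.arange(int(round(duration_ms / dt_ms))) + 0.5) * dt_ms
    k = params.evaluate(t)
    if normalize == "peak":
        peak = np.max(np.abs(k))
        if peak > 0:
            k = k / peak
    elif normalize == "step":
        peak = np.max(np.abs(np.cumsum(k)))
        if peak > 0:
            k = k / peak
    elif normalize is not None:
        raise ValueError(f"unknown normalization {normalize!r}")
    return k


def fit_damped_oscillator(filter_samples: np.ndarray,
                          dt_ms: float = 1.0) -> tuple[TemporalFilterParams, float]:
    """Nonlinear least-squares fit of the damped-oscillator model.

    Multi-starts over phase (0, 90, 180, 270 degrees) and log-spaced time
    constants to escape phase local minima.  Returns the fitted parameters
    and the time-to-peak (ms) of the fitted curve.
    """
    y = np.asarray(filter_samples, dtype=float)
    if y.size < 50:
        raise ValueError("need >= 50 filter samples covering the decay")
    peak = np.max(np.abs(y))
    if peak < 1e-12 * max(1.0, np.ptp(y)) or peak == 0:
        raise FlatFilterError("filter is flat; nothing to fit")

    t = (np.arange(y.size) + 0.5) * dt_ms
    t_peak_data = t[np.argmax(np.abs(y))]

    def model(theta, tt):
        a, tr, td, tp, nn, phi = theta
        s = (tt / tr) ** nn
        return (a * s / (1 + s) * np.exp(-tt / td)
                * np.cos(2 * np.pi * tt / tp + np.deg2rad(phi)))

    def residuals(theta):
        return model(theta, t) - y

    span = t[-1]
    best = None
    for phi0 in (0.0, 90.0, 180.0, 270.0):
        for tr0 in np.geomspace(max(t_peak_data / 4, dt_ms), t_peak_data + dt_ms, 3):
            for td0 in (t_peak_data + dt_ms, span / 2):
                x0 = np.array([peak * 2, tr0, td0, 4 * t_peak_data + dt_ms,
                               2.0, phi0])
                try:
                    sol = optimize.least_squares(
                        residuals, x0,
                        bounds=([-np.inf, dt_ms / 10, dt_ms / 10, dt_ms,
                                 1.0, -360.0],
                                [np.inf, span, 10 * span, 20 * span,
                                 12.0, 720.0]),
                        ftol=1e-9, xtol=1e-12)
                except ValueError:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
    if best is None:
        raise RuntimeError("damped-oscillator fit failed from every start")
    a, tr, td, tp, nn, phi = best.x
    params = TemporalFilterParams(A=a, tau_rise=tr, tau_decay=td,
                                  tau_period=tp, n=nn, phi=phi)
    t_fine = np.linspace(dt_ms / 10, t[-1], 10 * y.size)
    fitted = params.evaluate(t_fine)
    time_to_peak = float(t_fine[np.argmax(np.abs(fitted))])
    return params, time_to_peak


# ---------------------------------------------------------------------------
# Linear prediction and output nonlinearity
# ---------------------------------------------------------------------------

def compute_linear_prediction(filt: np.ndarray,
                              contrast_trajectory: np.ndarray
                              ) -> tuple[np.ndarray, int]:
    """Causal convolution P(t) = sum_tau F(tau) S(t - tau).

    Returns the prediction (same length as the trajectory) and the number
    of initial burn-in samples (len(filt) - 1) that are only partially
    driven and should be discarded before fitting.
    """
    filt = np.asarray(filt, dtype=float)
    s = np.asarray(contrast_trajectory, dtype=float)
    if filt.size >= s.size:
        raise ValueError("filter must be shorter than the trajectory")
    p = signal.fftconvolve(s, filt, mode="full")[: s.size]
    return p, filt.size - 1


@dataclass
class NonlinearityFit:
    params: NonlinearityParams
    bin_centers: np.ndarray
    bin_means: np.ndarray
    fitted: np.ndarray
    r_squared: float


def fit_output_nonlinearity(prediction: np.ndarray, response: np.ndarray,
                            n_bins: int = 40,
                            burn_in: int = 0) -> NonlinearityFit:
    """Fit the cumulative-Gaussian output nonlinearity.

    The prediction is divided into quantile bins; the mean response per bin
    is fitted with N(x) = epsilon + alpha*Phi(beta*x + gamma) by
    least squares.
    """
    p = np.asarray(prediction, dtype=float)[burn_in:]
    r = np.asarray(response, dtype=float)[burn_in:]
    if p.shape != r.shape:
        raise ValueError("prediction and response must have equal length")
    if np.ptp(p) == 0:
        raise ValueError("constant prediction: nonlinearity undefined")

    edges = np.quantile(p, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1,
                  0, edges.size - 2)
    n_eff = edges.size - 1
    counts = np.bincount(idx, minlength=n_eff)
    x_bin = np.bincount(idx, weights=p, minlength=n_eff) / np.maximum(counts, 1)
    y_bin = np.bincount(idx, weights=r, minlength=n_eff) / np.maximum(counts, 1)
    keep = counts > 0
    x_bin, y_bin = x_bin[keep], y_bin[keep]

    y_rng = max(np.ptp(y_bin), 1e-12)
    x_sd = max(np.std(x_bin), 1e-12)

    def model(theta):
        alpha, eps, beta, gamma = theta
        return eps + alpha * ndtr(beta * x_bin + gamma)

    def residuals(theta):
        return model(theta) - y_bin

    best = None
    for beta0 in (0.5 / x_sd, 2.0 / x_sd, 8.0 / x_sd):
        for gamma0 in (-1.0, 0.0, 1.0):
            x0 = np.array([1.5 * y_rng, y_bin.min(), beta0, gamma0])
            sol = optimize.least_squares(
                residuals, x0,
                bounds=([1e-12, -np.inf, 1e-12, -np.inf],
                        [np.inf, np.inf, np.inf, np.inf]))
            if best is None or sol.cost < best.cost:
                best = sol
    alpha, eps, beta, gamma = best.x
    params = NonlinearityParams(alpha=alpha, epsilon=eps, beta=beta,
                                gamma=gamma)
    fitted = params.evaluate(x_bin)
    ss_res = float(np.sum((fitted - y_bin) ** 2))
    ss_tot = float(np.sum((y_bin - y_bin.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return NonlinearityFit(params, x_bin, y_bin, fitted, r2)


# ---------------------------------------------------------------------------
# Center-surround delay and cross-validation
# ---------------------------------------------------------------------------

def center_surround_delay(filter_center: np.ndarray,
                          filter_surround: np.ndarray,
                          dt_ms: float = 1.0) -> float:
    """Surround lag (ms): time-to-peak(surround) - time-to-peak(center).

    Time-to-peak is the sample of maximal absolute value, so the measure is
    insensitive to the opposite response polarity of the surround.
    """
    tc = np.argmax(np.abs(np.asarray(filter_center)))
    ts = np.argmax(np.abs(np.asarray(filter_surround)))
    return float((ts - tc) * dt_ms)


def validate_on_repeats(filt: np.ndarray,
                        nonlinearity: NonlinearityParams | None,
                        repeated_stimulus: np.ndarray,
                        repeated_responses: np.ndarray) -> float:
    """Pearson r between the trial-averaged response and the LN prediction.

    ``repeated_responses`` is (n_trials, n_samples); the repeats must be
    held out from fitting.  Returns NaN when either signal is constant
    (degenerate correlation).
    """
    responses = np.atleast_2d(np.asarray(repeated_responses, dtype=float))
    mean_resp = responses.mean(axis=0)
    pred, burn = compute_linear_prediction(filt, repeated_stimulus)
    if nonlinearity is not None:
        pred = nonlinearity.evaluate(pred)
    pred, mean_resp = pred[burn:], mean_resp[burn:]
    if np.std(pred) == 0 or np.std(mean_resp) == 0:
        return float("nan")
    return float(pearsonr(pred, mean_resp)[0])


# ---------------------------------------------------------------------------
# Full LN estimation chain
# ---------------------------------------------------------------------------

@dataclass
class LNModelFit:
    filter: np.ndarray
    nonlinearity: NonlinearityFit
    dt_ms: float
    raw_filter: np.ndarray | None = None
    filter_params: TemporalFilterParams | None = None

    @property
    def time_to_peak(self) -> float:
        return float(np.argmax(np.abs(self.filter)) * self.dt_ms)

    def predict(self, contrast_trajectory: np.ndarray) -> np.ndarray:
        p, _ = compute_linear_prediction(self.filter, contrast_trajectory)
        return self.nonlinearity.params.evaluate(p)


def estimate_ln_model(contrast_trajectory: np.ndarray,
                      response_trace: np.ndarray,
                      dt_ms: float,
                      max_lag_ms: float = 500.0,
                      n_bins: int = 40,
                      parametric_filter: bool = False) -> LNModelFit:
    """Full LN characterization: filter by reverse correlation, then the
    static nonlinearity from binned (prediction, response) means.

    With ``parametric_filter`` the raw reverse-correlation estimate is
    denoised by the damped-oscillator fit before the linear prediction is
    formed.  Estimation noise in the filter otherwise propagates into the
    prediction and attenuates the fitted nonlinearity's slope
    (an errors-in-variables bias); the parametric smoothing removes it.
    """
    max_lag = int(round(max_lag_ms / dt_ms))
    raw = compute_temporal_filter(contrast_trajectory, response_trace,
                                  max_lag)
    filt = raw
    filter_params = None
    if parametric_filter:
        filter_params, _ = fit_damped_oscillator(raw, dt_ms=dt_ms)
        filt = filter_params.evaluate((np.arange(raw.size) + 0.5) * dt_ms)
    pred, burn = compute_linear_prediction(filt, contrast_trajectory)
    nl = fit_output_nonlinearity(pred, response_trace, n_bins=n_bins,
                                 burn_in=burn)
    return LNModelFit(filt, nl, dt_ms, raw_filter=raw,
                      filter_params=filter_params)
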
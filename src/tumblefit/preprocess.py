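"""Turn raw streaming angle data into denoised, periodicity-free features.

Stages, in order: fold the angle modulo pi into [-pi/2, pi/2); branch-
continue it so linear filters never straddle the fold; moving average
(window 0.08 dimensionless time, stride 0.005); wavelet soft-threshold
denoising with the universal (median-based) threshold estimated from the
finest-scale detail coefficients; refold; and finally the piecewise-linear
angular transform mapping the folded angle into [0, 1], which removes the
pi-periodicity of the tumbling observable before learning.

The angular speed fed to training is by default recomputed from the
denoised angle by central differences; a flag routes the raw speed channel
through the same MA+wavelet filters instead, since both the raw angle and
the raw speed streams exist in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .dynamics import ConfigurationError

__all__ = [
    "FilterConfig",
    "BodyKinetics",
    "moving_average",
    "soft_threshold",
    "universal_threshold",
    "wavelet_denoise",
    "fold_angle",
    "angular_transform",
    "estimate_angular_speed",
    "kinetic_split",
    "preprocess_series",
    "MovingAverageFilter",
    "WaveletDenoiser",
]


@dataclass(frozen=True)
class FilterConfig:
    """Denoising-filter settings.

    ``ma_window`` and ``ma_stride`` are in dimensionless time and are
    converted to sample counts by rounding half-up against the series'
    sampling interval.  ``max_level`` is the deepest wavelet decomposition
    level J (reduced automatically for short series).
    """

    ma_window: float = 0.08
    ma_stride: float = 0.005
    wavelet_family: str = "db4"
    max_level: int = 4
    threshold_mode: str = "soft"
    speed_from_raw_channel: bool = False

    def __post_init__(self):
        if not (self.ma_window > self.ma_stride > 0):
            raise ConfigurationError(
                "need ma_window > ma_stride > 0, got "
                f"window={self.ma_window}, stride={self.ma_stride}"
            )
        if self.max_level < 1:
            raise ConfigurationError("max_level must be >= 1")
        if self.threshold_mode != "soft":
            raise ConfigurationError("only soft thresholding is supported")

    def window_samples(self, dt: float) -> int:
        return max(1, int(np.floor(self.ma_window / dt + 0.5)))

    def stride_samples(self, dt: float) -> int:
        return max(1, int(np.floor(self.ma_stride / dt + 0.5)))


@dataclass(frozen=True)
class BodyKinetics:
    """Rigid-body kinetic state: mass M, centre-of-mass velocity V_com,
    angular velocity omega and the moment-of-inertia tensor I."""

    mass: float
    com_velocity: np.ndarray  # 3-vector
    angular_velocity: np.ndarray  # 3-vector
    inertia: np.ndarray  # 3x3 symmetric


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def moving_average(times, values, config: FilterConfig):
    """Unweighted moving mean over a sliding window.

    Output time stamps sit at window centres, spaced by the stride;
    windows truncated at the edges are dropped.  Returns
    ``(times_out, values_out)``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) == 0:
        return times, values
    if len(times) == 1:
        return times.copy(), values.copy()
    dt = float(np.median(np.diff(times)))
    w = config.window_samples(dt)
    s = config.stride_samples(dt)
    if w <= 1:
        warnings.warn(
            "moving-average window shorter than the sampling interval; "
            "passing the series through unchanged"
        )
        return times.copy(), values.copy()
    starts = np.arange(0, len(values) - w + 1, s)
    if len(starts) == 0:
        warnings.warn("series shorter than the moving-average window")
        return times.copy(), values.copy()
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out_vals = (csum[starts + w] - csum[starts]) / w
    ct = np.concatenate([[0.0], np.cumsum(times)])
    out_times = (ct[starts + w] - ct[starts]) / w
    return out_times, out_vals


def soft_threshold(coefficient, threshold: float):
    """Soft shrinkage: ``[D - mu sgn(D)] * 1{|D| > mu}``.

    Zeroes coefficients inside the dead zone and shrinks the remainder
    toward zero by the threshold; odd in D and a contraction.
    """
    if threshold < 0:
        raise ConfigurationError(f"threshold must be >= 0, got {threshold}")
    d = np.asarray(coefficient, dtype=float)
    out = np.where(np.abs(d) > threshold, d - threshold * np.sign(d), 0.0)
    return out if out.shape else float(out)


def universal_threshold(finest_details, n: int) -> float:
    """Universal threshold mu = eta sqrt(2 ln n) with the robust noise
    scale eta = median(|D1|)/0.6745 estimated from the finest-scale
    detail coefficients."""
    d1 = np.asarray(finest_details, dtype=float)
    if d1.size == 0:
        raise ValueError("finest-scale details are empty")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    eta = float(np.median(np.abs(d1))) / 0.6745
    return eta * float(np.sqrt(2.0 * np.log(n)))


def wavelet_denoise(values, config: FilterConfig | None = None):
    """Wavelet soft-threshold denoising.

    Decomposes to level J (symmetric extension), estimates one universal
    threshold from the finest-scale details, soft-thresholds every detail
    level with it, keeps the approximation coefficients, and reconstructs.
    Output length equals input length.
    """
    config = config or FilterConfig()
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return x
    wavelet = pywt.Wavelet(config.wavelet_family)
    max_allowed = pywt.dwt_max_level(len(x), wavelet.dec_len)
    level = min(config.max_level, max_allowed)
    if level < 1:
        warnings.warn("series too short for wavelet decomposition; passing through")
        return x.copy()
    if level < config.max_level:
        warnings.warn(
            f"series too short for level {config.max_level}; reduced to {level}"
        )
    coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=level)
    finest = coeffs[-1]
    if np.all(finest == 0.0):
        mu = 0.0
    else:
        mu = universal_threshold(finest, len(x))
    cleaned = [coeffs[0]] + [soft_threshold(d, mu) for d in coeffs[1:]]
    out = pywt.waverec(cleaned, wavelet, mode="symmetric")
    return out[: len(x)]


def fold_angle(unwrapped_angle):
    """Representative of the angle modulo pi lying in [-pi/2, pi/2)."""
    phi = np.asarray(unwrapped_angle, dtype=float)
    out = np.mod(phi + np.pi / 2.0, np.pi) - np.pi / 2.0
    return out if out.shape else float(out)


def angular_transform(folded_angle):
    """Piecewise-linear periodicity-removing map phi_f -> phi_p in [0, 1]:

    ``1 - 2 phi_f/pi`` on [0, pi/2), ``1 + 2 phi_f/pi`` on [-pi/2, 0).
    Even in phi_f; inputs outside the domain are folded first.
    """
    phi_f = fold_angle(folded_angle)
    out = 1.0 - 2.0 * np.abs(np.asarray(phi_f)) / np.pi
    return out if out.shape else float(out)


def estimate_angular_speed(times, angles):
    """Central-difference angular speed on a uniform grid.

    ``angles`` must be the unwrapped (continuous) angle; endpoints use
    one-sided differences.  Output grid equals the input grid.
    """
    times = np.asarray(times, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 samples")
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError(
            "non-uniform time grid; resample onto a uniform grid first"
        )
    return np.gradient(angles, times)


def kinetic_split(kinetics: BodyKinetics):
    """Translational, rotational and total kinetic energy:

    ``E_tr = 1/2 M |V_com|^2``, ``E_ro = 1/2 omega I omega^T``,
    ``E_k = E_tr + E_ro``.
    """
    if kinetics.mass < 0:
        raise ValueError(f"mass must be non-negative, got {kinetics.mass}")
    inertia = np.asarray(kinetics.inertia, dtype=float)
    if not np.allclose(inertia, inertia.T):
        raise ValueError("inertia tensor must be symmetric")
    v = np.asarray(kinetics.com_velocity, dtype=float)
    w = np.asarray(kinetics.angular_velocity, dtype=float)
    e_tr = 0.5 * kinetics.mass * float(v @ v)
    e_ro = 0.5 * float(w @ inertia @ w)
    return e_tr, e_ro, e_tr + e_ro


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def preprocess_series(
    frame: pd.DataFrame, config: FilterConfig | None = None
) -> pd.DataFrame:
    """Full pipeline: fold -> branch-continue -> MA -> wavelet -> refold ->
    angular transform, plus angular-speed estimation.

    ``frame`` needs columns ``gamma_t`` and ``phi`` (and ``phi_dot`` when
    ``speed_from_raw_channel`` is set).  Returns a processed stream with
    columns ``gamma_t, phi_f, phi_p, phi_dot`` on the moving-average grid.
    The result is invariant under adding integer multiples of pi to the
    raw angle, because folding happens first.
    """
    config = config or FilterConfig()
    times = frame["gamma_t"].to_numpy(dtype=float)
    phi_raw = frame["phi"].to_numpy(dtype=float)
    # fold, then continue the branch so the filters see a continuous signal
    folded = fold_angle(phi_raw)
    continuous = np.unwrap(folded, period=np.pi)
    t_ma, phi_ma = moving_average(times, continuous, config)
    phi_den = wavelet_denoise(phi_ma, config)
    phi_f = fold_angle(phi_den)
    phi_p = angular_transform(phi_f)
    if config.speed_from_raw_channel:
        if "phi_dot" not in frame:
            raise ConfigurationError(
                "speed_from_raw_channel requires a phi_dot column"
            )
        dot_raw = frame["phi_dot"].to_numpy(dtype=float)
        _, dot_ma = moving_average(times, dot_raw, config)
        phi_dot = wavelet_denoise(dot_ma, config)
    else:
        phi_dot = estimate_angular_speed(t_ma, phi_den)
    return pd.DataFrame(
        {"gamma_t": t_ma, "phi_f": phi_f, "phi_p": phi_p, "phi_dot": phi_dot}
    )


class MovingAverageFilter(TransformerMixin, BaseEstimator):
    """Moving-average smoother over (time, value) series.

    Transformer over arrays of shape (n, 2) with columns (time, value);
    returns the filtered (m, 2) array on the window-centre grid.
    """

    def __init__(self, window: float = 0.08, stride: float = 0.005):
        self.window = window
        self.stride = stride

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of (time, value) rows")
        self.n_features_in_ = 2
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        cfg = FilterConfig(ma_window=self.window, ma_stride=self.stride)
        t, v = moving_average(X[:, 0], X[:, 1], cfg)
        return np.column_stack([t, v])


class WaveletDenoiser(TransformerMixin, BaseEstimator):
    """Universal-threshold wavelet denoiser for 1-D signals.

    Transformer over arrays of shape (n,) or (n, 1); stateless apart from
    remembering the decomposition level actually used (``level_``).
    """

    def __init__(self, wavelet: str = "db4", max_level: int = 4):
        self.wavelet = wavelet
        self.max_level = max_level

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        w = pywt.Wavelet(self.wavelet)
        self.level_ = min(self.max_level, pywt.dwt_max_level(len(x), w.dec_len))
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        cfg = FilterConfig(wavelet_family=self.wavelet, max_level=self.max_level)
        out = wavelet_denoise(X.ravel(), cfg)
        return out.reshape(X.shape)
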
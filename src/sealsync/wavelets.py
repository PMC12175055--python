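"""Morlet wavelet power, coherence, and multivariate modulus ratio.

Continuous wavelet machinery for short annual ecological series, following
the Torrence & Compo conventions: Morlet mother wavelet with omega0 = 6
(Fourier factor 4*pi/(6+sqrt(38)) ~ 1.033, so period ~ 1.033 * scale),
FFT-based transform with zero padding, cone of influence at the sqrt(2)*s
e-folding time.  Default scale grid: powers of two from 2 to 8 years with
dj = 1/12.

Coherence uses Torrence & Webster smoothing: a Gaussian window in time with
SD equal to the scale, and a boxcar of 0.6 * scale along the scale axis.
Significance is assessed against AR(1) (red-noise) surrogate series rather
than a chi-square closed form, so power, coherence and the modulus ratio
share one null machinery.

Series are usually detrended first with :func:`gaussian_highpass`
(half-power at an 8-year period by default) and normalized to mean 0, SD 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WaveletSpectrum",
    "CoherenceSpectrum",
    "ModulusRatioField",
    "default_scales",
    "gaussian_highpass",
    "cwt_morlet",
    "wavelet_coherence",
    "modulus_ratio",
    "rednoise_significance",
]

OMEGA0 = 6.0
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))  # 1.0330


def default_scales(s0: float = 2.0, s_max: float = 8.0, dj: float = 1.0 / 12.0
                   ) -> np.ndarray:
    n = int(np.floor(np.log2(s_max / s0) / dj)) + 1
    return s0 * 2.0 ** (dj * np.arange(n))


@dataclass
class WaveletSpectrum:
    times: np.ndarray
    scales: np.ndarray
    coefficients: np.ndarray       # complex, (n_scales, n_times)
    coi: np.ndarray                # max reliable scale per time
    signif: np.ndarray | None = None

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    def inside_coi(self) -> np.ndarray:
        """(n_scales, n_times) mask of points unaffected by edge effects."""
        return self.scales[:, None] <= self.coi[None, :]


@dataclass
class CoherenceSpectrum:
    times: np.ndarray
    scales: np.ndarray
    coherence: np.ndarray          # in [0, 1]
    phase: np.ndarray              # radians in (-pi, pi]
    coi: np.ndarray
    signif: np.ndarray | None = None

    def inside_coi(self) -> np.ndarray:
        return self.scales[:, None] <= self.coi[None, :]


@dataclass
class ModulusRatioField:
    times: np.ndarray
    scales: np.ndarray
    ratio: np.ndarray              # in [0, 1]
    coi: np.ndarray

    def inside_coi(self) -> np.ndarray:
        return self.scales[:, None] <= self.coi[None, :]


def gaussian_highpass(series, cutoff_years: float = 8.0, dt: float = 1.0,
                      normalize: bool = True):
    """Remove variation slower than ``cutoff_years`` with a Gaussian filter.

    The low-pass kernel SD is set so the transfer function
    exp(-2 pi^2 sigma^2 / P^2) equals 1/2 at period P = cutoff; the
    high-pass output is the series minus this low-pass, computed with
    reflection padding.  The result is normalized to mean 0, SD 1 unless
    the filtered series is constant (returned as zeros with a log notice).
    """
    x = np.asarray(series, float)
    if np.any(~np.isfinite(x)):
        idx = np.arange(x.size)
        good = np.isfinite(x)
        logger.info("interpolating %d missing values before filtering",
                    int((~good).sum()))
        x = np.interp(idx, idx[good], x[good])
    if x.size * dt < cutoff_years:
        raise ValueError("series shorter than the cutoff period")
    sigma = cutoff_years / dt * np.sqrt(np.log(2.0)) / (np.pi * np.sqrt(2.0))
    half = int(np.ceil(4 * sigma))
    t = np.arange(-half, half + 1)
    kernel = np.exp(-t**2 / (2.0 * sigma**2))
    kernel /= kernel.sum()
    padded = np.concatenate([x[half:0:-1], x, x[-2:-half - 2:-1]])
    low = np.convolve(padded, kernel, mode="valid")
    out = x - low
    if not normalize:
        return out
    sd = out.std(ddof=0)
    if sd == 0:
        logger.info("high-pass output constant: returning zeros")
        return np.zeros_like(out)
    return (out - out.mean()) / sd


def cwt_morlet(series, scales=None, dt: float = 1.0,
               times=None) -> WaveletSpectrum:
    """Morlet continuous wavelet transform by FFT with zero padding."""
    x = np.asarray(series, float)
    if np.any(~np.isfinite(x)):
        raise ValueError("series must be gap-free (interpolate first)")
    n = x.size
    scales = default_scales() if scales is None else np.asarray(scales, float)
    if np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be strictly increasing")
    n_pad = int(2 ** np.ceil(np.log2(n)) * 2)
    xf = np.fft.fft(x, n_pad)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)
    W = np.empty((scales.size, n), complex)
    norm_const = np.pi**-0.25
    for i, s in enumerate(scales):
        # unit-energy normalization in frequency space
        psi_hat = (norm_const * np.sqrt(2.0 * np.pi * s / dt)
                   * np.exp(-0.5 * (s * omega - OMEGA0) ** 2) * (omega > 0))
        W[i] = np.fft.ifft(xf * psi_hat)[:n]
    t = np.arange(n) * dt if times is None else np.asarray(times, float)
    # e-folding time sqrt(2)*s: at distance d from an edge, scales up to
    # d/sqrt(2) are unaffected
    edge = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    coi = edge / np.sqrt(2.0)
    return WaveletSpectrum(times=t, scales=scales, coefficients=W, coi=coi)


# ---------------------------------------------------------------------------
# smoothing operators (Torrence & Webster)


def _smooth_time(field: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Gaussian smoothing along time with SD = scale (per row)."""
    out = np.empty_like(field)
    n = field.shape[1]
    for i, s in enumerate(scales):
        sigma = s / dt
        half = max(1, int(np.ceil(3 * sigma)))
        t = np.arange(-half, half + 1)
        k = np.exp(-(t**2) / (2.0 * sigma**2))
        k /= k.sum()
        re = np.convolve(np.pad(field[i].real, half, mode="reflect"), k, "valid")
        if np.iscomplexobj(field):
            im = np.convolve(np.pad(field[i].imag, half, mode="reflect"), k, "valid")
            out[i] = re + 1j * im
        else:
            out[i] = re
    return out[:, :n]


def _smooth_scale(field: np.ndarray, dj: float, width: float = 0.6) -> np.ndarray:
    """Boxcar smoothing along the scale axis over ``width`` octaves."""
    m = max(1, int(round(width / dj)))
    if m <= 1 or field.shape[0] == 1:
        return field.copy()
    k = np.ones(m) / m
    pad = m // 2
    out = np.empty_like(field)
    for j in range(field.shape[1]):
        col = np.pad(field[:, j], pad + 1, mode="edge")
        sm = np.convolve(col, k, "valid")
        off = (sm.size - field.shape[0]) // 2
        out[:, j] = sm[off:off + field.shape[0]]
    return out


def _dj_of(scales: np.ndarray) -> float:
    return float(np.mean(np.diff(np.log2(scales)))) if scales.size > 1 else 1.0


def wavelet_coherence(x, y, scales=None, dt: float = 1.0,
                      times=None, smooth: bool = True) -> CoherenceSpectrum:
    """Squared wavelet coherence of two equally pre-processed series.

    coherence = |S(Wx Wy* / s)|^2 / (S(|Wx|^2 / s) S(|Wy|^2 / s)) with the
    Torrence-Webster smoothing S (Gaussian in time, boxcar 0.6 octaves in
    scale); phase is the argument of the smoothed cross-spectrum (0 = in
    phase, pi/2 = y lagging a quarter cycle).  ``smooth=False`` is refused:
    unsmoothed coherence is identically 1.
    """
    if not smooth:
        raise ValueError("unsmoothed coherence is identically 1 and meaningless")
    wx = cwt_morlet(x, scales, dt, times)
    wy = cwt_morlet(y, scales, dt, times)
    if wx.coefficients.shape != wy.coefficients.shape:
        raise ValueError("series must have the same length")
    s = wx.scales[:, None]
    dj = _dj_of(wx.scales)
    cross = _smooth_scale(_smooth_time(wx.coefficients * np.conj(wy.coefficients) / s,
                                       wx.scales, dt), dj)
    px = _smooth_scale(_smooth_time(np.abs(wx.coefficients) ** 2 / s,
                                    wx.scales, dt), dj).real
    py = _smooth_scale(_smooth_time(np.abs(wy.coefficients) ** 2 / s,
                                    wx.scales, dt), dj).real
    denom = px * py
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(cross) ** 2 / denom
        phase = np.angle(cross)
    coh = np.clip(np.where(denom > 0, coh, 0.0), 0.0, 1.0)
    phase = np.where(denom > 0, phase, np.nan)
    return CoherenceSpectrum(times=wx.times, scales=wx.scales, coherence=coh,
                             phase=phase, coi=wx.coi)


def modulus_ratio(series_set, scales=None, dt: float = 1.0,
                  times=None, bandwidth: float = 1.0) -> ModulusRatioField:
    """Localized multivariate wavelet modulus ratio.

    rho(t, s) = G(|sum_i W_i|) / G(sum_i |W_i|) with Gaussian local
    smoothing G of bandwidth ``bandwidth * scale``; rho = 1 when all series
    oscillate in phase at (t, s), ~0 under cancellation.
    """
    series_set = [np.asarray(s, float) for s in series_set]
    if len(series_set) < 2:
        raise ValueError("modulus ratio needs at least 2 series")
    specs = [cwt_morlet(s, scales, dt, times) for s in series_set]
    Wsum = np.sum([sp.coefficients for sp in specs], axis=0)
    modsum = np.sum([np.abs(sp.coefficients) for sp in specs], axis=0)
    sc = specs[0].scales * bandwidth
    num = _smooth_time(np.abs(Wsum), sc, dt)
    den = _smooth_time(modsum, sc, dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    return ModulusRatioField(times=specs[0].times, scales=specs[0].scales,
                             ratio=np.clip(rho.real, 0.0, 1.0), coi=specs[0].coi)


# ---------------------------------------------------------------------------
# red-noise significance


def _ar1_coef(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    x = x - x.mean()
    denom = float(np.sum(x**2))
    if denom == 0:
        return 0.0
    rho = float(np.sum(x[1:] * x[:-1]) / denom)
    if abs(rho) >= 1.0:
        logger.warning("AR(1) estimate |rho| >= 1; clipping to 0.99")
        rho = np.sign(rho) * 0.99
    return rho


def _ar1_surrogates(x: np.ndarray, n: int, rng) -> np.ndarray:
    """AR(1) surrogates matching lag-1 autocorrelation and variance."""
    rho = _ar1_coef(x)
    var = float(np.var(x))
    innov_sd = np.sqrt(max(var * (1.0 - rho**2), 1e-300))
    T = x.size
    out = np.empty((n, T))
    out[:, 0] = rng.normal(0.0, np.sqrt(max(var, 1e-300)), size=n)
    e = rng.normal(0.0, innov_sd, size=(n, T))
    for t in range(1, T):
        out[:, t] = rho * out[:, t - 1] + e[:, t]
    mean = x.mean()
    return out + mean


def rednoise_significance(x, y=None, scales=None, dt: float = 1.0,
                          kind: str = "power", n_surrogates: int = 300,
                          alpha: float = 0.05, seed: int = 0):
    """Pointwise red-noise significance mask for power or coherence.

    AR(1) surrogate series are simulated from the lag-1 autocorrelation of
    the input(s); the mask marks (scale, time) cells where the observed
    quantity exceeds the 1-alpha surrogate quantile.  Seed-deterministic.
    Returns (mask, critical_values).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    if kind == "power":
        obs = cwt_morlet(x, scales, dt).power
        sur = np.empty((n_surrogates,) + obs.shape)
        reps = _ar1_surrogates(x, n_surrogates, rng)
        for i in range(n_surrogates):
            sur[i] = cwt_morlet(reps[i], scales, dt).power
    elif kind == "coherence":
        if y is None:
            raise ValueError("coherence significance needs both series")
        y = np.asarray(y, float)
        obs = wavelet_coherence(x, y, scales, dt).coherence
        sur = np.empty((n_surrogates,) + obs.shape)
        rx = _ar1_surrogates(x, n_surrogates, rng)
        ry = _ar1_surrogates(y, n_surrogates, rng)
        for i in range(n_surrogates):
            sur[i] = wavelet_coherence(rx[i], ry[i], scales, dt).coherence
    else:
        raise ValueError(f"unknown kind {kind!r}")
    crit = np.quantile(sur, 1.0 - alpha, axis=0)
    return obs > crit, crit
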
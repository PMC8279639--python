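"""Morlet continuous wavelet transform of generalized-mode velocities.

A mode-velocity signal Qdot(t) is decomposed on a family of wavelets
obtained from the Morlet mother wavelet

    psi(u) = exp(i*omega0*u) * exp(-u**2 / 2)

by L²-normalized dilatation (scale a, fs) and translation (shift b, fs):

    psi_ab(t) = a**-1/2 * psi((t - b) / a) .

The squared magnitude |W(nu, t)|² of the transform is the time–frequency
power map ("spectrogram"); the scale–frequency mapping

    nu[cm^-1] = omega0 / (2 pi a[fs]) * 33356.40952

is exact for a pure tone in the analytic-Morlet approximation, which is
accurate for omega0 >= 5 (the small correction term that restores exact
admissibility is dropped). Band-integrated power versus time gives the
operational decay time of a transient vibration: the first time, after
the early maximum, at which smoothed band power falls and stays below a
threshold fraction (1/e by default) of that maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from ._units import CM1_PER_CYCLE_FS

__all__ = [
    "WaveletParams",
    "Spectrogram",
    "morlet",
    "scale_for_frequency",
    "frequency_for_scale",
    "cwt",
    "band_power",
    "decay_time",
    "NO_DECAY",
]

#: sentinel returned by :func:`decay_time` when band power never decays
NO_DECAY = math.inf


@dataclass
class WaveletParams:
    """Morlet CWT configuration.

    omega0 is the dimensionless Morlet center parameter (default 6, the
    standard time/frequency-balance choice); frequencies span
    [fmin, fmax] cm^-1 on a logarithmic grid with ``voices_per_octave``
    points per frequency doubling unless ``n_scales`` is set explicitly.
    """

    fmin: float
    fmax: float
    omega0: float = 6.0
    voices_per_octave: int = 12
    n_scales: int | None = None

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError("omega0 must be >= 5 (analytic-Morlet regime)")
        if not 0 < self.fmin < self.fmax:
            raise ValueError("need 0 < fmin < fmax")
        if self.n_scales is not None and self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")

    def frequency_grid(self) -> np.ndarray:
        """Strictly increasing cm^-1 grid, logarithmically spaced."""
        if self.n_scales is not None:
            n = self.n_scales
        else:
            n = int(np.ceil(np.log2(self.fmax / self.fmin) * self.voices_per_octave)) + 1
            n = max(n, 2)
        return np.geomspace(self.fmin, self.fmax, n)


@dataclass
class Spectrogram:
    """Time–frequency power map |W(nu, t)|² with physical axes.

    ``power`` has shape (n_freq, n_time); ``coi[t]`` is the
    cone-of-influence bound in cm^-1 — at time t, frequencies *below*
    ``coi[t]`` are contaminated by the signal edges.
    """

    times: np.ndarray  # fs
    frequencies: np.ndarray  # cm^-1
    power: np.ndarray  # (n_freq, n_time)
    coi: np.ndarray  # cm^-1 per time point

    def outside_coi(self) -> np.ndarray:
        """Boolean mask (n_freq, n_time), True where edge effects are small."""
        return self.frequencies[:, None] >= self.coi[None, :]

    def ridge(self, restrict_to_coi: bool = True) -> np.ndarray:
        """Per-time frequency of maximum power, cm^-1.

        With ``restrict_to_coi`` the argmax is taken over frequencies
        outside the cone of influence; times where no frequency
        qualifies give NaN.
        """
        power = self.power
        if restrict_to_coi:
            power = np.where(self.outside_coi(), power, -np.inf)
        out = np.full(self.times.size, np.nan)
        valid = np.isfinite(power).any(axis=0)
        out[valid] = self.frequencies[np.argmax(power[:, valid], axis=0)]
        return out


def scale_for_frequency(nu_cm1: float, omega0: float = 6.0) -> float:
    """Morlet scale a (fs) whose center frequency is ``nu_cm1``."""
    return omega0 * CM1_PER_CYCLE_FS / (2.0 * math.pi * nu_cm1)


def frequency_for_scale(a_fs: float, omega0: float = 6.0) -> float:
    """Center frequency (cm^-1) of the Morlet wavelet at scale a (fs)."""
    return omega0 * CM1_PER_CYCLE_FS / (2.0 * math.pi * a_fs)


def morlet(a: float, b: float, t, omega0: float = 6.0):
    """Dilated/translated Morlet wavelet psi_ab(t) = psi((t-b)/a)/sqrt(a).

    Analytic form exp(i*omega0*u)*exp(-u²/2); the admissibility
    correction is negligible for omega0 >= 5. L²-normalized: the
    integral of |psi_ab|² over t is independent of a.
    """
    if a <= 0:
        raise ValueError("scale a must be positive")
    u = (np.asarray(t, dtype=float) - b) / a
    return (1.0 / math.sqrt(a)) * np.exp(1j * omega0 * u) * np.exp(-0.5 * u**2)


def cwt(signal: np.ndarray, dt: float, params: WaveletParams) -> Spectrogram:
    """Continuous Morlet wavelet transform of a mode-velocity signal.

    The transform W(a, b) = ∫ s(t) psi*_ab(t) dt is evaluated by FFT
    convolution with each scaled wavelet, on a logarithmic frequency
    grid spanning [fmin, fmax]. The signal is extended by symmetric
    reflection so the convolution is defined up to the edges; the cone
    of influence marks where edge attenuation of the Gaussian envelope
    exceeds e⁻², i.e. times closer to an edge than the e-folding time
    sqrt(2)·a.
    """
    s = np.asarray(signal, dtype=float).ravel()
    n = s.size
    if n < 64:
        raise ValueError(f"signal too short for a CWT ({n} < 64 samples)")
    nyquist_cm1 = CM1_PER_CYCLE_FS / (2.0 * dt)
    if params.fmax > nyquist_cm1:
        raise ValueError(
            f"fmax = {params.fmax:g} cm^-1 exceeds the Nyquist frequency "
            f"{nyquist_cm1:g} cm^-1 for dt = {dt:g} fs"
        )
    freqs = params.frequency_grid()
    power = np.empty((freqs.size, n))
    s_mean = s.mean()
    sc = s - s_mean
    for k, nu in enumerate(freqs):
        a = scale_for_frequency(nu, params.omega0)
        half = int(np.ceil(5.0 * a / dt))  # Gaussian support, e^-12.5 at edge
        tk = np.arange(-half, half + 1) * dt
        kernel = np.conj(morlet(a, 0.0, tk, params.omega0))
        pad = min(half, n - 1)
        left = sc[1 : pad + 1][::-1]
        right = sc[-pad - 1 : -1][::-1]
        spad = np.concatenate([left, sc, right])
        if pad < half:  # reflection shorter than kernel support: zero-extend
            extra = half - pad
            spad = np.pad(spad, (extra, extra))
        W = fftconvolve(spad, kernel[::-1], mode="valid") * dt
        power[k] = np.abs(W) ** 2
    times = np.arange(n) * dt
    # e-folding time of |psi|^2 envelope is sqrt(2)*a; a time t within
    # sqrt(2)*a of either edge is contaminated at scales >= t/sqrt(2)
    edge = np.minimum(times, times[-1] - times)
    with np.errstate(divide="ignore"):
        coi = np.where(
            edge > 0,
            math.sqrt(2.0) * params.omega0 * CM1_PER_CYCLE_FS / (2.0 * math.pi * edge),
            np.inf,
        )
    return Spectrogram(times=times, frequencies=freqs, power=power, coi=coi)


def band_power(spec: Spectrogram, band: tuple[float, float]) -> np.ndarray:
    """Per-time trapezoidal integral of power over a frequency band (cm^-1)."""
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    if hi < spec.frequencies[0] or lo > spec.frequencies[-1]:
        raise ValueError("band lies outside the spectrogram frequency range")
    mask = (spec.frequencies >= lo) & (spec.frequencies <= hi)
    if mask.sum() < 2:
        raise ValueError("band contains fewer than 2 frequency grid points")
    return np.trapezoid(spec.power[mask], x=spec.frequencies[mask], axis=0)


def decay_time(
    band_series: np.ndarray,
    times: np.ndarray,
    threshold_fraction: float = math.exp(-1),
    smooth_window: int = 5,
) -> float:
    """Operational decay time of a transient band-power series, fs.

    The series is smoothed with a moving average (``smooth_window``
    steps), its early maximum located within the first quarter of the
    window, and the decay time is the first time after that maximum at
    which the smoothed power falls — and stays — below
    ``threshold_fraction`` × the early maximum. Returns the
    :data:`NO_DECAY` sentinel (inf) if the threshold is never
    permanently crossed.
    """
    p = np.asarray(band_series, dtype=float).ravel()
    t = np.asarray(times, dtype=float).ravel()
    if p.size != t.size:
        raise ValueError("series and times lengths differ")
    if p.size < 8:
        raise ValueError("need at least 8 points to estimate a decay time")
    if np.any(p < 0):
        raise ValueError("band power must be non-negative")
    if not np.any(p > 0):
        raise ValueError("band power is identically zero")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        ps = np.convolve(p, kernel, mode="same")
    else:
        ps = p
    quarter = max(1, p.size // 4)
    i_max = int(np.argmax(ps[:quarter]))
    peak = ps[i_max]
    threshold = threshold_fraction * peak
    below = ps < threshold
    # first index after the maximum from which the series stays below
    stays_below = np.logical_and.accumulate(below[::-1])[::-1]
    idx = np.nonzero(stays_below[i_max + 1 :])[0]
    if idx.size == 0:
        return NO_DECAY
    return float(t[i_max + 1 + idx[0]])
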
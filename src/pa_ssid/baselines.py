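"""Comparison feature families: time-domain, frequency-domain, and ARMA.

Each extractor returns a :class:`~pa_ssid.modal.FeatureVector` with exactly
four named values, mirroring the four-parameter state-space family it is
benchmarked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.signal

from .modal import FeatureVector
from .signal import ONSET_THRESHOLD, PASignal

__all__ = [
    "PowerSpectrum",
    "time_domain_features",
    "power_spectrum",
    "frequency_domain_features",
    "arma_features",
    "DEFAULT_FD_BAND",
]

DEFAULT_FD_BAND = (1e6, 20e6)


@dataclass
class PowerSpectrum:
    """One-sided power spectral density in dB."""

    frequencies: np.ndarray  # Hz, strictly increasing, >= 0
    power_db: np.ndarray  # 10 log10(PSD)
    resolution: float  # Hz

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if self.frequencies.size != self.power_db.size:
            raise ValueError("frequency/power length mismatch")
        if np.any(self.frequencies < 0) or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be non-negative and strictly increasing")


def time_domain_features(signal: PASignal, sample_id: str = "") -> FeatureVector:
    """Four time-domain descriptors: peak amplitude, arrival time, RMS, and
    the trapezoidal area under |y|."""
    y = signal.samples
    if np.all(y == 0):
        raise ValueError("all-zero signal has no time-domain features")
    onset = signal.onset_index()
    values = {
        "max_amplitude": float(np.max(y)),
        "arrival_time": float(signal.t0 + signal.ts * onset),
        "rms": float(np.sqrt(np.mean(y**2))),
        "auc": float(np.trapezoid(np.abs(y), dx=signal.ts)),
    }
    return FeatureVector(sample_id=sample_id, label=signal.label, family="TD",
                         values=values)


def power_spectrum(
    signal: PASignal,
    window: str = "hann",
    onset_align: bool = True,
    nfft: Optional[int] = None,
) -> PowerSpectrum:
    """One-sided periodogram of the (optionally onset-aligned) trace, in dB.

    The window defaults to Hann; pass ``"boxcar"`` for a raw periodogram
    (exact Parseval behaviour).  ``nfft`` zero-pads the transform (finer
    peak interpolation); default is 2x the window length rounded up to a
    power of two.
    """
    if len(signal) < 16:
        raise ValueError("need at least 16 samples for a spectrum")
    work = signal.aligned(ONSET_THRESHOLD) if onset_align else signal
    n = len(work)
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f, pxx = scipy.signal.periodogram(
        work.samples, fs=1.0 / work.ts, window=window, scaling="density", nfft=nfft
    )
    # drop the DC bin so the dB scale is well defined for zero-mean traces
    f, pxx = f[1:], pxx[1:]
    floor = np.max(pxx) * 1e-300 if np.max(pxx) > 0 else 1e-300
    power_db = 10.0 * np.log10(np.maximum(pxx, floor))
    return PowerSpectrum(frequencies=f, power_db=power_db, resolution=float(f[1] - f[0]))


def frequency_domain_features(
    signal: PASignal,
    band: tuple[float, float] = DEFAULT_FD_BAND,
    sample_id: str = "",
    window: str = "hann",
) -> FeatureVector:
    """Line fit of the dB spectrum over an analysis band.

    Features: spectral slope (dB/MHz), magnitude intercept (dB extrapolated
    to 0 Hz), midband fit (dB at the band centre), and peak frequency (Hz)
    within the band.
    """
    f_lo, f_hi = band
    if f_lo >= f_hi:
        raise ValueError("band must satisfy f_lo < f_hi")
    nyquist = 0.5 / signal.ts
    if f_hi > nyquist:
        raise ValueError(f"band edge {f_hi:g} Hz beyond Nyquist {nyquist:g} Hz")
    spec = power_spectrum(signal, window=window)
    mask = (spec.frequencies >= f_lo) & (spec.frequencies <= f_hi)
    if np.count_nonzero(mask) < 3:
        raise ValueError("fewer than 3 spectral bins in the analysis band")
    f_band = spec.frequencies[mask]
    p_band = spec.power_db[mask]
    slope_per_hz, intercept = np.polyfit(f_band, p_band, 1)
    f_mid = 0.5 * (f_lo + f_hi)
    values = {
        "spectral_slope": float(slope_per_hz * 1e6),  # dB/MHz
        "intercept": float(intercept),
        "midband_fit": float(intercept + slope_per_hz * f_mid),
        "peak_frequency": float(f_band[np.argmax(p_band)]),
    }
    return FeatureVector(sample_id=sample_id, label=signal.label, family="FD",
                         values=values)


def _hannan_rissanen(y: np.ndarray, p: int, q: int, n_ar: int) -> np.ndarray:
    """Two-stage long-AR ARMA estimate; returns (a1..ap, b1..bq) for the
    convention y(k) = sum a_m y(k-m) + e(k) + sum b_m e(k-m)."""
    n = y.size
    # stage 1: long AR by least squares -> innovation estimates
    X = np.column_stack([y[n_ar - m : n - m] for m in range(1, n_ar + 1)])
    target = y[n_ar:]
    phi, *_ = np.linalg.lstsq(X, target, rcond=None)
    e = np.zeros(n)
    e[n_ar:] = target - X @ phi
    # stage 2: regress y on its own lags and lagged innovations
    lag = max(p, q)
    start = n_ar + lag
    cols = [y[start - m : n - m] for m in range(1, p + 1)]
    cols += [e[start - m : n - m] for m in range(1, q + 1)]
    Z = np.column_stack(cols)
    # adaptive ridge: near white noise the y-lag and innovation-lag columns
    # are almost collinear (AR/MA cancellation) and plain least squares puts
    # large cancelling weights on both; scale the penalty by the innovation
    # variance so deterministic signals are left untouched
    G = Z.T @ Z
    target = y[start:]
    theta0, *_ = np.linalg.lstsq(Z, target, rcond=None)
    s2 = float(np.mean((target - Z @ theta0) ** 2))
    delta = 3e-3 * s2 * len(target)
    theta = np.linalg.solve(G + delta * np.eye(G.shape[0]), Z.T @ target)
    return theta


def arma_features(
    signal: PASignal,
    p: int = 2,
    q: int = 2,
    sample_id: str = "",
    n_ar: Optional[int] = None,
) -> FeatureVector:
    """ARMA(p, q) coefficients of the onset-aligned trace, fitted by the
    two-stage long-AR (Hannan-Rissanen) procedure.

    The four features (default order (2, 2)) are (a1, a2, b1, b2).  A fit
    whose AR polynomial has roots on or inside the unit circle is flagged in
    ``meta['stationary'] = False`` but still returned.
    """
    work = signal.aligned(ONSET_THRESHOLD)
    y = work.samples
    n = y.size
    if n < 50:
        raise ValueError(f"need at least 50 samples after onset alignment, got {n}")
    if n_ar is None:
        n_ar = min(20, n // 4)
    theta = _hannan_rissanen(y, p, q, n_ar)
    values = {f"a{m + 1}": float(theta[m]) for m in range(p)}
    values.update({f"b{m + 1}": float(theta[p + m]) for m in range(q)})
    # stationarity: roots of z^p - a1 z^{p-1} - ... - ap must lie inside |z| = 1
    roots = np.roots(np.r_[1.0, -theta[:p]])
    stationary = bool(np.all(np.abs(roots) < 1.0))
    return FeatureVector(
        sample_id=sample_id,
        label=signal.label,
        family="ARMA",
        values=values,
        meta={"stationary": stationary},
    )
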
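"""Spectral analysis: FFT amplitude spectra, PSD, noise-colour exponents, CWT.

The central quantity is the power-law exponent β of the power spectral
density, PSD ∝ 1/f^β, estimated by ordinary least squares on log10(PSD)
vs log10(f).  β classifies the noise colour of an electrome: 0 white,
≈ 1 pink (long-range correlation, self-organised criticality), ≈ 2 brown,
≈ 3 black.  A narrow exclusion band around 5 Hz is applied by default
when fitting, because a constant 5 Hz component in EPG acquisitions is an
instrumentation artifact rather than a biological signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as ssig
from scipy import stats as sstats

from .io import Recording

__all__ = [
    "SpectrumEstimate",
    "PowerLawFit",
    "Scalogram",
    "fft_spectrum",
    "psd",
    "fit_psd_exponent",
    "classify_noise",
    "is_reddened",
    "cwt_scalogram",
    "total_power",
    "DEFAULT_FIT_BAND",
    "DEFAULT_EXCLUDE_BANDS",
]

DEFAULT_FIT_BAND = (0.01, 10.0)
DEFAULT_EXCLUDE_BANDS = ((4.5, 5.5),)


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided spectrum: frequencies (Hz) and amplitude or power values."""

    freqs: np.ndarray
    values: np.ndarray
    kind: str  # "fft_amplitude" or "psd"
    fs: float
    method_params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log OLS fit of a power law.

    ``slope`` is the signed log10-log10 regression slope and ``exponent``
    its negative (β for a PSD fit, μ for a PDF tail fit), so a decaying
    spectrum has positive exponent.
    """

    exponent: float
    slope: float
    intercept: float
    fit_band: tuple[float, float]
    r2: float
    stderr: float
    n_points: int
    ok: bool


@dataclass(frozen=True)
class Scalogram:
    """Continuous-wavelet magnitude over (pseudo-)frequencies × times."""

    frequencies: np.ndarray
    times: np.ndarray
    magnitude: np.ndarray  # shape (n_scales, n_times)
    wavelet: str


def fft_spectrum(rec: Recording) -> SpectrumEstimate:
    """One-sided FFT amplitude spectrum of a recording.

    Amplitudes are scaled so that a pure sinusoid of amplitude A produces
    a peak of height ≈ A at its frequency.  The DC bin is included in the
    grid (frequency 0) but excluded from power-law fitting downstream.
    """
    if rec.n < 16:
        raise ValueError("series too short for a meaningful spectrum")
    n = rec.n
    spec = np.fft.rfft(rec.samples)
    amp = np.abs(spec) / n
    amp[1:] *= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    return SpectrumEstimate(
        freqs=freqs, values=amp, kind="fft_amplitude", fs=rec.fs,
        method_params={"n": n, "scaling": "amplitude"},
    )


def total_power(spec: SpectrumEstimate) -> float:
    """Variance-equivalent total power of a spectrum (Parseval check).

    For an amplitude spectrum this is Σ a_k²/2 over the doubled bins plus
    the Nyquist term; for a PSD it is the trapezoidal integral over
    frequency.  Both equal the series variance up to estimator bias.
    """
    if spec.kind == "fft_amplitude":
        a = spec.values
        n = spec.method_params["n"]
        power = np.sum(a[1:] ** 2) / 2.0
        if n % 2 == 0:
            power += a[-1] ** 2 / 2.0  # undo the halving: Nyquist enters once
        return float(power)
    return float(np.trapezoid(spec.values, spec.freqs))


def _default_nperseg(n: int) -> int:
    target = max(n // 8, 16)
    return int(min(2 ** 14, 2 ** round(math.log2(target)), n))


def psd(
    rec: Recording,
    method: str = "welch",
    seg_len: int | None = None,
    window: str = "hann",
    overlap: float = 0.5,
) -> SpectrumEstimate:
    """One-sided power spectral density in µV²/Hz.

    Welch's method (Hann window, 50 % overlap, segment length
    ``min(2^14, n/8 rounded to a power of two)``) is the default; a raw
    periodogram is available for cross-checks.
    """
    x = rec.samples
    if method == "welch":
        nperseg = seg_len if seg_len is not None else _default_nperseg(rec.n)
        if nperseg > rec.n:
            raise ValueError("seg_len must not exceed the series length")
        freqs, values = ssig.welch(
            x, fs=rec.fs, window=window, nperseg=nperseg,
            noverlap=int(round(overlap * nperseg)), detrend="constant",
        )
        params = {"method": "welch", "nperseg": int(nperseg),
                  "window": window, "overlap": overlap}
    elif method == "periodogram":
        freqs, values = ssig.periodogram(x, fs=rec.fs, window="boxcar",
                                         detrend="constant")
        params = {"method": "periodogram"}
    else:
        raise ValueError("method must be 'welch' or 'periodogram'")
    return SpectrumEstimate(freqs=freqs, values=values, kind="psd",
                            fs=rec.fs, method_params=params)


def fit_psd_exponent(
    spec: SpectrumEstimate,
    band: tuple[float, float] = DEFAULT_FIT_BAND,
    exclude_bands: tuple[tuple[float, float], ...] = DEFAULT_EXCLUDE_BANDS,
) -> PowerLawFit:
    """Fit PSD ∝ 1/f^β by OLS of log10(PSD) on log10(f) over a band.

    Frequencies inside any of ``exclude_bands`` are dropped before the
    fit (default: the 4.5–5.5 Hz instrumentation-artifact band), as are
    non-positive PSD values and the DC bin.  Requires at least 10 usable
    frequency points.  β = −slope.
    """
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi) & (spec.freqs > 0)
    for (xlo, xhi) in exclude_bands or ():
        mask &= ~((spec.freqs >= xlo) & (spec.freqs <= xhi))
    mask &= spec.values > 0
    if mask.sum() < 10:
        raise ValueError("fewer than 10 usable frequency points in the fit band")
    logf = np.log10(spec.freqs[mask])
    logp = np.log10(spec.values[mask])
    res = sstats.linregress(logf, logp)
    r2 = float(res.rvalue**2)
    return PowerLawFit(
        exponent=float(-res.slope), slope=float(res.slope),
        intercept=float(res.intercept), fit_band=(lo, hi), r2=r2,
        stderr=float(res.stderr), n_points=int(mask.sum()),
        ok=bool(np.isfinite(res.slope)),
    )


_COLOUR_CENTRES = (("white", 0.0), ("pink", 1.0), ("brown", 2.0), ("black", 3.0))


def classify_noise(
    beta: float,
    window: float = 0.25,
    reddened_range: tuple[float, float] = (0.5, 1.5),
) -> str:
    """Noise-colour name for a PSD exponent β.

    ``white``/``pink``/``brown``/``black`` when β is within ``window`` of
    0/1/2/3; otherwise ``reddened`` when β lies in ``reddened_range``
    (long-range-correlated but off the pink centre); otherwise ``other``.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    for name, centre in _COLOUR_CENTRES:
        if abs(beta - centre) <= window:
            return name
    if reddened_range[0] <= beta <= reddened_range[1]:
        return "reddened"
    return "other"


def is_reddened(beta: float, reddened_range: tuple[float, float] = (0.5, 1.5)) -> bool:
    """Whether β falls in the reddened-noise range (0.5–1.5 by default)."""
    return bool(reddened_range[0] <= beta <= reddened_range[1])


def cwt_scalogram(
    rec: Recording,
    wavelet: str = "morl",
    n_scales: int = 64,
    freq_range: tuple[float, float] | None = None,
) -> Scalogram:
    """Continuous wavelet transform magnitude on log-spaced frequencies.

    Scales are chosen so the wavelet pseudo-frequencies cover
    ``freq_range`` (default: from ~4 cycles per record up to fs/4)
    logarithmically with ``n_scales`` steps; Morlet by default.
    """
    dt = 1.0 / rec.fs
    if freq_range is None:
        freq_range = (max(4.0 / rec.duration_s, 1e-6), rec.fs / 4.0)
    lo, hi = freq_range
    if not (0 < lo < hi <= rec.fs / 2):
        raise ValueError("freq_range must satisfy 0 < lo < hi <= fs/2")
    target = np.geomspace(hi, lo, n_scales)
    fc = pywt.central_frequency(wavelet)
    scales = fc / (target * dt)
    coefs, freqs = pywt.cwt(rec.samples, scales, wavelet, sampling_period=dt)
    return Scalogram(
        frequencies=np.asarray(freqs), times=rec.times,
        magnitude=np.abs(coefs), wavelet=wavelet,
    )
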
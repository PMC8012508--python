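"""Complexity measures: approximate entropy, sample entropy, multiscale
entropy, and the power-law exponent μ of the voltage-magnitude PDF tail.

Approximate entropy (ApEn) quantifies the regularity of a time series:
0 for deterministic (e.g. constant or strictly periodic sampled exactly)
dynamics, larger for irregular ones.  Multiscale entropy evaluates the
same statistic on coarse-grained versions of the series (non-overlapping
block means of length s) and separates genuinely complex signals from
uncorrelated noise: for white noise the entropy falls monotonically with
scale, while for strongly correlated low-complexity signals (brown noise)
it rises.

Neighbour counting is O(N²); the kernels below are numba-compiled with a
chunked pure-numpy fallback, and both agree exactly with the textbook
double-loop definition (which the test suite re-implements as an oracle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .io import Recording
from .spectral import PowerLawFit

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "ComplexityProfile",
    "apen",
    "sampen",
    "coarse_grain",
    "multiscale_entropy",
    "pdf_tail_fit",
]


@dataclass(frozen=True)
class ComplexityProfile:
    """Entropy per coarse-graining scale s = 1..S with its parameters."""

    scales: np.ndarray
    values: np.ndarray
    m: int
    r_coef: float
    r_abs: float
    variant: str  # "apen" or "sampen"


# ---------------------------------------------------------------------------
# neighbour-count kernels


def _phi_numpy(x: np.ndarray, m: int, r: float) -> float:
    nm = x.size - m + 1
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    log_counts = np.empty(nm)
    chunk = max(1, int(2e7 // max(nm * m, 1)))
    for s in range(0, nm, chunk):
        d = np.abs(emb[s : s + chunk, None, :] - emb[None, :, :]).max(axis=-1)
        log_counts[s : s + chunk] = np.log((d <= r).sum(axis=1) / nm)
    return float(log_counts.mean())


def _sampen_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    nt = x.size - m  # templates that admit an (m+1)-extension
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    a = b = 0
    chunk = max(1, int(2e7 // max(nt * (m + 1), 1)))
    for s in range(0, nt, chunk):
        dm = np.abs(emb_m[s : s + chunk, None, :] - emb_m[None, :, :]).max(axis=-1)
        dm1 = np.abs(emb_m1[s : s + chunk, None, :] - emb_m1[None, :, :]).max(axis=-1)
        match_m = dm <= r
        match_m1 = dm1 <= r
        for i_local in range(match_m.shape[0]):
            i = s + i_local
            b += int(match_m[i_local, i + 1 :].sum())
            a += int(match_m1[i_local, i + 1 :].sum())
    return a, b


if _HAVE_NUMBA:

    @njit(cache=False, fastmath=False)
    def _phi_numba(x, m, r):  # pragma: no cover - compiled
        n = x.shape[0]
        nm = n - m + 1
        total = 0.0
        for i in range(nm):
            count = 0
            for j in range(nm):
                d = 0.0
                ok = True
                for k in range(m):
                    diff = abs(x[i + k] - x[j + k])
                    if diff > d:
                        d = diff
                    if d > r:
                        ok = False
                        break
                if ok:
                    count += 1
            total += np.log(count / nm)
        return total / nm

    @njit(cache=False, fastmath=False)
    def _sampen_numba(x, m, r):  # pragma: no cover - compiled
        n = x.shape[0]
        nt = n - m
        a = 0
        b = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                d = 0.0
                ok = True
                for k in range(m):
                    diff = abs(x[i + k] - x[j + k])
                    if diff > d:
                        d = diff
                    if d > r:
                        ok = False
                        break
                if ok:
                    b += 1
                    diff = abs(x[i + m] - x[j + m])
                    if diff > d:
                        d = diff
                    if d <= r:
                        a += 1
        return a, b


def _phi(x: np.ndarray, m: int, r: float) -> float:
    if _HAVE_NUMBA:
        return float(_phi_numba(x, m, r))
    return _phi_numpy(x, m, r)


def _samples(x) -> np.ndarray:
    if isinstance(x, Recording):
        return x.samples
    return np.asarray(x, dtype=np.float64)


def _resolve_r(x: np.ndarray, r: float | None, r_coef: float) -> float:
    if r is None:
        r = r_coef * float(np.std(x))
    if not (r > 0):
        raise ValueError("tolerance r must be positive")
    return float(r)


def apen(series, m: int = 2, r: float | None = None, r_coef: float = 0.2) -> float:
    """Approximate entropy ApEn(m, r) in nats (Pincus definition).

    Φ^m(r) − Φ^{m+1}(r) with Chebyshev template distance and self-matches
    included.  ``r`` is an absolute tolerance in µV; when omitted it is
    ``r_coef`` times the series standard deviation (the literature-standard
    r = 0.2·SD with m = 2).  A constant series has ApEn exactly 0.
    """
    x = _samples(series)
    if x.size < m + 2:
        raise ValueError("series too short for the requested embedding dimension")
    r = _resolve_r(x, r, r_coef)
    return _phi(x, m, r) - _phi(x, m + 1, r)


def sampen(series, m: int = 2, r: float | None = None, r_coef: float = 0.2) -> float:
    """Sample entropy −log(A/B) in nats (self-matches excluded).

    B counts matching template pairs of length m (over the templates that
    admit an extension), A those still matching at length m + 1.  A
    constant series gives 0 (A = B); if no template pairs match, NaN is
    returned with a warning.
    """
    x = _samples(series)
    if x.size < m + 2:
        raise ValueError("series too short for the requested embedding dimension")
    r = _resolve_r(x, r, r_coef)
    if _HAVE_NUMBA:
        a, b = _sampen_numba(x, m, r)
    else:
        a, b = _sampen_numpy(x, m, r)
    if b == 0 or a == 0:
        warnings.warn("sample entropy undefined: no matching templates")
        return float("nan")
    return float(-np.log(a / b))


def coarse_grain(series, s: int) -> np.ndarray:
    """Coarse-grained series at scale s: non-overlapping block means.

    Output length is floor(n / s); s = 1 returns the series unchanged.
    """
    x = _samples(series)
    if s < 1:
        raise ValueError("scale must be >= 1")
    if s > x.size:
        raise ValueError("scale exceeds the series length")
    nblocks = x.size // s
    return x[: nblocks * s].reshape(nblocks, s).mean(axis=1)


def multiscale_entropy(
    rec,
    m: int = 2,
    r_coef: float = 0.2,
    S: int = 50,
    variant: str = "apen",
    max_n: int = 20000,
    r_mode: str = "scale1",
) -> ComplexityProfile:
    """Entropy of the coarse-grained series at scales s = 1..S.

    The tolerance r is fixed from the scale-1 standard deviation
    (r = r_coef · SD₁, the Costa convention) unless ``r_mode='per_scale'``.
    Exact neighbour counting is quadratic in length, so series longer
    than ``max_n`` samples are reduced to a centred sub-window of that
    length before coarse-graining.  Scales too short for the embedding
    (fewer than 10·2^m points) are truncated with a warning.
    """
    if variant not in ("apen", "sampen"):
        raise ValueError("variant must be 'apen' or 'sampen'")
    if r_mode not in ("scale1", "per_scale"):
        raise ValueError("r_mode must be 'scale1' or 'per_scale'")
    x = _samples(rec)
    if x.size > max_n:
        start = (x.size - max_n) // 2
        x = x[start : start + max_n]
    min_len = 10 * 2**m
    s_max = min(S, max(x.size // min_len, 1))
    if s_max < S:
        warnings.warn(
            f"series too short for S={S}; truncating the profile at s={s_max}"
        )
    sd1 = float(np.std(x))
    constant = sd1 == 0
    r_abs = 0.0 if constant else r_coef * sd1
    fn = apen if variant == "apen" else sampen
    scales = np.arange(1, s_max + 1)
    values = np.empty(s_max)
    for idx, s in enumerate(scales):
        cg = coarse_grain(x, int(s))
        if constant:
            values[idx] = 0.0
            continue
        r = r_abs if r_mode == "scale1" else r_coef * float(np.std(cg))
        if r == 0:
            values[idx] = 0.0
            continue
        values[idx] = fn(cg, m=m, r=r)
    return ComplexityProfile(
        scales=scales, values=values, m=m, r_coef=r_coef,
        r_abs=r_abs, variant=variant,
    )


def _loglog_ols(logx: np.ndarray, logy: np.ndarray, band, min_points: int,
                span_ok: bool) -> PowerLawFit:
    res = sstats.linregress(logx, logy)
    r2 = float(res.rvalue**2)
    return PowerLawFit(
        exponent=float(-res.slope), slope=float(res.slope),
        intercept=float(res.intercept), fit_band=band, r2=r2,
        stderr=float(res.stderr), n_points=logx.size,
        ok=bool(r2 >= 0.9 and logx.size >= 5 and span_ok),
    )


def pdf_tail_fit(
    rec,
    tail_quantile: float = 0.90,
    n_bins: int = 60,
    min_count: int = 5,
) -> PowerLawFit:
    """Power-law exponent μ of the PDF tail of |ΔV|: f(|ΔV|) ∝ |ΔV|^−μ.

    The series is centred, magnitudes are histogrammed on log-spaced bins
    (geometric bin centres) and normalised to a density; log10(density)
    is regressed on log10(|ΔV|) over the bins above the ``tail_quantile``
    of |ΔV|.  μ = −slope.  Bins holding fewer than ``min_count`` events
    are dropped: near-empty far-tail bins survive only when their count
    fluctuates high, which would otherwise flatten the fitted slope.
    The ``ok`` flag requires a good straight-line
    fit (r² ≥ 0.9), at least 5 tail bins, and a fitted tail spanning at
    least a factor 3 in |ΔV| (steep μ ≈ 4–5 tails cover less than a
    decade, but a Gaussian tail spans well under 3×) — light-tailed data
    fail the gate, flagging series whose PDF fits no power law.
    """
    if not (0.5 <= tail_quantile < 1.0):
        raise ValueError("tail_quantile must be in [0.5, 1)")
    x = _samples(rec)
    # trimmed-mean centring: a single extreme spike can drag the plain mean
    # far from the baseline and wreck every magnitude below it
    a = np.abs(x - sstats.trim_mean(x, 0.01))
    a = a[a > 0]
    if a.size < 100:
        raise ValueError("too few non-zero magnitudes for a tail fit")
    lo = float(np.quantile(a, 0.5))
    hi = float(a.max())
    if not (lo > 0 and hi > lo):
        raise ValueError("degenerate magnitude range")
    edges = np.geomspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    widths = np.diff(edges)
    centres = np.sqrt(edges[:-1] * edges[1:])
    density = counts / (a.size * widths)
    threshold = float(np.quantile(a, tail_quantile))
    sel = (centres >= threshold) & (counts >= max(min_count, 1))
    if sel.sum() < 3:
        raise ValueError("too few populated tail bins for a fit")
    span_ok = bool(centres[sel].max() / centres[sel].min() >= 3.0)
    return _loglog_ols(
        np.log10(centres[sel]), np.log10(density[sel]),
        band=(threshold, hi), min_points=5, span_ok=span_ok,
    )
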
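"""Synthetic electrome generator.

Real EPG recordings of dodder twigs show three statistical ingredients that
the analysis stack in this package is designed to quantify:

* a pink-like baseline, i.e. colored noise with power spectral density
  PSD ∝ 1/f^β and β around 1.2;
* slow "undulation" waves after a stimulus — long-period oscillations of
  the voltage around its mean;
* rare, high-amplitude spikes whose amplitude distribution is heavy
  tailed (PDF tail ∝ |ΔV|^−μ with μ around 4–5).

The generators here compose those ingredients into labelled recordings so
that every stage of the pipeline (spectral exponents, entropy, correlation
time, classification) can be exercised and verified against known ground
truth.  All generators are seed-deterministic and length-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .io import Recording

__all__ = [
    "SynthesisConfig",
    "gen_colored_noise",
    "gen_brownian",
    "gen_undulation",
    "gen_spikes",
    "gen_from_config",
    "gen_experiment",
    "default_experiment_configs",
]


@dataclass(frozen=True)
class SynthesisConfig:
    """Parameters for one synthetic recording class.

    beta : spectral exponent of the colored-noise baseline (PSD ∝ 1/f^beta)
    n, fs : length in samples and sampling rate in Hz
    undulation_amp : RMS of the slow waves relative to the baseline RMS
    undulation_band : (f_lo, f_hi) in Hz for the slow-wave frequencies
    spike_rate : Poisson rate of spike events, events per second
    spike_tail_mu : PDF tail exponent of the spike peak amplitudes (> 1)
    """

    beta: float = 1.2
    n: int = 16384
    fs: float = 62.5
    undulation_amp: float = 0.0
    undulation_band: tuple[float, float] = (0.002, 0.02)
    undulation_components: int = 5
    spike_rate: float = 0.0
    spike_tail_mu: float = 4.5

    def __post_init__(self) -> None:
        lo, hi = self.undulation_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("undulation_band must satisfy 0 < f_lo < f_hi < fs/2")
        if self.beta < 0 or self.undulation_amp < 0 or self.spike_rate < 0:
            raise ValueError("beta, undulation_amp and spike_rate must be >= 0")
        if self.spike_tail_mu <= 1:
            raise ValueError("spike_tail_mu must exceed 1")


def _standardise(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardise a constant series")
    return x / sd


def gen_colored_noise(
    beta: float, n: int, fs: float = 62.5, seed: int | None = None
) -> Recording:
    """Colored noise with PSD ∝ 1/f^beta by Fourier spectral synthesis.

    Fourier amplitudes are set proportional to f^(−beta/2) with i.i.d.
    uniform phases and zero DC, inverse-transformed, and standardised to
    mean 0 / variance 1.  beta = 0 gives white noise, 1 pink, 2 brown,
    3 black.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if n < 16:
        raise ValueError("n must be >= 16")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1]  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    return Recording(samples=_standardise(x), fs=fs, plant_id=f"noise-beta{beta:g}")


def gen_brownian(n: int, fs: float = 62.5, seed: int | None = None) -> Recording:
    """Brownian-motion-like series: cumulative sum of Gaussian increments.

    Its PSD falls off as 1/f^2 (brown noise).  Standardised to mean 0,
    variance 1.
    """
    if n < 16:
        raise ValueError("n must be >= 16")
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.standard_normal(n))
    return Recording(samples=_standardise(x), fs=fs, plant_id="brownian")


def gen_undulation(
    base: Recording,
    amp: float,
    band: tuple[float, float] = (0.002, 0.02),
    n_components: int = 5,
    seed: int | None = None,
) -> Recording:
    """Superimpose slow undulation waves on a base recording.

    Adds ``n_components`` sinusoids with frequencies drawn uniformly in
    ``band`` (Hz) and random phases, scaled so the total RMS of the added
    waves equals ``amp`` times the RMS of the (centred) base.  ``amp = 0``
    returns the base unchanged.
    """
    lo, hi = band
    if not (0 < lo < hi < base.fs / 2):
        raise ValueError("band must satisfy 0 < f_lo < f_hi < fs/2")
    if amp < 0:
        raise ValueError("amp must be >= 0")
    if amp == 0:
        return base.with_samples(base.samples.copy())
    rng = np.random.default_rng(seed)
    t = base.times
    base_rms = np.sqrt(np.mean((base.samples - base.samples.mean()) ** 2))
    a = amp * base_rms * np.sqrt(2.0 / n_components)
    wave = np.zeros(base.n)
    for _ in range(n_components):
        f = rng.uniform(lo, hi)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        wave += a * np.sin(2.0 * np.pi * f * t + phi)
    wave -= wave.mean()  # slow waves oscillate around the mean, not shift it
    return base.with_samples(base.samples + wave)


def _spike_kernel(fs: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Biexponential transient normalised to unit peak amplitude."""
    length = max(int(round(6.0 * decay_s * fs)), 2)
    t = np.arange(length) / fs
    g = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = g.max()
    if peak <= 0:
        raise ValueError("degenerate spike kernel; need rise_s < decay_s")
    return g / peak


def gen_spikes(
    base: Recording,
    rate: float,
    tail_mu: float,
    seed: int | None = None,
    rise_s: float = 0.2,
    decay_s: float = 2.0,
) -> Recording:
    """Add Poisson-timed biexponential spikes with Pareto peak amplitudes.

    Peak amplitudes follow a power-law PDF ∝ a^−tail_mu for a ≥ 1 (in
    units of the base standard deviation), so the PDF tail fit of the
    output recovers ``tail_mu``.  ``rate`` is in events per second;
    ``rate = 0`` returns the base unchanged.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if tail_mu <= 1:
        raise ValueError("tail_mu must exceed 1")
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate * base.duration_s)
    if n_events == 0:
        return base.with_samples(base.samples.copy())
    positions = np.sort(rng.integers(0, base.n, size=n_events))
    # 1 + Lomax(mu - 1) has PDF (mu-1) a^-mu on a >= 1: tail exponent mu
    amplitudes = (1.0 + rng.pareto(tail_mu - 1.0, size=n_events)) * base.samples.std()
    kernel = _spike_kernel(base.fs, rise_s, decay_s)
    out = base.samples.copy()
    for pos, a in zip(positions, amplitudes):
        seg = min(kernel.size, base.n - pos)
        out[pos : pos + seg] += a * kernel[:seg]
    return base.with_samples(out)


def gen_from_config(cfg: SynthesisConfig, seed: int | None = None) -> Recording:
    """Compose baseline noise, undulation and spikes from one config."""
    ss = np.random.SeedSequence(seed)
    s_noise, s_und, s_spk = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    rec = gen_colored_noise(cfg.beta, cfg.n, cfg.fs, seed=s_noise)
    rec = gen_undulation(
        rec,
        cfg.undulation_amp,
        cfg.undulation_band,
        cfg.undulation_components,
        seed=s_und,
    )
    rec = gen_spikes(rec, cfg.spike_rate, cfg.spike_tail_mu, seed=s_spk)
    return rec


def default_experiment_configs(
    n: int = 16384, fs: float = 62.5
) -> dict[str, SynthesisConfig]:
    """Default class configurations emulating the before/after host design.

    The two *before* classes share one configuration (mildly undulating
    pink-like noise, sparse heavy-tailed spikes) and differ only by seed.
    ``CB-after`` (viable host, bean) departs strongly: large undulation
    amplitude, which lowers entropy and raises the correlation time;
    ``CW-after`` (unviable host, wheat) departs intermediately and with a
    higher spectral exponent, mirroring the direction (not the values) of
    the reported treatment effects.
    """
    before = SynthesisConfig(
        beta=1.2, n=n, fs=fs, undulation_amp=0.15, spike_rate=0.02, spike_tail_mu=4.5
    )
    return {
        "CB-before": before,
        "CB-after": replace(before, undulation_amp=2.0, spike_rate=0.1),
        "CW-before": before,
        "CW-after": replace(before, undulation_amp=0.9, beta=1.4, spike_rate=0.05),
    }


_CLASS_LABELS = {
    "CB-before": ("bean", "before"),
    "CB-after": ("bean", "after"),
    "CW-before": ("wheat", "before"),
    "CW-after": ("wheat", "after"),
}


def gen_experiment(
    configs: Mapping[str, SynthesisConfig] | Sequence[tuple[str, SynthesisConfig]] | None = None,
    n_per_class: int = 5,
    seed: int | None = None,
    n: int = 16384,
    fs: float = 62.5,
) -> dict[str, list[Recording]]:
    """Generate a labelled set of synthetic recordings, one list per class.

    Per-recording seeds are derived deterministically from the master
    ``seed``.  Class names of the form ``CB-before`` etc. get treatment
    and phase labels attached; other names are labelled ``synthetic``.
    """
    if configs is None:
        configs = default_experiment_configs(n=n, fs=fs)
    items = list(configs.items()) if isinstance(configs, Mapping) else list(configs)
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names")
    if len(names) < 2:
        raise ValueError("need at least 2 classes")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(items) * n_per_class)
    out: dict[str, list[Recording]] = {}
    k = 0
    for name, cfg in items:
        treatment, phase = _CLASS_LABELS.get(name, ("synthetic", "none"))
        recs = []
        for i in range(n_per_class):
            child = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            rec = gen_from_config(cfg, seed=child)
            recs.append(
                replace(
                    rec,
                    plant_id=f"{name}-{i}",
                    treatment=treatment,
                    phase=phase,
                    channel=1,
                )
            )
        out[name] = recs
    return out
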
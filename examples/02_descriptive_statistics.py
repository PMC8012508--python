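"""Descriptive statistics and the correlation time of a recording.

The average correlation time L (in samples) summarises how persistent a
signal is: white noise has L ~ 1, while slow undulation waves push L
into the hundreds — the signature seen after a plant detects a host.
"""

from electrome import (
    acf,
    correlation_time,
    dispersion,
    gen_colored_noise,
    gen_undulation,
    mean_voltage,
)

base = gen_colored_noise(beta=0.5, n=2**14, fs=62.5, seed=10)
stimulated = gen_undulation(base, amp=2.0, band=(0.002, 0.02), seed=11)

for name, rec in [("before", base), ("after", stimulated)]:
    d = dispersion(rec)
    L = correlation_time(acf(rec, max_lag=2000))
    print(
        f"{name:>7}: mean={mean_voltage(rec):+.3f} uV  sd={d.sd:.3f}  "
        f"skew={d.skewness:+.3f}  kurt={d.kurtosis:.2f}  "
        f"L={L.samples:.1f} samples ({L.seconds:.1f} s)"
    )

# L jumps from ~14 to ~540 samples once the slow waves are present,
# while the moment statistics barely move: persistence, not amplitude,
# is what distinguishes the stimulated state.
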
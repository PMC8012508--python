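"""Build a synthetic electrome recording from its three ingredients.

A realistic EPG baseline is pink-like 1/f^1.2 noise; after a stimulus,
slow undulation waves and heavy-tailed voltage spikes appear on top of
it.  This script composes the three layers and prints how each changes
the standard deviation and the mean.
"""

from electrome import gen_colored_noise, gen_spikes, gen_undulation

base = gen_colored_noise(beta=1.2, n=2**15, fs=62.5, seed=1)
waved = gen_undulation(base, amp=2.0, band=(0.002, 0.02), seed=2)
spiky = gen_spikes(waved, rate=0.1, tail_mu=4.5, seed=3)

for name, rec in [("baseline", base), ("+undulation", waved), ("+spikes", spiky)]:
    print(
        f"{name:>12}: n={rec.n}, mean={rec.samples.mean():+.3f} uV, "
        f"sd={rec.samples.std():.3f} uV"
    )

# The baseline is standardised (mean 0, sd 1).  Undulation roughly
# triples the sd (amp=2 adds waves with twice the baseline RMS); the
# positive-going spikes raise both the sd and the mean.
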
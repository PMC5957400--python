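"""The strict-clock likelihood-ratio test on simulated genes.

For each gene the ML score is computed with free branch lengths (2n-3
parameters) and under a clock constraint (n-1 node heights); twice the
difference is referred to chi-square with n-2 degrees of freedom.
"""

import numpy as np

import geneshop as gs
from geneshop.likelihood import jc

rng = np.random.default_rng(1)
chronogram = gs.rescale_height(gs.simulate_yule(8, 1.0, seed=rng), 0.5)

conditions = {
    "strict clock": gs.RateDecoration("strict"),
    "noisy clock (sd 0.25)": gs.RateDecoration("noisy_clock", noise_sd=0.25),
    "UCLN (stdev_log 1.0)": gs.RateDecoration("ucln", mean_log=-0.5, stdev_log=1.0),
}

for name, deco in conditions.items():
    phylogram = gs.apply_rates(chronogram, deco, rng=rng)
    alignment = gs.simulate_alignment(phylogram, jc(), 1500, seed=rng)
    res = gs.clock_lrt(alignment, chronogram, jc())
    verdict = "REJECT clock" if res.rejected else "keep clock"
    print(
        f"{name:24s} statistic={res.statistic:8.3f}  df={res.df}  "
        f"p={res.p_value:.4f}  -> {verdict}"
    )

print()
print("Clock-like data should rarely be rejected at alpha=0.05, while data")
print("with strong branch-rate heterogeneity yields large statistics and")
print("tiny p-values.")
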
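"""Size factors, the dispersion trend and the variance-stabilizing transform.

Median-of-ratios size factors absorb library-size differences; the
method-of-moments dispersion trend alpha(mu) = a0 + a1/mu feeds the
closed-form VST, which makes the variance of transformed counts roughly
independent of the mean (a prerequisite for the Gaussian LMM route).
"""

import numpy as np

from longde import (
    StudyDesign,
    draw_gene_params,
    fit_dispersion_trend,
    median_ratio_size_factors,
    simulate_dataset,
    vst_transform,
)

design = StudyDesign.balanced(5)
params = draw_gene_params(2000, seed=10)
counts = simulate_dataset(params, design, seed=11)

sf = median_ratio_size_factors(counts.counts)
print("size factor range: %.3f - %.3f (geometric mean 1)" % (sf.min(), sf.max()))

trend = fit_dispersion_trend(counts.counts, sf)
print(f"fitted dispersion trend: alpha(mu) = {trend.a0:.4f} + {trend.a1:.2f}/mu")

vst = vst_transform(counts.counts, sf, trend)
mu = (counts.counts / sf).mean(axis=1)
lo, hi = mu < np.quantile(mu, 0.3), mu > np.quantile(mu, 0.7)
print("variance of raw counts, low vs high expression: %.1f vs %.1f"
      % (counts.counts[lo].var(axis=1).mean(), counts.counts[hi].var(axis=1).mean()))
print("variance of VST values,  low vs high expression: %.3f vs %.3f"
      % (vst[lo].var(axis=1).mean(), vst[hi].var(axis=1).mean()))
# After the VST the two variance scales are comparable, so a single
# Gaussian error variance per gene is a reasonable model.
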
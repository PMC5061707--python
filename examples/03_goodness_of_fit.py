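"""Goodness of fit of the fitted log-logistic model.

Computes the Kolmogorov-Smirnov distance between the empirical CDF of the
bladder-cancer data and the fitted model, plus the Q-Q and P-P point sets
that would feed the usual diagnostic plots.
"""

import numpy as np

from llsurv import fit_mle, ks_test, load_bladder_fixture, pp_points, qq_points

sample = load_bladder_fixture()
fit = fit_mle(sample)

gof = ks_test(sample, fit.params)
print(f"K-S distance D = {gof.ks_D:.8f}")
print(f"asymptotic significance = {gof.ks_pvalue:.3f}")
print("A large significance value (>> 0.05) means the empirical and fitted "
      "CDFs are statistically indistinguishable at this sample size.\n")

qq = qq_points(sample, fit.params)
r = np.corrcoef(qq["theoretical"], qq["observed"])[0, 1]
print(f"Q-Q correlation (theoretical vs observed quantiles): {r:.4f}")

pp = pp_points(sample, fit.params)
dev = np.max(np.abs(pp["fitted"] - pp["position"]))
print(f"P-P maximum deviation from the 45-degree line: {dev:.4f}")
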
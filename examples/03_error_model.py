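"""Fit the time-value error model and benchmark its variance estimates.

Simulates duplicate noisy timecourses for a subset of the catalog,
fits the global error model in both modes, and compares the predicted
per-point variances with the empirical truth from many noise draws.
"""

import numpy as np
from scipy.stats import pearsonr

from grslogic import NoiseConfig, build_panel, empirical_variance, \
    fit_global_error_params, generate_noisy_dataset, total_variance
from grslogic.benchmarks import reference_catalog
from grslogic.enumeration import GRSCatalog

retained = reference_catalog().retained()
subset = GRSCatalog(retained.entries[::4], provenance="example")  # 24 GRSs
panel = build_panel("amplitude26")

data = generate_noisy_dataset(subset, panel, 2, noise=NoiseConfig(), seed=7)
truth = empirical_variance(
    generate_noisy_dataset(subset, panel, 500, seed=1007).values)

for mode in ("time_value", "conventional"):
    params, stats = fit_global_error_params(data.values, data.timepoints,
                                            mode=mode)
    est = np.where(stats.mu <= params.eta, params.sigma_bg2,
                   total_variance(stats.mu, stats.slope, params))
    r = pearsonr(est.ravel(), truth.ravel())[0]
    print(f"{mode:12s} sigma_bg2={params.sigma_bg2:7.3f} "
          f"alpha2={params.alpha2:7.4f} sigma_t2={params.sigma_t2:6.1f}  "
          f"r(truth) = {r:.3f}")

raw = empirical_variance(data.values)
print(f"{'raw 2-rep':12s} {'':40s} r(truth) = "
      f"{pearsonr(raw.ravel(), truth.ravel())[0]:.3f}")
print("\nThe slope^2 * sigma_t^2 term recovers the timing-driven variance at"
      "\nsteep timepoints that a mean-only (conventional) trend misses.")
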
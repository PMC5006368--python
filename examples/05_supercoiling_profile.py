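"""Reconstruct the DNA supercoiling dip around oriented binding sites.

Simulates psoralen (bTMP) microarray probe intensities with a planted
Gaussian dip (depth -0.5, sigma 300 bp) at feature centers, assigns each
probe to its nearest oriented feature, bins signed distances by 100 bp,
takes per-bin medians, smooths with a rolling mean (window 10, step 2)
and compares against uniformly re-drawn random feature sets.
"""

import numpy as np

from triplesite import supercoiling_profile
from triplesite.simulate import (
    SimulationConfig,
    plant_uniform_features,
    simulate_probes,
)

config = SimulationConfig(seed=6, n_sites=2000, genome={"chrS": 4_000_000})
features = plant_uniform_features(config)
probes = simulate_probes(config, features)

profile = supercoiling_profile(probes, features, config.genome, seed=7)

i = int(np.argmin(profile.smooth_values))
print(f"Probes used: {len(probes)}, bins: {profile.bin_centers.size}")
print(f"Smoothed minimum: {profile.smooth_values[i]:.3f} "
      f"at {profile.smooth_centers[i]:+.0f} bp from the feature")
print(f"KS test vs random background: p = {profile.ks_pvalue:.3g}")
print()
print("Negative bTMP log-ratios mean less psoralen intercalation, i.e. less")
print("negative supercoiling; the trough at the feature center recovers the")
print("planted dip, and the KS test rejects the random-placement control.")
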
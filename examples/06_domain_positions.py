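"""Locate binding sites within topological domains (TADs).

Simulates a domain tiling of the genome with half of the sites re-placed
within 10% of domain borders, computes each site's relative position
(0 = 5' border, 0.5 = center, 1 = 3' border) and quantifies border
enrichment as the edge-vs-center density ratio.
"""

import numpy as np

from triplesite import border_enrichment, relative_domain_position
from triplesite.simulate import SimulationConfig, plant_sites, simulate_domains

config = SimulationConfig(seed=8, n_sites=2000, genome={"chrS": 4_000_000})
sites = plant_sites(config)
domains, placed = simulate_domains(config, sites)

positions = [relative_domain_position(s, domains) for s in placed]
res = border_enrichment(positions)

hist, _ = np.histogram([p for p in positions if p is not None],
                       bins=10, range=(0, 1))
print("Relative-position histogram (10 bins, 0 = 5' border):")
print(" ", " ".join(f"{h:4d}" for h in hist))
print(f"Edge density (outer 10% each side): {res['edge_density']:.2f}")
print(f"Center density (0.45-0.55):         {res['center_density']:.2f}")
print(f"Edge/center ratio:                  {res['ratio']:.1f}")
print()
print("A ratio well above 1 reproduces the border enrichment of co-bound")
print("CTCF/cohesin/TOP2B sites at topological domain boundaries.")
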
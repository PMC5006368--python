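"""Call exonuclease-protection footprints from ChIP-exo 5'-end pileups.

Simulates strand-specific exo reads whose 5' ends mark planted protection
boundaries (+13..+26 on the forward strand, -27..-13 on the reverse,
relative to the oriented CTCF motif center), builds the permuted-motif
background envelope and calls footprints where the observed pileup
exceeds background mean + 3 sd for at least 3 consecutive bp.
"""

from triplesite import (
    GenomicInterval,
    call_footprints,
    exo_profile,
    permuted_background,
)
from triplesite.simulate import (
    SimulationConfig,
    simulate_exo_reads,
    simulate_genome_and_motifs,
)

config = SimulationConfig(seed=3, n_sites=300, genome={"chrS": 600_000})
sequences, sites = simulate_genome_and_motifs(config)
reads = simulate_exo_reads(config, sites)

observed = exo_profile(reads, sites, flank=50, min_reads=10)
regions = [GenomicInterval("chrS", s.center - 150, s.center + 150) for s in sites]
background = permuted_background(
    reads, regions, config.motif, sequences, n_perm=10, seed=4
)

print(f"Profiled {observed.n_regions} regions, {observed.total_ends():.0f} 5' ends")
for call in call_footprints(observed, background):
    print(
        f"  {call.strand:>7s}-strand protection at offsets "
        f"{call.start_offset:+d} to {call.end_offset:+d} bp"
    )
print()
print("Offsets are bp from the motif center in its G-rich direction; the")
print("reverse-strand footprint 5' of the motif is where TOP2B protects,")
print("the forward-strand footprint 3' of it is where cohesin protects.")
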
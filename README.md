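# triplesite

Analysis toolkit for the genome architecture of combinatorially bound
CTCF / cohesin (RAD21) / topoisomerase IIβ (TOP2B) sites.

In mammalian genomes CTCF binds an asymmetric DNA motif, cohesin co-occupies
many CTCF sites, and TOP2B joins a large fraction of these to form
"triple sites" that concentrate at topological domain (TAD) borders with a
fixed spatial grammar: reading the CTCF motif in its G-rich direction,
TOP2B sits ~15 bp 5′ of the motif center and RAD21 ~12 bp 3′ of it.
`triplesite` implements the analyses that establish and quantify this
organisation, end-to-end, for anyone working with peak calls, tag files,
motif matrices, allelic count tables, probe intensities and domain
intervals:

- **Combinatorial occupancy** — merge ≥1 bp-overlapping peaks of several
  factors and classify every merged region by its occupants
  (`classify_occupancy`), compare signal (RPKM) between classes with
  BH-adjusted one-sided Wilcoxon tests, test overlap enrichment by
  randomisation, tally cross-tissue ("constitutive", shared in >7 tissues)
  and cross-species (mouse only / rodents only / beyond rodents) sharing.
- **Motif scanning and orientation** (`scan`, `best_hit_per_region`) — PWM
  scanning with an order-0/1 Markov background estimated from the scanned
  sequences, exact score p-values by column-wise convolution, per-region
  best hits, and seeded column-permuted control matrices.
- **Directionality** (`site_offsets`, `order_enrichment`) — signed summit
  offsets on the motif-oriented axis, distance summaries before/after
  orientation, ordering classification of the three factors, and Fisher
  tests for the canonical TOP2B–CTCF–RAD21 order.
- **ChIP-exo footprinting** (`exo_profile`, `call_footprints`) — strand
  resolved 5′-end pileups at base-pair resolution around oriented motif
  centers, permuted-motif background envelopes, and footprint-boundary
  calls where protection exceeds background mean + 3 sd.
- **Allele-specific binding** (`classify_bias`, `cobinding_correlation`,
  `group_shift_test`) — exact binomial bias classification of F1-hybrid
  allelic counts against an unbiased 0.5 ratio, allele-frequency
  correlation between co-bound factors, and one-sided Wilcoxon shifts of a
  target factor's frequencies across the anchor factor's bias classes.
- **Supercoiling profiles** (`supercoiling_profile`, `normalize_btmp`) —
  psoralen (bTMP) probe normalisation, signed oriented probe-to-feature
  distances, 100 bp binned medians with a rolling mean, random-feature
  backgrounds and a calibrated Kolmogorov–Smirnov comparison.
- **Domain positions** (`relative_domain_position`, `border_enrichment`) —
  normalized site positions within TADs and edge-vs-center density ratios.
- **Synthetic data with planted truth** (`triplesite.simulate`) — a fully
  seeded generator for every input above (FASTA genome with embedded motif
  instances, narrowPeak/tagAlign files, allelic count tables, probe tables,
  domain tilings), with the ground truth emitted alongside so each analysis
  stage can be validated by recovery.

Standard plain-text formats are supported throughout (`triplesite.io`):
BED3/6, ENCODE narrowPeak, tagAlign, bedGraph, FASTA, TRANSFAC count
matrices. Coordinates are 0-based half-open everywhere.

## Worked example

Each script in `examples/` demonstrates one capability on generated data.

```sh
python examples/02_motif_orientation.py
```

```
factor       mode   n  median   q25   q75
  CTCF   oriented 992     0.0  -4.0   3.0
  CTCF unoriented 992     0.0  -4.0   4.0
 RAD21   oriented 992    12.0   8.0  15.0
 RAD21 unoriented 992    -1.0 -12.0  12.0
 TOP2B   oriented 992   -15.0 -18.0 -12.0
 TOP2B unoriented 992     2.5 -15.0  15.0

Canonical order TOP2B-CTCF-RAD21:
  before orienting motifs: 47.4%
  after  orienting motifs: 94.9%
  Fisher p = 4.04e-134
```

The generator planted TOP2B summits 15 bp 5′ and RAD21 summits 12 bp 3′
of each CTCF motif center. Scanning the simulated genome, anchoring each
site on its best motif hit and signing the summit offsets along the
G-rich axis recovers exactly those medians; without motif orientation the
offsets are symmetric around zero and the factor ordering is at chance
(47%), while orientation reveals the canonical TOP2B–CTCF–RAD21
arrangement in 95% of sites.

Similarly, `examples/03_chip_exo_footprints.py` recovers the planted
exonuclease protection boundaries (forward strand +13..+26, reverse
strand −27..−13 relative to the motif center), and
`examples/04_allele_specific_binding.py` recovers a planted
allele-frequency correlation of 0.4 between CTCF and TOP2B.

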
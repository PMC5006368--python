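"""ChIP-exo 5'-end pileups, permuted backgrounds and footprint calling."""

import numpy as np
import pytest

from triplesite import (
    GenomicInterval,
    OrientedSite,
    Read,
    call_footprints,
    exo_profile,
    five_prime_position,
    permuted_background,
)
from triplesite.exo import BackgroundEnvelope, ExoProfile
from triplesite.simulate import ExoModel, SimulationConfig, simulate_exo_reads


def read_at(chrom, five_prime, strand, length=36):
    if strand == "+":
        return Read(GenomicInterval(chrom, five_prime, five_prime + length, "+"))
    return Read(GenomicInterval(chrom, five_prime - length + 1, five_prime + 1, "-"))


class TestFivePrime:
    def test_plus(self):
        assert five_prime_position(Read(GenomicInterval("c", 100, 136, "+"))) == 100

    def test_minus(self):
        assert five_prime_position(Read(GenomicInterval("c", 100, 136, "-"))) == 135

    def test_single_bp(self):
        assert five_prime_position(Read(GenomicInterval("c", 7, 8, "+"))) == 7
        assert five_prime_position(Read(GenomicInterval("c", 7, 8, "-"))) == 7


class TestProfile:
    def test_single_plus_site(self):
        site = OrientedSite("c", 1000, "+")
        prof = exo_profile([read_at("c", 987, "+")], [site], min_reads=1)
        assert prof.forward[prof.flank - 13] == 1
        assert prof.forward.sum() == 1 and prof.reverse.sum() == 0
        assert prof.n_regions == 1

    def test_minus_site_mirrors_and_swaps_strand(self):
        # same genomic read geometry around a minus-oriented site: the
        # oriented offset flips sign and the strand label swaps
        site = OrientedSite("c", 1000, "-")
        prof = exo_profile([read_at("c", 987, "+")], [site], min_reads=1)
        assert prof.reverse[prof.flank + 13] == 1
        assert prof.forward.sum() == 0

    def test_min_reads_filter_excludes_site(self):
        site_ok = OrientedSite("c", 1000, "+")
        site_low = OrientedSite("c", 100_000, "+")
        reads = [read_at("c", 1000 + i, "+") for i in range(10)]
        reads += [read_at("c", 100_000 + i, "+") for i in range(9)]
        prof = exo_profile(reads, [site_ok, site_low], min_reads=10)
        assert prof.n_regions == 1
        assert prof.total_ends() == 10

    def test_no_site_survives_raises(self):
        site = OrientedSite("c", 1000, "+")
        with pytest.raises(ValueError, match="min_reads"):
            exo_profile([read_at("c", 1000, "+")], [site], min_reads=10)

    def test_count_conservation(self, rng):
        """Sum of profile x n_regions equals the 5' ends inside windows."""
        sites = [
            OrientedSite("c", int(c), "+" if rng.random() < 0.5 else "-")
            for c in rng.integers(500, 100_000, 20)
        ]
        reads = [
            read_at("c", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(400, 100_100, 2000)
        ]
        prof = exo_profile(reads, sites, min_reads=1)
        in_windows = 0
        for s in sites:
            n = sum(
                1 for r in reads if abs(r.five_prime() - s.center) <= 50
            )
            if n >= 1:
                in_windows += n
        assert prof.total_ends() == pytest.approx(in_windows)

    def test_reflection_equivariance(self, rng):
        """Mirroring reads and sites mirrors the profile and swaps strands."""
        L = 50_000
        sites = [OrientedSite("c", 10_000, "+"), OrientedSite("c", 30_000, "-")]
        reads = [
            read_at("c", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(9_900, 30_100, 500)
        ]
        prof = exo_profile(reads, sites, min_reads=1)
        m_sites = [
            OrientedSite("c", L - s.center, "-" if s.orientation == "+" else "+")
            for s in sites
        ]
        m_reads = [
            read_at("c", L - r.five_prime(), "-" if r.strand == "+" else "+")
            for r in reads
        ]
        m_prof = exo_profile(m_reads, m_sites, min_reads=1)
        assert np.array_equal(m_prof.forward, prof.forward)
        assert np.array_equal(m_prof.reverse, prof.reverse)


class TestFootprints:
    def _flat_background(self, flank=50, mean=0.5, sd=0.1):
        w = 2 * flank + 1
        return BackgroundEnvelope(
            *(np.full(w, v) for v in (mean, mean, sd, sd, 0, 0, 1, 1)),
            n_permutations=10,
            flank=flank,
        )

    def test_flat_observed_no_calls(self):
        bg = self._flat_background()
        obs = ExoProfile(np.full(101, 0.5), np.full(101, 0.5), 10)
        assert call_footprints(obs, bg) == []

    def test_single_spike_not_called(self):
        bg = self._flat_background()
        fwd = np.full(101, 0.5)
        fwd[60] = 10.0
        obs = ExoProfile(fwd, np.full(101, 0.5), 10)
        assert call_footprints(obs, bg) == []

    def test_planted_boundaries_recovered(self):
        bg = self._flat_background()
        fwd = np.full(101, 0.5)
        rev = np.full(101, 0.5)
        fwd[50 + 13 : 50 + 27] = 5.0  # offsets +13..+26
        rev[50 - 27 : 50 - 12] = 5.0  # offsets -27..-13
        obs = ExoProfile(fwd, rev, 10)
        calls = {(c.strand, c.start_offset, c.end_offset)
                 for c in call_footprints(obs, bg)}
        assert calls == {("forward", 13, 26), ("reverse", -27, -13)}


class TestPermutedBackground:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=21, n_sites=40, genome={"chrS": 100_000})
        from triplesite.simulate import simulate_genome_and_motifs

        seqs, sites = simulate_genome_and_motifs(cfg)
        reads = simulate_exo_reads(cfg, sites)
        regions = [
            GenomicInterval("chrS", s.center - 120, s.center + 120) for s in sites
        ]
        bg1 = permuted_background(reads, regions, cfg.motif, seqs, n_perm=3, seed=5)
        bg2 = permuted_background(reads, regions, cfg.motif, seqs, n_perm=3, seed=5)
        assert np.array_equal(bg1.mean_forward, bg2.mean_forward)
        assert np.array_equal(bg1.sd_reverse, bg2.sd_reverse)

    def test_uniform_reads_indistinguishable_from_background(self, rng):
        """Reads placed uniformly across regions: observed and permuted
        backgrounds see the same flat rate, so their difference stays
        within Monte-Carlo error at every offset."""
        cfg = SimulationConfig(seed=22, n_sites=60, genome={"chrS": 150_000})
        from triplesite.simulate import simulate_genome_and_motifs

        seqs, sites = simulate_genome_and_motifs(cfg)
        # uniform 5' ends across each region plus margin for window shifts
        reads = []
        for s in sites:
            for p in rng.integers(s.center - 200, s.center + 200, 120):
                reads.append(
                    read_at("chrS", int(p), "+" if rng.random() < 0.5 else "-")
                )
        obs = exo_profile(reads, sites, min_reads=1)
        regions = [
            GenomicInterval("chrS", s.center - 120, s.center + 120) for s in sites
        ]
        bg = permuted_background(
            reads, regions, cfg.motif, seqs, n_perm=20, seed=6, min_reads=1
        )
        lam = obs.total_ends() / (202 * obs.n_regions)  # flat per-bp rate
        for o, m, sd in (
            (obs.forward, bg.mean_forward, bg.sd_forward),
            (obs.reverse, bg.mean_reverse, bg.sd_reverse),
        ):
            # observed Poisson error plus the background-mean MC error
            se = np.sqrt(lam / obs.n_regions + sd**2 / bg.n_permutations + 1e-6)
            assert np.all(np.abs(o - m) < 4 * se)
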
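"""Co-occupancy classification, enrichment and conservation comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

import pandas as pd

from triplesite import (
    GenomicInterval,
    Peak,
    Read,
    classify_occupancy,
    constitutive_classification,
    intensity_by_category,
    overlap_enrichment_test,
    phylo_category_counts,
    summit_repeat_filter,
)
from triplesite.occupancy import fisher_2x2, phylo_category
from triplesite.simulate import SimulationConfig, plant_sites, simulate_peaks


def peak(chrom, start, end, factor="X", summit=None, signal=1.0):
    return Peak(
        GenomicInterval(chrom, start, end),
        summit=summit if summit is not None else (start + end) // 2,
        signal=signal,
        factor=factor,
    )


class TestClassify:
    def test_chained_triple(self):
        sites, table = classify_occupancy(
            {
                "TOP2B": [peak("chr1", 100, 200)],
                "CTCF": [peak("chr1", 150, 250)],
                "RAD21": [peak("chr1", 240, 300)],
            }
        )
        assert len(sites) == 1
        assert sites[0].members == frozenset({"TOP2B", "CTCF", "RAD21"})
        assert table == {"CTCF+RAD21+TOP2B": 1}

    def test_disjoint_singletons(self):
        sites, table = classify_occupancy(
            {"TOP2B": [peak("chr1", 100, 200)], "CTCF": [peak("chr1", 500, 600)]}
        )
        assert table == {"TOP2B": 1, "CTCF": 1}

    def test_invariant_under_factor_order(self, rng):
        cfg = SimulationConfig(seed=11, n_sites=300, genome={"chrS": 600_000})
        peaks, _ = simulate_peaks(cfg, plant_sites(cfg))
        _, t1 = classify_occupancy(peaks)
        _, t2 = classify_occupancy(dict(reversed(list(peaks.items()))))
        assert t1 == t2

    def test_empty_factor_warns_but_is_retained(self):
        with pytest.warns(UserWarning, match="no peaks"):
            _, table = classify_occupancy(
                {"TOP2B": [peak("chr1", 0, 100)], "CTCF": []}
            )
        assert table == {"TOP2B": 1}

    def test_planted_proportions_recovered(self):
        cfg = SimulationConfig(seed=12, n_sites=10_000, genome={"chrS": 16_000_000})
        sites = plant_sites(cfg)
        peaks, truth = simulate_peaks(cfg, sites)
        occ, table = classify_occupancy(peaks)
        assert sum(table.values()) == 10_000
        n = 10_000
        for cls, p in cfg.occupancy_proportions.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(table.get(cls, 0) / n - p) <= 3 * se


class TestIntensity:
    def _reads_at(self, chrom, positions):
        return [
            Read(GenomicInterval(chrom, p, p + 36, "+")) for p in positions
        ]

    def test_identical_groups_fold_one(self):
        # two classes whose peaks receive identical read counts
        peaks = {
            "CTCF": [peak("chr1", 100, 300, "CTCF"), peak("chr1", 10_000, 10_200, "CTCF")],
            "RAD21": [peak("chr1", 100, 300, "RAD21")],
        }
        sites, _ = classify_occupancy(peaks)
        reads = {
            "CTCF": self._reads_at("chr1", [150, 160, 10_050, 10_060]),
            "RAD21": self._reads_at("chr1", [150]),
        }
        values, tests = intensity_by_category(
            sites, reads, {"CTCF": 10**6, "RAD21": 10**6}
        )
        ctcf = values[values.factor == "CTCF"]
        assert ctcf.rpkm.nunique() == 1
        row = tests[(tests.factor == "CTCF")].iloc[0]
        assert row.median_fold_change == pytest.approx(1.0)
        assert row.skipped  # classes of size 1 are flagged, not tested

    def test_planted_fold_change_recovered(self, rng):
        # build two singleton-class groups with a planted 2x median shift
        peaks = {"A": [], "B": []}
        reads = {"A": [], "B": []}
        for i in range(500):
            for factor, offset, lam in (("A", 0, 40), ("B", 2_000_000, 20)):
                start = offset + i * 2000
                peaks[factor].append(peak("chr1", start, start + 1000, factor))
                k = rng.poisson(lam)
                reads[factor].extend(
                    self._reads_at("chr1", [start + 100] * int(k))
                )
        sites, _ = classify_occupancy(peaks)
        values, _ = intensity_by_category(
            sites, reads, {"A": 10**6, "B": 10**6}
        )
        med = values.groupby("factor").rpkm.median()
        assert med["A"] / med["B"] == pytest.approx(2.0, rel=0.10)
        p = sps.mannwhitneyu(
            values[values.factor == "A"].rpkm,
            values[values.factor == "B"].rpkm,
            alternative="greater",
        ).pvalue
        assert p < 0.01


class TestOverlapEnrichment:
    def test_query_equals_reference(self):
        ws = [GenomicInterval("chr1", 0, 100_000)]
        ref = [GenomicInterval("chr1", i * 1000, i * 1000 + 200) for i in range(50)]
        res = overlap_enrichment_test(ref, ref, ws, n_sim=99, seed=0)
        assert res["observed_fraction"] == 1.0
        assert res["pvalue"] == pytest.approx(1 / 100)

    def test_empty_reference(self):
        ws = [GenomicInterval("chr1", 0, 100_000)]
        q = [GenomicInterval("chr1", 0, 100)]
        res = overlap_enrichment_test(q, [], ws, n_sim=99, seed=0)
        assert res["observed_fraction"] == 0.0
        assert res["pvalue"] == 1.0

    def test_workspace_too_small(self):
        ws = [GenomicInterval("chr1", 0, 50)]
        q = [GenomicInterval("chr1", 0, 40), GenomicInterval("chr1", 0, 40)]
        with pytest.raises(ValueError, match="workspace"):
            overlap_enrichment_test(q, q, ws, n_sim=10)

    def test_null_mean_matches_coverage_and_p_valid(self, rng):
        """Reference covering ~10% of the workspace: null mean ~0.1 wrt
        point-ish queries; empirical p is valid (super-uniform)."""
        ws = [GenomicInterval("chr1", 0, 1_000_000)]
        ref = [
            GenomicInterval("chr1", i * 10_000, i * 10_000 + 1000) for i in range(100)
        ]
        res = overlap_enrichment_test(
            [GenomicInterval("chr1", 0, 2)] * 400, ref, ws, n_sim=200, seed=3
        )
        assert res["null_mean"] == pytest.approx(0.10, abs=0.01)
        ps = []
        for rep in range(200):
            q = [
                GenomicInterval("chr1", int(s), int(s) + 300)
                for s in rng.integers(0, 999_000, 30)
            ]
            ps.append(
                overlap_enrichment_test(q, ref, ws, n_sim=99, seed=rep)["pvalue"]
            )
        ps = np.array(ps)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            observed = (ps <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert observed <= alpha + 3 * se


class TestConstitutive:
    def _tissues(self, n, hit):
        return {
            f"t{i}": [GenomicInterval("chr1", 100, 200)] if i < hit else
            [GenomicInterval("chr1", 5000, 5100)]
            for i in range(n)
        }

    def test_more_than_seven_rule(self):
        p = [peak("chr1", 120, 180)]
        assert constitutive_classification(p, self._tissues(14, 8)).constitutive[0]
        assert not constitutive_classification(p, self._tissues(14, 7)).constitutive[0]

    def test_fisher_matches_hypergeometric_oracle(self, rng):
        """Two-sided Fisher p equals the sum of hypergeometric point masses
        no larger than the observed table's, for all small tables."""
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, 4) + 1)
            _, p = fisher_2x2(a, b, c, d)
            n1, n2, k = a + b, c + d, a + c
            rv = sps.hypergeom(n1 + n2, n1, k)
            support = np.arange(max(0, k - n2), min(k, n1) + 1)
            pmf = rv.pmf(support)
            oracle = pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum()
            assert p == pytest.approx(oracle, abs=1e-9)


class TestPhylo:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((True, False, False), "Rodents only"),
            ((False, True, False), "Beyond rodents"),
            ((True, False, True), "Beyond rodents"),
            ((False, False, False), "Mouse only"),
        ],
    )
    def test_category_rules(self, flags, expected):
        assert phylo_category(*flags) == expected

    def test_planted_fraction_difference_detected(self, rng):
        """45% vs 21% beyond-rodents at n=1000 per class is detected at
        p < 1e-6 (directional analog of the conservation contrast)."""
        rows = []
        for cls, frac in (("triple", 0.45), ("double", 0.21)):
            beyond = rng.random(1000) < frac
            for b in beyond:
                rows.append(
                    {
                        "occupancy_class": cls,
                        "rat": bool(rng.random() < 0.5),
                        "human": bool(b),
                        "dog": False,
                    }
                )
        counts, tests = phylo_category_counts(pd.DataFrame(rows))
        assert set(counts.columns) == {
            "Mouse only", "Rodents only", "Beyond rodents"
        }
        assert tests.iloc[0].pvalue < 1e-6


class TestSummitRepeatFilter:
    def test_summit_inside_kept(self):
        p = peak("chr1", 100, 300, summit=150)
        assert summit_repeat_filter([p], [GenomicInterval("chr1", 100, 200)]) == [p]

    def test_summit_outside_dropped(self):
        p = peak("chr1", 50, 300, summit=99)
        assert summit_repeat_filter([p], [GenomicInterval("chr1", 100, 200)]) == []

    def test_matches_linear_scan_oracle(self, rng):
        peaks = []
        for _ in range(200):
            s = int(rng.integers(0, 20_000))
            w = int(rng.integers(50, 300))
            peaks.append(peak("chr1", s, s + w, summit=s + int(rng.integers(w))))
        repeats = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(1, 400)))
            for s in rng.integers(0, 20_000, 100)
        ]
        got = summit_repeat_filter(peaks, repeats)
        oracle = [
            p
            for p in peaks
            if any(r.start <= p.summit < r.end for r in repeats)
        ]
        assert got == oracle
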
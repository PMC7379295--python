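import numpy as np
import pandas as pd
import pytest

from bilmap.bins import bin_genotype_matrix, build_bins
from bilmap.genmap import build_map
from bilmap.qtl import (
    QtlResult,
    ScanConfig,
    anova_scan,
    conserved_qtls,
    hk_dosage,
    hk_scan,
    lod_support_interval,
    regress_lod,
)
from bilmap.sim import SimulationConfig, simulate_population
from bilmap.studies import power_study
from oracles import oracle_hk_dosage


@pytest.fixture(scope="module")
def scan_setup():
    cfg = SimulationConfig(seed=21, n_lines=80, n_chromosomes=4, markers_per_chromosome=60)
    res = simulate_population(cfg)
    bins = build_bins(res.genotypes, res.marker_map, res.chromosome_table)
    bg = bin_genotype_matrix(bins, res.genotypes.index)
    return res, bins, bg


def _phen_from_indicator(bg, bin_id, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = (bg[bin_id] != "A").astype(float) + rng.normal(0, noise, len(bg))
    return pd.DataFrame(
        {
            "line_id": bg.index,
            "trait_id": "t",
            "replicate": 1,
            "value": y + 10.0,
        }
    )


class TestAnovaScan:
    def test_perfect_association_maximizes_lod_at_the_bin(self, scan_setup):
        res, bins, bg = scan_setup
        target = bins[len(bins) // 3]
        # pick a bin with enough donor lines for a clean two-class layout
        while (bg[target.bin_id] != "A").sum() < 3:
            target = bins[bins.index(target) + 1]
        phen = _phen_from_indicator(bg, target.bin_id)
        scan = anova_scan(phen, bg, bins, ScanConfig(threshold_mode="nominal"))
        curves = scan.curves
        peak = curves.loc[curves["lod"].idxmax()]
        assert peak["bin_id"] == target.bin_id
        assert peak["p_value"] <= 1e-12
        assert peak["lod"] > 50

    def test_missing_trait_rejected(self, scan_setup):
        res, bins, bg = scan_setup
        phen = _phen_from_indicator(bg, bins[0].bin_id)
        with pytest.raises(ValueError, match="absent"):
            anova_scan(phen, bg, bins, ScanConfig(threshold_mode="nominal"), traits=["no_such"])

    def test_effect_direction_follows_sign(self, scan_setup):
        res, bins, bg = scan_setup
        target = next(b for b in bins if (bg[b.bin_id] != "A").sum() >= 3)
        phen = _phen_from_indicator(bg, target.bin_id)
        phen["value"] = 20.0 - phen["value"]  # wild allele now decreases the trait
        scan = anova_scan(phen, bg, bins, ScanConfig(threshold_mode="bonferroni"))
        q = next(q for q in scan.qtls if q.bin_id == target.bin_id)
        assert q.effect_direction == "wild_decreases"
        assert q.effect_size < 0

    def test_lod_zero_for_null_fit_and_monotone_in_f(self):
        rng = np.random.default_rng(5)
        x = np.repeat([0.0, 1.0], 20)
        Y = rng.normal(size=(40, 50))
        lod, p, eff, n = regress_lod(Y, x)
        # constant phenotype -> zero LOD
        lod0, _, _, _ = regress_lod(np.ones((40, 1)), x)
        assert lod0[0] == 0.0
        # LOD and p are monotonically (inversely) related
        order_lod = np.argsort(lod)
        order_p = np.argsort(p)[::-1]
        assert np.array_equal(order_lod, order_p)

    def test_permutation_threshold_reproducible(self, scan_setup):
        res, bins, bg = scan_setup
        phen = _phen_from_indicator(bg, bins[0].bin_id, noise=1.0, seed=1)
        a = anova_scan(phen, bg, bins, ScanConfig(n_permutations=100, seed=99))
        b = anova_scan(phen, bg, bins, ScanConfig(n_permutations=100, seed=99))
        assert a.thresholds == b.thresholds


class TestHkScan:
    def test_dosage_matches_path_enumeration(self):
        grid = [0.0, 0.01, 0.1, 0.25, 0.4]
        for l in (0, 1, None):
            for r in (0, 1, None):
                if l is None and r is None:
                    continue
                for r1 in grid:
                    for r2 in grid:
                        if l is not None and r is not None and l != r and r1 == 0 and r2 == 0:
                            continue  # contradictory flanks at zero distance
                        got = hk_dosage(l, r, r1, r2)
                        want = oracle_hk_dosage(l, r, r1, r2)
                        assert got == pytest.approx(want, abs=1e-12)

    def test_midpoint_between_opposite_flanks_is_half(self):
        assert hk_dosage(0, 1, 0.1, 0.1) == pytest.approx(0.5)

    def test_equals_anova_at_bin_positions(self, scan_setup):
        res, bins, bg = scan_setup
        target = next(b for b in bins if (bg[b.bin_id] != "A").sum() >= 3)
        phen = _phen_from_indicator(bg, target.bin_id, noise=0.5, seed=3)
        gmap = build_map(bg, bins)
        cfg = ScanConfig(threshold_mode="nominal", grid_step_cm=0.0)
        a = anova_scan(phen, bg, bins, cfg)
        h = hk_scan(phen, bg, gmap, bins, cfg)
        bin_cm = {}
        for g in gmap.groups:
            bin_cm.update(dict(zip(g.bin_ids, g.cum_cm)))
        hk = h.curves
        at_bins = hk[np.isclose(hk["cm"], hk["bin_id"].map(bin_cm))]
        merged = at_bins.merge(a.curves, on=["trait_id", "bin_id"], suffixes=("_hk", "_anova"))
        merged = merged.dropna(subset=["lod_hk", "lod_anova"])
        assert len(merged) > 10
        np.testing.assert_allclose(merged["lod_hk"], merged["lod_anova"], rtol=1e-9)

    def test_zero_rf_interval_gives_flat_lod(self):
        # two bins split by an H/B difference collapse to the same donor state
        import pandas as pd
        from bilmap.io import ChromosomeTable, MarkerMap

        rows = [(f"m{i + 1}", "c1", 1_000_000 * (i + 1)) for i in range(2)]
        mm = MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"]))
        ct = ChromosomeTable({"c1": 3_000_000})
        calls = ["BH", "BB", "AA", "AA", "BB", "AA"]
        G = pd.DataFrame([list(c) for c in calls], index=[f"L{i}" for i in range(6)],
                         columns=mm.marker_ids)
        bins = build_bins(G, mm, ct)
        assert len(bins) == 2
        bg = bin_genotype_matrix(bins, G.index)
        gmap = build_map(bg, bins)
        assert gmap.total_length_cm == 0.0
        rng = np.random.default_rng(0)
        phen = pd.DataFrame({"line_id": G.index, "trait_id": "t", "replicate": 1,
                             "value": 10 + rng.normal(size=6)})
        h = hk_scan(phen, bg, gmap, bins, ScanConfig(threshold_mode="nominal"))
        lods = h.curves["lod"].to_numpy()
        np.testing.assert_allclose(lods, lods[0])


class TestSupportInterval:
    def test_single_point_spike(self):
        starts = [1, 11, 21, 31, 41]
        ends = [10, 20, 30, 40, 50]
        lods = [0.1, 0.2, 5.0, 0.2, 0.1]
        assert lod_support_interval(starts, ends, lods, 2, 1.0) == (21, 30)

    def test_symmetric_triangle_drop_half_per_bin(self):
        starts = list(range(0, 90, 10))
        ends = [s + 9 for s in starts]
        lods = [1.0, 1.5, 2.0, 2.5, 3.0, 2.5, 2.0, 1.5, 1.0]
        # 1-LOD drop reaches two bins either side of the peak at index 4
        assert lod_support_interval(starts, ends, lods, 4, 1.0) == (starts[2], ends[6])

    def test_flat_curve_spans_whole_extent_with_warning(self, caplog):
        import logging

        starts, ends = [1, 11], [10, 20]
        with caplog.at_level(logging.WARNING):
            iv = lod_support_interval(starts, ends, [2.0, 2.0], 0, 1.0)
        assert iv == (1, 20)
        assert "flat" in caplog.text


class TestConserved:
    def _q(self, trait, exp, chrom, lo, hi):
        return QtlResult(trait, exp, chrom, "b", (lo + hi) // 2, 5.0, 1e-4,
                         "wild_increases", 1.0, lo, hi)

    def test_identical_results_all_conserved(self):
        qs = [self._q("phe", "e1", "c10", 100, 200), self._q("phe", "e2", "c10", 100, 200)]
        (c,) = conserved_qtls(qs)
        assert c.experiment_ids == ("e1", "e2")
        assert (c.start_bp, c.end_bp) == (100, 200)

    def test_disjoint_intervals_not_conserved(self):
        qs = [self._q("phe", "e1", "c10", 100, 200), self._q("phe", "e2", "c10", 300, 400)]
        assert conserved_qtls(qs) == []

    def test_same_experiment_overlap_not_conserved(self):
        qs = [self._q("phe", "e1", "c10", 100, 200), self._q("phe", "e1", "c10", 150, 250)]
        assert conserved_qtls(qs) == []

    def test_chained_overlap_groups_across_three_experiments(self):
        qs = [
            self._q("met", "e1", "c2", 100, 200),
            self._q("met", "e2", "c2", 180, 300),
            self._q("met", "e3", "c2", 280, 400),
            self._q("met", "e3", "c3", 100, 200),  # other chromosome: separate
        ]
        (c,) = conserved_qtls(qs)
        assert c.experiment_ids == ("e1", "e2", "e3")
        assert c.n_qtls == 3


def test_power_increases_with_effect_size():
    """Detection power is monotone over planted effects of 0.25, 0.5, 1 SD."""
    powers = [
        power_study(n_sims=30, effect=e, seed=17).power_pct for e in (0.25, 0.5, 1.0)
    ]
    assert powers[0] <= powers[1] <= powers[2]
    assert powers[2] > powers[0]
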
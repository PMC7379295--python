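import math

import numpy as np
import pandas as pd
import pytest

from bilmap.bins import build_bins, bin_genotype_matrix
from bilmap.genmap import (
    build_map,
    correct_rf_selfing,
    design_rf_corrector,
    distance_to_rf,
    estimate_rf,
    expected_observed_rf,
    map_distance,
)
from bilmap.io import ChromosomeTable, MarkerMap
from bilmap.sim import SimulationConfig, simulate_population
from bilmap.studies import map_recovery_study


class TestEstimateRf:
    def test_identical_columns(self):
        assert estimate_rf("AABB", "AABB") == (0.0, 4)

    def test_fully_discordant_capped_at_half(self):
        rf, n = estimate_rf("AAAA", "BBBB")
        assert rf == 0.5 and n == 4

    def test_hand_counted_toy(self):
        a = list("AABBAABU")
        b = list("ABBBAAAU")
        # informative pairs: 7 (last line missing in both); recombinant: lines 2 and 7
        rf, n = estimate_rf(a, b)
        assert n == 7
        assert rf == pytest.approx(2 / 7)

    def test_heterozygous_counts_as_donor_state(self):
        rf, _ = estimate_rf("AH", "AB")
        assert rf == 0.0

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.choice(list("ABHU"), 12)
            b = rng.choice(list("ABHU"), 12)
            assert estimate_rf(a, b) == estimate_rf(b, a)
            perm = rng.permutation(12)
            assert estimate_rf(a[perm], b[perm]) == estimate_rf(a, b)

    def test_no_informative_lines_is_a_gap(self):
        rf, n = estimate_rf("UU", "AB")
        assert math.isnan(rf) and n == 0


class TestMapFunctions:
    def test_haldane_values(self):
        assert map_distance(0.0) == 0.0
        assert map_distance(0.1) == pytest.approx(-50 * math.log(0.8))
        assert map_distance(0.1) == pytest.approx(11.157, abs=1e-3)

    def test_haldane_dominates_kosambi(self):
        for rf in np.linspace(0.01, 0.49, 25):
            assert map_distance(rf, "haldane") >= map_distance(rf, "kosambi")

    def test_half_is_infinite(self):
        assert map_distance(0.5) == float("inf")

    def test_inverse_round_trip(self):
        for fn in ("haldane", "kosambi"):
            for rf in (0.01, 0.1, 0.3):
                assert distance_to_rf(map_distance(rf, fn), fn) == pytest.approx(rf)


class TestDesignCorrection:
    def test_single_backcross_is_identity(self):
        for r in (0.01, 0.1, 0.3):
            assert expected_observed_rf(r, 1, 0) == pytest.approx(r)

    def test_selfing_limit_is_haldane_waddington(self):
        # many selfings from an F1: R -> 2r/(1+2r), the classic selfed-RIL relation
        for r in (0.05, 0.2, 0.4):
            got = expected_observed_rf(r, 0, 60)
            assert got == pytest.approx(2 * r / (1 + 2 * r), rel=1e-6)
            # and the closed-form inverse recovers r
            assert correct_rf_selfing(got) == pytest.approx(r, rel=1e-6)

    def test_corrector_inverts_the_forward_model(self):
        invert = design_rf_corrector(3, 10)
        for r in (0.01, 0.05, 0.15, 0.3):
            assert invert(expected_observed_rf(r, 3, 10)) == pytest.approx(r, abs=2e-3)

    def test_backcrossing_contracts_the_observed_map(self):
        # more backcrosses -> fewer retained junctions -> smaller observed rf
        r = 0.05
        obs = [expected_observed_rf(r, bc, 10) for bc in (1, 2, 3, 4)]
        assert all(a > b for a, b in zip(obs, obs[1:]))


def _toy_population():
    """6 lines, 1 chromosome; a donor cluster in the middle, all-A elsewhere."""
    rows = [(f"m{i + 1}", "c1", 1_000_000 * (i + 1)) for i in range(6)]
    mm = MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"]))
    ct = ChromosomeTable({"c1": 7_000_000})
    calls = [
        "AABBAA",
        "AABBAA",
        "AAABAA",
        "AAAAAA",
        "AAAAAA",
        "AAAAAA",
    ]
    G = pd.DataFrame([list(c) for c in calls], index=[f"L{i}" for i in range(6)],
                     columns=mm.marker_ids)
    return G, mm, ct


class TestBuildMap:
    def test_uncovered_bins_form_their_own_groups(self):
        G, mm, ct = _toy_population()
        bins = build_bins(G, mm, ct)
        bg = bin_genotype_matrix(bins, G.index)
        gmap = build_map(bg, bins)
        # bins: all-A prefix, m3 (B in 2 lines), m4 (B in 3), all-A suffix
        assert len(bins) == 4
        # the two covered bins share donor lines -> one group; flanking all-A
        # bins have no donor bridge -> singleton groups
        sizes = sorted(g.n_bins for g in gmap.groups)
        assert sizes == [1, 1, 2]
        covered = next(g for g in gmap.groups if g.n_bins == 2)
        # rf between the covered bins: 1 discordant line of 6
        assert covered.length_cm == pytest.approx(map_distance(1 / 6))

    def test_zero_recombination_population_has_zero_length_map(self):
        cfg = SimulationConfig(seed=2, n_lines=20, n_chromosomes=2,
                               markers_per_chromosome=10, chrom_length_cm=0.0)
        res = simulate_population(cfg)
        bins = build_bins(res.genotypes, res.marker_map, res.chromosome_table)
        bg = bin_genotype_matrix(bins, res.genotypes.index)
        gmap = build_map(bg, bins)
        assert gmap.total_length_cm == 0.0

    def test_map_frame_round_trip(self, sim_small):
        bins = build_bins(sim_small.genotypes, sim_small.marker_map, sim_small.chromosome_table)
        bg = bin_genotype_matrix(bins, sim_small.genotypes.index)
        gmap = build_map(bg, bins)
        from bilmap.genmap import GeneticMap

        back = GeneticMap.from_frame(gmap.to_frame())
        assert back.n_groups == gmap.n_groups
        assert back.total_length_cm == pytest.approx(gmap.total_length_cm)


class TestMapRecovery:
    def test_positions_and_corrected_length_recovered(self):
        res = map_recovery_study(seed=20240905)
        assert res.spearman_mean >= 0.95
        # design-corrected total length within 25% of the true spanned length
        assert res.corrected_total_cm == pytest.approx(res.true_span_cm, rel=0.25)
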
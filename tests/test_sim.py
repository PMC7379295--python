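import numpy as np
import pandas as pd
import pytest

from bilmap.segments import call_all_segments
from bilmap.sim import (
    Haplotype,
    PlantedQtl,
    SimulationConfig,
    simulate_gamete,
    simulate_phenotypes,
    simulate_population,
)
from bilmap.studies import bc_donor_fraction_study, selfing_heterozygosity_study


def _pure(length, origin):
    return Haplotype(np.array([length]), np.array([origin], dtype=np.int8))


class TestGamete:
    def test_zero_length_chromosome_passes_a_parent_intact(self):
        rng = np.random.default_rng(0)
        a, b = _pure(0.0, 1), _pure(0.0, 0)
        for _ in range(20):
            g = simulate_gamete(a, b, 0.0, rng)
            assert g.origins.tolist() in ([1], [0])

    def test_identical_homologs_pass_through(self):
        rng = np.random.default_rng(1)
        h = Haplotype(np.array([30.0, 70.0, 100.0]), np.array([0, 1, 0], dtype=np.int8))
        for _ in range(20):
            g = simulate_gamete(h, Haplotype(h.ends.copy(), h.origins.copy()), 100.0, rng)
            assert np.array_equal(g.ends, h.ends) and np.array_equal(g.origins, h.origins)

    def test_crossover_count_matches_poisson_mean(self):
        # on a 100 cM chromosome the Haldane model expects 1 crossover/meiosis;
        # with pure distinct parents every crossover leaves a junction
        rng = np.random.default_rng(2)
        a, b = _pure(100.0, 1), _pure(100.0, 0)
        n = 10_000
        junctions = sum(len(simulate_gamete(a, b, 100.0, rng).ends) - 1 for _ in range(n))
        mean = junctions / n
        se = np.sqrt(1.0 / n)  # Poisson variance = mean = 1
        assert abs(mean - 1.0) <= 3 * se

    def test_gamete_segments_are_well_formed(self):
        rng = np.random.default_rng(3)
        a = Haplotype(np.array([20.0, 80.0, 100.0]), np.array([1, 0, 1], dtype=np.int8))
        b = _pure(100.0, 0)
        for _ in range(200):
            g = simulate_gamete(a, b, 100.0, rng)
            assert g.ends[-1] == 100.0
            assert np.all(np.diff(g.ends) > 0)
            assert np.all(g.origins[1:] != g.origins[:-1])  # compressed


class TestPopulation:
    def test_fixed_seed_is_reproducible(self):
        cfg = SimulationConfig(seed=9, n_lines=15, n_chromosomes=3, markers_per_chromosome=20)
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        assert a.truth.segments == b.truth.segments

    def test_bc3_donor_fraction_matches_mendelian_expectation(self):
        r = bc_donor_fraction_study(n_lines=200, seed=20240902)
        assert abs(r.mean - r.expected) <= 3 * r.se

    def test_selfing_halves_heterozygosity_each_generation(self):
        r = selfing_heterozygosity_study(n_lines=500, seed=20240903)
        assert abs(r.mean - r.expected) <= 3 * r.se

    def test_truth_segments_consistent_with_emitted_genotypes(self, sim_small):
        res = sim_small
        donor_by_line = {}
        for s in res.truth.segments:
            donor_by_line.setdefault((s.line_id, s.chromosome), []).append(s)
        mm = res.marker_map
        for line in list(res.genotypes.index)[:10]:
            for chrom in mm.chromosomes:
                calls = res.genotypes.loc[line, mm.markers(chrom)].to_numpy()
                cm = res.marker_cm[chrom]
                segs = donor_by_line.get((line, chrom), [])
                donor_marker = np.zeros(len(cm), dtype=bool)
                for s in segs:
                    donor_marker |= (cm > s.start_cm) & (cm <= s.end_cm)
                np.testing.assert_array_equal(donor_marker, calls != "A")

    def test_caller_recovers_true_segments_within_marker_spacing(self, sim_small):
        res = sim_small
        called = call_all_segments(res.genotypes, res.marker_map, res.chromosome_table)
        spacing_bp = res.config.chrom_length_bp / res.config.markers_per_chromosome
        true_by_key = {}
        for s in res.truth.segments:
            true_by_key.setdefault((s.line_id, s.chromosome), []).append(s)
        for c in called:
            candidates = true_by_key.get((c.line_id, c.chromosome), [])
            # each called border lies within one inter-marker interval of a
            # true border (chromosome-tip extensions excluded)
            start_ok = c.start_bp == 1 or any(
                abs(t.start_bp - c.start_bp) <= spacing_bp for t in candidates
            )
            end_ok = c.end_bp == res.chromosome_table[c.chromosome] or any(
                abs(t.end_bp - c.end_bp) <= spacing_bp for t in candidates
            )
            assert start_ok and end_ok, (c, candidates)

    def test_hybrid_of_homozygous_line_is_heterozygous_with_same_borders(self):
        cfg = SimulationConfig(
            seed=31, n_lines=25, n_chromosomes=4, markers_per_chromosome=50,
            make_hybrids=True,
        )
        res = simulate_population(cfg)
        assert res.hybrid_genotypes is not None
        hyb = res.hybrid_genotypes.copy()
        hyb.index = [i.replace("xRP", "") for i in hyb.index]
        assert set(hyb.to_numpy().ravel()) <= {"A", "H"}
        called_h = call_all_segments(hyb, res.marker_map, res.chromosome_table)
        called = call_all_segments(res.genotypes, res.marker_map, res.chromosome_table)
        keyed = {(s.line_id, s.chromosome, s.start_bp, s.end_bp) for s in called}
        fully_hom = {
            line
            for line in res.genotypes.index
            if not (res.genotypes.loc[line] == "H").any()
        }
        for s in called_h:
            if s.line_id in fully_hom:
                assert s.zygosity == "heterozygous"
                assert (s.line_id, s.chromosome, s.start_bp, s.end_bp) in keyed

    def test_mean_segments_per_line_in_plausible_band(self, sim_small):
        from bilmap.segments import summarize_population

        segs = call_all_segments(sim_small.genotypes, sim_small.marker_map, sim_small.chromosome_table)
        summ = summarize_population(segs, len(sim_small.genotypes), sim_small.chromosome_table)
        # 6 chromosomes of 100 cM: about half the genome of the default config,
        # so roughly half of the 2-8 segments band
        assert 1.0 <= summ.mean_segments_per_line <= 5.0


class TestPhenotypes:
    def test_zero_effect_zero_noise_is_baseline(self, sim_small):
        cfg = SimulationConfig(seed=1, noise_sd=0.0, baseline=42.0)
        phen = simulate_phenotypes(sim_small.genotypes, cfg, seed=1, n_null_traits=2)
        assert len(phen) > 0
        assert (phen["value"] == 42.0).all()

    def test_class_mean_difference_equals_planted_effect(self, sim_small):
        marker = sim_small.marker_map.marker_ids[10]
        cfg = SimulationConfig(
            seed=1, noise_sd=0.0, planted_qtls=(PlantedQtl("t", marker, 1.7),)
        )
        phen = simulate_phenotypes(sim_small.genotypes, cfg, seed=1, include_control=False)
        means = phen.groupby("line_id")["value"].mean()
        donor = sim_small.genotypes[marker] == "B"
        rec = sim_small.genotypes[marker] == "A"
        if donor.any() and rec.any():
            diff = means[donor[donor].index].mean() - means[rec[rec].index].mean()
            assert diff == pytest.approx(1.7)

    def test_unknown_qtl_marker_rejected(self, sim_small):
        cfg = SimulationConfig(seed=1, planted_qtls=(PlantedQtl("t", "nope", 1.0),))
        with pytest.raises(ValueError, match="not in marker map"):
            simulate_phenotypes(sim_small.genotypes, cfg)

    def test_control_line_gets_baseline_only(self, sim_small):
        marker = sim_small.marker_map.marker_ids[0]
        cfg = SimulationConfig(
            seed=1, noise_sd=0.0, baseline=10.0,
            planted_qtls=(PlantedQtl("t", marker, 5.0),),
        )
        phen = simulate_phenotypes(sim_small.genotypes, cfg, seed=2)
        ctrl = phen[phen["line_id"] == cfg.control_line_id]
        assert (ctrl["value"] == 10.0).all()
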
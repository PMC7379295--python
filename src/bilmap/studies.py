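"""Calibration and power studies on simulated populations.

These routines quantify how the scan behaves under the breeding design the
simulator emulates: type-I error of the single-bin ANOVA on null traits,
power and support-interval coverage for a planted QTL, Mendelian expectations
of the breeding scheme (donor genome fraction after backcrossing, residual
heterozygosity after selfing), and recovery of true genetic-map positions.

All routines are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bins import bin_genotype_matrix, build_bins
from .genmap import build_map
from .qtl import ScanConfig, anova_scan, lod_support_interval
from .sim import PlantedQtl, SimulationConfig, simulate_phenotypes, simulate_population

__all__ = [
    "type1_error_study",
    "power_study",
    "bc_donor_fraction_study",
    "selfing_heterozygosity_study",
    "map_recovery_study",
]

_MAX_SEED = 2**31 - 1


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _MAX_SEED, size=n)


@dataclass(frozen=True)
class Type1Result:
    rate_independent: float  # one designated bin per trait: independent draws
    rate_pooled: float  # all (trait, bin) tests pooled
    n_traits: int
    n_tests_pooled: int
    alpha: float


def type1_error_study(
    *,
    n_traits: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_lines: int = 107,
    n_replicates: int = 3,
) -> Type1Result:
    """Empirical rejection rate of the raw (nominal-alpha) ANOVA scan on
    pure-noise traits.

    One bin per trait (cycled over the testable bins) gives independent
    Bernoulli(alpha) draws so exact binomial bounds apply; the pooled rate
    over every (trait, bin) pair is reported alongside.
    """
    s1, s2 = _spawn_seeds(seed, 2)
    cfg = SimulationConfig(seed=int(s1), n_lines=n_lines, n_replicates=n_replicates)
    res = simulate_population(cfg)
    bins = build_bins(res.genotypes, res.marker_map, res.chromosome_table)
    bg = bin_genotype_matrix(bins, res.genotypes.index)
    phen = simulate_phenotypes(
        res.genotypes, cfg, seed=int(s2), n_null_traits=n_traits, include_control=False
    )
    scan = anova_scan(
        phen, bg, bins, ScanConfig(threshold_mode="nominal", alpha=alpha)
    )
    curves = scan.curves.dropna(subset=["p_value"])
    pooled = float((curves["p_value"] < alpha).mean())

    # designated bin per trait, cycled over testable bins
    testable = sorted(curves["bin_id"].unique())
    by_trait = curves.set_index(["trait_id", "bin_id"])["p_value"]
    hits = 0
    traits = sorted(curves["trait_id"].unique())
    for t, trait in enumerate(traits):
        bin_id = testable[t % len(testable)]
        if (trait, bin_id) in by_trait.index:
            hits += int(by_trait.loc[(trait, bin_id)] < alpha)
    return Type1Result(
        rate_independent=hits / len(traits),
        rate_pooled=pooled,
        n_traits=len(traits),
        n_tests_pooled=len(curves),
        alpha=alpha,
    )


@dataclass(frozen=True)
class PowerResult:
    power_pct: float  # genome-wide LOD peak within +/-1 bin of the true bin
    coverage_pct: float  # planted marker inside the peak's 1-LOD interval
    power_significant_pct: float  # Bonferroni-significant peak on the true chromosome
    coverage_detected_pct: float  # interval coverage among significant detections
    n_sims: int
    effect_sd: float


def power_study(
    *,
    n_sims: int = 100,
    effect: float = 1.0,
    seed: int = 0,
    n_lines: int = 107,
    n_replicates: int = 3,
    lod_drop: float = 1.0,
    alpha: float = 0.05,
) -> PowerResult:
    """Detection power and 1-LOD interval coverage for one planted QTL.

    The QTL sits at the middle marker of chromosome 5. Four statistics are
    reported: localization power (genome-wide LOD argmax in the true bin or
    an adjacent one), unconditional interval coverage (planted position
    inside the 1-LOD interval around the genome-wide peak), significance
    power (genome-wide Bonferroni at ``alpha`` with the peak on the true
    chromosome), and the interval procedure's own coverage among those
    significant detections.
    """
    seeds = _spawn_seeds(seed, 2 * n_sims).reshape(n_sims, 2)
    detected = 0
    covered = 0
    significant = 0
    covered_sig = 0
    for s in range(n_sims):
        cfg = SimulationConfig(
            seed=int(seeds[s, 0]), n_lines=n_lines, n_replicates=n_replicates
        )
        res = simulate_population(cfg)
        chrom = res.marker_map.chromosomes[4]
        markers = res.marker_map.markers(chrom)
        qtl_marker = markers[len(markers) // 2]
        qcfg = SimulationConfig(
            seed=cfg.seed,
            n_lines=n_lines,
            n_replicates=n_replicates,
            noise_sd=cfg.noise_sd,
            planted_qtls=(PlantedQtl("trait", qtl_marker, effect * cfg.noise_sd),),
        )
        phen = simulate_phenotypes(
            res.genotypes, qcfg, seed=int(seeds[s, 1]), include_control=False
        )
        bins = build_bins(res.genotypes, res.marker_map, res.chromosome_table)
        bg = bin_genotype_matrix(bins, res.genotypes.index)
        scan = anova_scan(
            phen, bg, bins, ScanConfig(threshold_mode="nominal"), traits=["trait"]
        )
        curves = scan.curves
        true_idx = next(i for i, b in enumerate(bins) if qtl_marker in b.marker_ids)
        lods = curves["lod"].to_numpy()
        if np.isnan(lods).all():
            continue
        peak = int(np.nanargmax(lods))
        same_chrom = bins[peak].chromosome == bins[true_idx].chromosome
        if same_chrom and abs(peak - true_idx) <= 1:
            detected += 1
        # 1-LOD support interval around the genome-wide peak
        chrom_sel = [i for i, b in enumerate(bins) if b.chromosome == bins[peak].chromosome]
        iv = lod_support_interval(
            [bins[i].start_bp for i in chrom_sel],
            [bins[i].end_bp for i in chrom_sel],
            lods[chrom_sel],
            chrom_sel.index(peak),
            lod_drop,
        )
        qtl_bp = int(
            res.marker_map.frame.set_index("marker_id").loc[qtl_marker, "position_bp"]
        )
        covers = same_chrom and iv[0] <= qtl_bp <= iv[1]
        if covers:
            covered += 1
        pvals = curves["p_value"].to_numpy()
        n_tests = int((~np.isnan(pvals)).sum())
        if same_chrom and pvals[peak] < alpha / max(n_tests, 1):
            significant += 1
            if covers:
                covered_sig += 1
    return PowerResult(
        power_pct=100.0 * detected / n_sims,
        coverage_pct=100.0 * covered / n_sims,
        power_significant_pct=100.0 * significant / n_sims,
        coverage_detected_pct=100.0 * covered_sig / max(significant, 1),
        n_sims=n_sims,
        effect_sd=effect,
    )


@dataclass(frozen=True)
class FractionResult:
    mean: float
    se: float
    expected: float
    n_lines: int


def bc_donor_fraction_study(*, n_lines: int = 200, seed: int = 0) -> FractionResult:
    """Mean donor-genome fraction right after the backcross phase.

    The Mendelian expectation after three backcrosses of an F1 is
    (1/2)^4 = 6.25% of the genome.
    """
    cfg = SimulationConfig(seed=seed, n_lines=n_lines, n_selfings=0)
    res = simulate_population(cfg)
    vals = res.genotypes.to_numpy(dtype="U1")
    dose = (vals == "B") * 1.0 + (vals == "H") * 0.5
    per_line = dose.mean(axis=1)
    return FractionResult(
        mean=float(per_line.mean()),
        se=float(per_line.std(ddof=1) / np.sqrt(n_lines)),
        expected=0.5 ** (cfg.n_backcrosses + 1),
        n_lines=n_lines,
    )


def selfing_heterozygosity_study(*, n_lines: int = 500, seed: int = 0) -> FractionResult:
    """Residual per-marker heterozygosity after the selfing phase.

    Each selfing generation halves per-locus heterozygosity, so the
    expectation is the post-backcross level (1/2)^3 scaled by (1/2)^10.
    """
    cfg = SimulationConfig(seed=seed, n_lines=n_lines)
    res = simulate_population(cfg)
    vals = res.genotypes.to_numpy(dtype="U1")
    per_line = (vals == "H").mean(axis=1)
    return FractionResult(
        mean=float(per_line.mean()),
        se=float(per_line.std(ddof=1) / np.sqrt(n_lines)),
        expected=0.5**cfg.n_backcrosses * 0.5**cfg.n_selfings,
        n_lines=n_lines,
    )


@dataclass(frozen=True)
class MapRecoveryResult:
    spearman_mean: float  # over linkage groups with >= 5 bins
    spearman_min: float
    estimated_total_cm: float  # uncorrected (raw discordance fractions)
    corrected_total_cm: float  # with the design-based rf inversion
    true_span_cm: float  # true cM extent spanned by the recovered groups
    n_groups_tested: int


def map_recovery_study(*, n_lines: int = 141, seed: int = 0) -> MapRecoveryResult:
    """Compare estimated bin positions with the simulator's true cM positions.

    Spearman correlation is computed within each linkage group of >= 5 bins.
    Total lengths are compared with the true cM span of the recovered groups
    (regions without donor coverage contribute no linkage information and are
    excluded by construction): the raw discordance-fraction map measures the
    breakpoint density retained by the inbred genomes, while the design-based
    correction recovers meiotic distances.
    """
    cfg = SimulationConfig(seed=seed, n_lines=n_lines)
    res = simulate_population(cfg)
    bins = build_bins(res.genotypes, res.marker_map, res.chromosome_table)
    bg = bin_genotype_matrix(bins, res.genotypes.index)
    gmap = build_map(bg, bins)
    gmap_corr = build_map(
        bg, bins, rf_correction="design", design=(cfg.n_backcrosses, cfg.n_selfings)
    )

    # true cM of a bin: midpoint of its marker cM positions
    marker_cm = {}
    for chrom in res.marker_map.chromosomes:
        for mid, cm in zip(res.marker_map.markers(chrom), res.marker_cm[chrom]):
            marker_cm[mid] = cm
    true_cm = {
        b.bin_id: (marker_cm[b.marker_ids[0]] + marker_cm[b.marker_ids[-1]]) / 2.0
        for b in bins
    }

    rhos = []
    span = 0.0
    for g in gmap.groups:
        truths = np.array([true_cm[b] for b in g.bin_ids])
        span += float(truths.max() - truths.min())
        if g.n_bins >= 5:
            rho = stats.spearmanr(np.asarray(g.cum_cm), truths).statistic
            if not np.isnan(rho):
                rhos.append(float(rho))
    return MapRecoveryResult(
        spearman_mean=float(np.mean(rhos)) if rhos else float("nan"),
        spearman_min=float(np.min(rhos)) if rhos else float("nan"),
        estimated_total_cm=gmap.total_length_cm,
        corrected_total_cm=gmap_corr.total_length_cm,
        true_span_cm=span,
        n_groups_tested=len(rhos),
    )
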
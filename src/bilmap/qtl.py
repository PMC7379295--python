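"""Metabolite-QTL scanning: single-bin ANOVA and Haley–Knott regression.

Replicates are collapsed to per-line means before scanning. Genotype classes
collapse to donor-vs-recurrent (an H call counts as donor, consistent with the
segment caller), so the single-bin test is a two-class one-way ANOVA, which is
identical to regressing the line means on a 0/1 donor indicator. The LOD score
is the regression form

    LOD = (n / 2) * log10(RSS0 / RSS1)

with RSS0 the residual sum of squares of the grand-mean (null) fit.

Haley–Knott regression replaces the observed indicator by the expected donor
dosage at a grid position, computed from the nearest informative flanking bins
and the inter-locus recombination fractions under a no-interference two-point
model; phenotype is then regressed on that expected dosage.

Genome-wide significance uses trait-wise permutation thresholds by default
(the distribution of the genome-wide maximum LOD under shuffled line labels);
Bonferroni and nominal per-test modes are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bins import Bin
from .genmap import GeneticMap, distance_to_rf, donor_state
from .io import line_means

logger = logging.getLogger(__name__)

WILD_INCREASES = "wild_increases"
WILD_DECREASES = "wild_decreases"

_TINY_P = 5e-324  # smallest positive float; keeps p in (0, 1] for perfect fits

__all__ = [
    "ScanConfig",
    "QtlResult",
    "ScanResult",
    "anova_scan",
    "hk_scan",
    "hk_dosage",
    "lod_support_interval",
    "conserved_qtls",
    "ConservedQtl",
    "permutation_threshold",
    "regress_lod",
]


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of a QTL scan.

    lod_drop
        LOD decrease defining the support interval around a peak (default 1.0).
    threshold_mode
        ``"permutation"`` (trait-wise genome-wide max-LOD null), ``"bonferroni"``
        (alpha divided by the number of tested positions) or ``"nominal"``
        (raw per-test alpha, for calibration studies).
    """

    lod_drop: float = 1.0
    threshold_mode: str = "permutation"
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    min_class_size: int = 2
    grid_step_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.lod_drop <= 0:
            raise ValueError("lod_drop must be > 0")
        if self.threshold_mode == "permutation" and self.n_permutations < 100:
            raise ValueError("need >= 100 permutations in permutation mode")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class QtlResult:
    trait_id: str
    experiment_id: str
    chromosome: str
    bin_id: str
    position_bp: int
    lod: float
    p_value: float
    effect_direction: str
    effect_size: float
    interval_start_bp: int
    interval_end_bp: int


@dataclass(frozen=True)
class ScanResult:
    qtls: tuple[QtlResult, ...]
    curves: pd.DataFrame = field(repr=False)  # long: trait, position, lod, p, ...
    thresholds: dict[str, float] = field(default_factory=dict)

    def qtl_frame(self) -> pd.DataFrame:
        return pd.DataFrame([q.__dict__ for q in self.qtls])


def regress_lod(
    Y: np.ndarray, x: np.ndarray, *, min_class_size: int = 2, binary: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """LOD, p and effect of regressing each column of Y on x.

    ``x`` may contain nan (lines excluded). For binary x the fit is the
    two-class one-way ANOVA; ``min_class_size`` lines are required per class.
    Returns ``(lod, p, effect, n_used)`` with nan rows when the position is
    untestable.
    """
    Y = np.asarray(Y, dtype=float)
    x = np.asarray(x, dtype=float)
    n_traits = Y.shape[1]
    nanrow = (np.full(n_traits, np.nan),) * 3
    ok = ~np.isnan(x)
    valid_y = ~np.isnan(Y).any(axis=1)
    ok &= valid_y
    n = int(ok.sum())
    if n < 3:
        return (*nanrow, n)
    xb = x[ok]
    if binary:
        n_donor = int((xb == 1).sum())
        n_rec = int((xb == 0).sum())
        if min(n_donor, n_rec) < min_class_size:
            return (*nanrow, n)
    Yb = Y[ok]
    xc = xb - xb.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        return (*nanrow, n)
    Yc = Yb - Yb.mean(axis=0)
    sxy = xc @ Yc
    rss0 = np.einsum("ij,ij->j", Yc, Yc)
    rss1 = rss0 - sxy**2 / sxx
    rss1 = np.maximum(rss1, 0.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        lod = np.where(rss0 > 0, (n / 2.0) * np.log10(rss0 / np.maximum(rss1, _TINY_P)), 0.0)
        fstat = np.where(rss1 > 0, (n - 2) * (rss0 - rss1) / np.maximum(rss1, _TINY_P), np.inf)
    p = stats.f.sf(fstat, 1, n - 2)
    p = np.maximum(p, _TINY_P)
    effect = sxy / sxx  # slope == donor-class mean minus recurrent-class mean for 0/1 x
    return lod, p, effect, n


def _dosage_columns(bin_genotypes: pd.DataFrame, bins: Sequence[Bin]) -> np.ndarray:
    return np.column_stack(
        [donor_state(bin_genotypes[b.bin_id].to_numpy()) for b in bins]
    )


def _align(phenotypes: pd.DataFrame, bin_genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-line trait means restricted and ordered to the genotyped lines."""
    means = line_means(phenotypes)
    common = [l for l in bin_genotypes.index.astype(str) if l in means.index]
    if not common:
        raise ValueError("no overlap between phenotyped and genotyped lines")
    return means.loc[common]


def permutation_threshold(
    y: np.ndarray,
    D: np.ndarray,
    *,
    n_permutations: int,
    alpha: float,
    rng: np.random.Generator,
    min_class_size: int = 2,
) -> float:
    """(1 - alpha) quantile of the genome-wide max LOD under permutation."""
    n = len(y)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_permutations)])
    Yp = y[perm_idx].T  # n x P
    max_lod = np.zeros(n_permutations)
    for j in range(D.shape[1]):
        lod, _, _, _ = regress_lod(Yp, D[:, j], min_class_size=min_class_size)
        with np.errstate(invalid="ignore"):
            max_lod = np.fmax(max_lod, np.nan_to_num(lod, nan=0.0))
    return float(np.quantile(max_lod, 1.0 - alpha))


def lod_support_interval(
    positions_start_bp: Sequence[int],
    positions_end_bp: Sequence[int],
    lods: Sequence[float],
    peak_index: int,
    lod_drop: float,
) -> tuple[int, int]:
    """Maximal contiguous bp region around a peak within ``lod_drop`` of it.

    ``positions_*`` are the bp extents of the scanned positions (bins or grid
    points collapsed to unit intervals), ordered along one chromosome or
    linkage group. A flat curve returns the whole extent with a warning.
    """
    lods = np.asarray(lods, dtype=float)
    peak = lods[peak_index]
    cutoff = peak - lod_drop
    lo = peak_index
    while lo > 0 and not np.isnan(lods[lo - 1]) and lods[lo - 1] >= cutoff:
        lo -= 1
    hi = peak_index
    m = len(lods)
    while hi < m - 1 and not np.isnan(lods[hi + 1]) and lods[hi + 1] >= cutoff:
        hi += 1
    if lo == 0 and hi == m - 1 and (np.nanmax(lods) - np.nanmin(lods)) == 0.0:
        logger.warning("flat LOD curve: support interval spans the whole extent")
    return (int(positions_start_bp[lo]), int(positions_end_bp[hi]))


def _direction(effect: float) -> str:
    return WILD_INCREASES if effect > 0 else WILD_DECREASES


def _extract_qtls(
    trait: str,
    experiment_id: str,
    chrom_of: np.ndarray,
    bin_ids: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    mids: np.ndarray,
    lod: np.ndarray,
    p: np.ndarray,
    effect: np.ndarray,
    significant: np.ndarray,
    lod_drop: float,
) -> list[QtlResult]:
    """Group contiguous significant positions per chromosome into QTL peaks."""
    out: list[QtlResult] = []
    for chrom in dict.fromkeys(chrom_of):
        sel = np.flatnonzero(chrom_of == chrom)
        sig = significant[sel] & ~np.isnan(lod[sel])
        if not sig.any():
            continue
        # contiguous runs of significant positions
        k = 0
        while k < len(sel):
            if not sig[k]:
                k += 1
                continue
            j = k
            while j + 1 < len(sel) and sig[j + 1]:
                j += 1
            run = sel[k : j + 1]
            peak_local = run[np.nanargmax(lod[run])]
            peak_in_chrom = int(np.flatnonzero(sel == peak_local)[0])
            iv = lod_support_interval(
                starts[sel], ends[sel], lod[sel], peak_in_chrom, lod_drop
            )
            out.append(
                QtlResult(
                    trait_id=trait,
                    experiment_id=experiment_id,
                    chromosome=str(chrom),
                    bin_id=str(bin_ids[peak_local]),
                    position_bp=int(mids[peak_local]),
                    lod=float(lod[peak_local]),
                    p_value=float(p[peak_local]),
                    effect_direction=_direction(float(effect[peak_local])),
                    effect_size=float(effect[peak_local]),
                    interval_start_bp=iv[0],
                    interval_end_bp=iv[1],
                )
            )
            k = j + 1
    return out


def anova_scan(
    phenotypes: pd.DataFrame,
    bin_genotypes: pd.DataFrame,
    bins: Sequence[Bin],
    config: ScanConfig = ScanConfig(),
    *,
    experiment_id: str = "exp1",
    traits: Sequence[str] | None = None,
) -> ScanResult:
    """Per-bin two-class ANOVA scan of every trait.

    Raises if a requested trait is absent; bins where any genotype class has
    fewer than ``config.min_class_size`` lines are skipped (nan in the curve).
    """
    means = _align(phenotypes, bin_genotypes)
    if traits is not None:
        missing = [t for t in traits if t not in means.columns]
        if missing:
            raise ValueError(f"traits absent from phenotype table: {missing}")
        means = means[list(traits)]
    D = _dosage_columns(bin_genotypes.loc[means.index], bins)
    Y = means.to_numpy(dtype=float)
    trait_ids = list(means.columns)
    n_bins = len(bins)

    lod = np.full((n_bins, len(trait_ids)), np.nan)
    p = np.full_like(lod, np.nan)
    eff = np.full_like(lod, np.nan)
    skipped = 0
    for j in range(n_bins):
        lj, pj, ej, _ = regress_lod(Y, D[:, j], min_class_size=config.min_class_size)
        if np.isnan(lj).all():
            skipped += 1
        lod[j], p[j], eff[j] = lj, pj, ej
    if skipped:
        logger.info("anova_scan: %d of %d bins untestable (single class)", skipped, n_bins)

    chrom_of = np.asarray([b.chromosome for b in bins])
    bin_ids = np.asarray([b.bin_id for b in bins])
    starts = np.asarray([b.start_bp for b in bins])
    ends = np.asarray([b.end_bp for b in bins])
    mids = (starts + ends) // 2

    n_tests = int((~np.isnan(lod[:, 0])).sum()) or n_bins
    thresholds: dict[str, float] = {}
    qtls: list[QtlResult] = []
    rng = np.random.default_rng(config.seed)
    for t, trait in enumerate(trait_ids):
        if config.threshold_mode == "permutation":
            thr = permutation_threshold(
                Y[:, t],
                D,
                n_permutations=config.n_permutations,
                alpha=config.alpha,
                rng=rng,
                min_class_size=config.min_class_size,
            )
            sig = lod[:, t] >= thr
            thresholds[trait] = thr
        elif config.threshold_mode == "bonferroni":
            sig = p[:, t] < config.alpha / max(n_tests, 1)
        elif config.threshold_mode == "nominal":
            sig = p[:, t] < config.alpha
        else:
            raise ValueError(f"unknown threshold mode {config.threshold_mode!r}")
        qtls.extend(
            _extract_qtls(
                trait, experiment_id, chrom_of, bin_ids, starts, ends, mids,
                lod[:, t], p[:, t], eff[:, t], np.asarray(sig), config.lod_drop,
            )
        )

    curves = pd.DataFrame(
        {
            "trait_id": np.repeat(trait_ids, n_bins),
            "bin_id": np.tile(bin_ids, len(trait_ids)),
            "chromosome": np.tile(chrom_of, len(trait_ids)),
            "position_bp": np.tile(mids, len(trait_ids)),
            "lod": lod.T.ravel(),
            "p_value": p.T.ravel(),
            "effect": eff.T.ravel(),
        }
    )
    return ScanResult(qtls=tuple(qtls), curves=curves, thresholds=thresholds)


def hk_dosage(
    left_state: float | None,
    right_state: float | None,
    rf_left: float,
    rf_right: float,
) -> float:
    """Expected donor dosage at a position given flanking donor states.

    Two-point no-interference Markov model on the donor/recurrent state:
    the transition probability across a recombination fraction r is r for a
    state change and 1 - r otherwise. With both flanks observed the posterior
    is conditioned on both; with one flank, on that flank alone.
    """
    def trans(state: float, target: int, r: float) -> float:
        return r if int(state) != target else 1.0 - r

    if left_state is None and right_state is None:
        return float("nan")
    if left_state is None:
        return trans(right_state, 1, rf_right)
    if right_state is None:
        return trans(left_state, 1, rf_left)
    w1 = trans(left_state, 1, rf_left) * trans(right_state, 1, rf_right)
    w0 = trans(left_state, 0, rf_left) * trans(right_state, 0, rf_right)
    if w0 + w1 == 0.0:  # contradictory flanks at zero distance; undefined
        return 0.5
    return w1 / (w1 + w0)


def _group_grid(cum_cm: Sequence[float], step_cm: float) -> list[float]:
    """Bin positions plus interior grid points every ``step_cm``."""
    grid: list[float] = []
    for a, b in zip(cum_cm[:-1], cum_cm[1:]):
        grid.append(a)
        if step_cm > 0:
            x = a + step_cm
            while x < b - 1e-9:
                grid.append(x)
                x += step_cm
    grid.append(cum_cm[-1])
    return grid


def hk_scan(
    phenotypes: pd.DataFrame,
    bin_genotypes: pd.DataFrame,
    genetic_map: GeneticMap,
    bins: Sequence[Bin],
    config: ScanConfig = ScanConfig(),
    *,
    experiment_id: str = "exp1",
    traits: Sequence[str] | None = None,
) -> ScanResult:
    """Haley–Knott regression scan over each linkage group's cM grid.

    Lines missing both flanking bins at a position are excluded there. A group
    with a single bin degenerates to the single-bin ANOVA at that bin.
    """
    means = _align(phenotypes, bin_genotypes)
    if traits is not None:
        missing = [t for t in traits if t not in means.columns]
        if missing:
            raise ValueError(f"traits absent from phenotype table: {missing}")
        means = means[list(traits)]
    Y = means.to_numpy(dtype=float)
    trait_ids = list(means.columns)
    bin_by_id = {b.bin_id: b for b in bins}
    mapfn = genetic_map.map_function

    rows_meta: list[tuple[str, str, str, float, int, int, int]] = []
    # (group_id, chromosome, nearest_bin, cm, start_bp, end_bp, mid_bp)
    dosages: list[np.ndarray] = []

    for group in genetic_map.groups:
        gbins = [bin_by_id[b] for b in group.bin_ids]
        S = _dosage_columns(bin_genotypes.loc[means.index], gbins)  # lines x gbins
        cms = np.asarray(group.cum_cm)
        anchors_bp = np.asarray([(b.start_bp + b.end_bp) // 2 for b in gbins], dtype=float)
        grid = _group_grid(list(cms), config.grid_step_cm) if len(gbins) > 1 else [cms[0]]

        # nearest informative flank per line, per bin index: forward/backward fill
        n_lines, n_b = S.shape
        idx = np.arange(n_b)
        informative = ~np.isnan(S)
        left_idx = np.where(informative, idx, -1)
        left_idx = np.maximum.accumulate(left_idx, axis=1)
        right_idx = np.where(informative, idx, n_b)
        right_idx = np.minimum.accumulate(right_idx[:, ::-1], axis=1)[:, ::-1]

        for pos in grid:
            k = int(np.searchsorted(cms, pos, side="right") - 1)
            k = min(max(k, 0), n_b - 1)
            at_bin = abs(pos - cms[k]) < 1e-9
            if at_bin:
                li = left_idx[:, k]
                ri = right_idx[:, k]
            else:
                li = left_idx[:, k]
                ri = right_idx[:, min(k + 1, n_b - 1)] if k + 1 < n_b else np.full(n_lines, n_b)
            x = np.full(n_lines, np.nan)
            for i in range(n_lines):
                l, r = int(li[i]), int(ri[i])
                ls = S[i, l] if l >= 0 else None
                rs = S[i, r] if r < n_b else None
                if ls is None and rs is None:
                    continue
                r1 = distance_to_rf(pos - cms[l], mapfn) if l >= 0 else 0.0
                r2 = distance_to_rf(cms[r] - pos, mapfn) if r < n_b else 0.0
                x[i] = hk_dosage(ls, rs, r1, r2)
            if len(gbins) > 1:
                bp = float(np.interp(pos, cms, anchors_bp)) if cms[-1] > cms[0] else anchors_bp[0]
            else:
                bp = anchors_bp[0]
            nearest = gbins[int(np.argmin(np.abs(cms - pos)))]
            rows_meta.append(
                (
                    group.group_id,
                    group.chromosome,
                    nearest.bin_id,
                    float(pos),
                    nearest.start_bp,
                    nearest.end_bp,
                    int(round(bp)),
                )
            )
            dosages.append(x)

    n_pos = len(dosages)
    lod = np.full((n_pos, len(trait_ids)), np.nan)
    p = np.full_like(lod, np.nan)
    eff = np.full_like(lod, np.nan)
    for j, x in enumerate(dosages):
        binary = bool(np.all(np.isin(x[~np.isnan(x)], (0.0, 1.0))))
        lj, pj, ej, _ = regress_lod(Y, x, min_class_size=config.min_class_size, binary=binary)
        lod[j], p[j], eff[j] = lj, pj, ej

    group_of = np.asarray([m[0] for m in rows_meta])
    chrom_of = np.asarray([m[1] for m in rows_meta])
    bin_ids = np.asarray([m[2] for m in rows_meta])
    cms_all = np.asarray([m[3] for m in rows_meta])
    starts = np.asarray([m[4] for m in rows_meta])
    ends = np.asarray([m[5] for m in rows_meta])
    mids = np.asarray([m[6] for m in rows_meta])

    D_for_perm = np.column_stack(dosages) if dosages else np.empty((Y.shape[0], 0))
    n_tests = int((~np.isnan(lod[:, 0])).sum()) or max(n_pos, 1)
    thresholds: dict[str, float] = {}
    qtls: list[QtlResult] = []
    rng = np.random.default_rng(config.seed)
    for t, trait in enumerate(trait_ids):
        if config.threshold_mode == "permutation":
            thr = permutation_threshold(
                Y[:, t],
                D_for_perm,
                n_permutations=config.n_permutations,
                alpha=config.alpha,
                rng=rng,
                min_class_size=config.min_class_size,
            )
            sig = lod[:, t] >= thr
            thresholds[trait] = thr
        elif config.threshold_mode == "bonferroni":
            sig = p[:, t] < config.alpha / n_tests
        elif config.threshold_mode == "nominal":
            sig = p[:, t] < config.alpha
        else:
            raise ValueError(f"unknown threshold mode {config.threshold_mode!r}")
        # group-wise extraction keeps intervals inside a linkage group
        for gid in dict.fromkeys(group_of):
            gsel = group_of == gid
            qtls.extend(
                _extract_qtls(
                    trait, experiment_id, chrom_of[gsel], bin_ids[gsel],
                    starts[gsel], ends[gsel], mids[gsel],
                    lod[gsel, t], p[gsel, t], eff[gsel, t],
                    np.asarray(sig)[gsel], config.lod_drop,
                )
            )

    curves = pd.DataFrame(
        {
            "trait_id": np.repeat(trait_ids, n_pos),
            "group_id": np.tile(group_of, len(trait_ids)),
            "chromosome": np.tile(chrom_of, len(trait_ids)),
            "bin_id": np.tile(bin_ids, len(trait_ids)),
            "cm": np.tile(cms_all, len(trait_ids)),
            "position_bp": np.tile(mids, len(trait_ids)),
            "lod": lod.T.ravel(),
            "p_value": p.T.ravel(),
            "effect": eff.T.ravel(),
        }
    )
    return ScanResult(qtls=tuple(qtls), curves=curves, thresholds=thresholds)


@dataclass(frozen=True)
class ConservedQtl:
    trait_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    experiment_ids: tuple[str, ...]
    n_qtls: int


def conserved_qtls(results: Iterable[QtlResult]) -> list[ConservedQtl]:
    """Same-trait QTLs whose support intervals intersect on one chromosome,
    grouped by chained overlap; conserved iff the group spans >= 2 experiments.
    """
    by_key: dict[tuple[str, str], list[QtlResult]] = {}
    for q in results:
        by_key.setdefault((q.trait_id, q.chromosome), []).append(q)

    out: list[ConservedQtl] = []
    for (trait, chrom), qs in sorted(by_key.items()):
        qs = sorted(qs, key=lambda q: (q.interval_start_bp, q.interval_end_bp))
        cluster: list[QtlResult] = []
        cur_end = -1

        def _flush() -> None:
            exps = tuple(sorted({q.experiment_id for q in cluster}))
            if len(exps) >= 2:
                out.append(
                    ConservedQtl(
                        trait_id=trait,
                        chromosome=chrom,
                        start_bp=min(q.interval_start_bp for q in cluster),
                        end_bp=max(q.interval_end_bp for q in cluster),
                        experiment_ids=exps,
                        n_qtls=len(cluster),
                    )
                )

        for q in qs:
            if not cluster or q.interval_start_bp <= cur_end:
                cluster.append(q)
                cur_end = max(cur_end, q.interval_end_bp)
            else:
                _flush()
                cluster = [q]
                cur_end = q.interval_end_bp
        if cluster:
            _flush()
    return out
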
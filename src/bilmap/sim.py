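"""Forward simulation of a backcross-inbred-line breeding scheme.

The generator emulates the construction of the BIL population the package
analyzes: an interspecific F1 (donor x recurrent) is backcrossed to the
recurrent parent for a configurable number of cycles (default 3), then
advanced by single-seed-descent selfing (default 10 generations), optionally
followed by a final cross back to the recurrent parent that renders every
introgression heterozygous ("BIL hybrids"). Meiosis follows the Haldane
model: per chromosome the crossover count is Poisson(length in Morgans) with
breakpoints uniform on the cM scale and no interference; there is no
selection and no selfing failure.

Haplotypes are piecewise-constant ancestry functions over the cM axis, so the
emitted marker genotypes and the recorded truth segments are exact (no grid
discretization). cM-to-bp conversion is linear per chromosome.

Phenotypes are additive: line value = baseline + sum of effect x donor dosage
at each planted QTL (+ an optional dominance deviation for heterozygotes),
plus independent Gaussian replicate noise. The recurrent-parent control line
carries no donor allele and therefore gets the baseline only.

Defaults mirror the population the package targets: 12 chromosomes of
100 cM / 65 Mbp carrying 260 markers each (3120 genome-anchored SNPs), 141
lines, three backcrosses, ten selfings, three replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import ChromosomeTable, MarkerMap

__all__ = [
    "PlantedQtl",
    "SimulationConfig",
    "TrueSegment",
    "SimTruth",
    "SimulationResult",
    "Haplotype",
    "simulate_gamete",
    "simulate_population",
    "simulate_phenotypes",
]


class Haplotype(NamedTuple):
    """Piecewise ancestry: segment i spans (ends[i-1], ends[i]] on the cM axis."""

    ends: np.ndarray  # ascending, last value == chromosome length in cM
    origins: np.ndarray  # int8, 0 = recurrent, 1 = donor


def _pure(length_cm: float, origin: int) -> Haplotype:
    return Haplotype(np.array([length_cm]), np.array([origin], dtype=np.int8))


@dataclass(frozen=True)
class PlantedQtl:
    trait_id: str
    marker_id: str
    additive: float  # donor-homozygote minus recurrent-homozygote class means
    dominance: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_chromosomes: int = 12
    markers_per_chromosome: int = 260
    chrom_length_cm: float = 100.0
    chrom_length_bp: int = 65_000_000
    n_lines: int = 141
    n_backcrosses: int = 3
    n_selfings: int = 10
    make_hybrids: bool = False
    planted_qtls: tuple[PlantedQtl, ...] = ()
    n_replicates: int = 3
    noise_sd: float = 1.0
    baseline: float = 100.0
    missing_rate: float = 0.0
    control_line_id: str = "RP"

    def __post_init__(self) -> None:
        if self.n_backcrosses < 0 or self.n_selfings < 0:
            raise ValueError("generation counts must be >= 0")
        if not all(np.isfinite([q.additive for q in self.planted_qtls])):
            raise ValueError("planted QTL effects must be finite")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrueSegment:
    line_id: str
    chromosome: str
    start_cm: float
    end_cm: float
    start_bp: int
    end_bp: int
    zygosity: str


@dataclass(frozen=True)
class SimTruth:
    segments: tuple[TrueSegment, ...]
    qtls: tuple[PlantedQtl, ...]


@dataclass(frozen=True)
class SimulationResult:
    genotypes: pd.DataFrame = field(repr=False)
    hybrid_genotypes: pd.DataFrame | None = field(repr=False)
    marker_map: MarkerMap
    chromosome_table: ChromosomeTable
    marker_cm: dict[str, np.ndarray]
    truth: SimTruth
    config: SimulationConfig


def simulate_gamete(
    hap_a: Haplotype, hap_b: Haplotype, length_cm: float, rng: np.random.Generator
) -> Haplotype:
    """One meiotic product of a diploid chromosome (Haldane model).

    Crossover count ~ Poisson(length/100), breakpoints uniform in cM, phase
    chosen fairly at the chromosome start. Identical homologs short-circuit:
    the gamete equals the shared haplotype whatever the crossovers do.
    """
    if np.array_equal(hap_a.ends, hap_b.ends) and np.array_equal(
        hap_a.origins, hap_b.origins
    ):
        return hap_a
    n_x = int(rng.poisson(length_cm / 100.0))
    phase = int(rng.integers(2))
    if n_x == 0:
        return hap_a if phase == 0 else hap_b
    xs = np.sort(rng.uniform(0.0, length_cm, n_x))
    cuts = np.unique(np.concatenate([xs, hap_a.ends, hap_b.ends]))
    mids = (np.concatenate([[0.0], cuts[:-1]]) + cuts) / 2.0
    active = (phase + np.searchsorted(xs, mids)) % 2
    o_a = hap_a.origins[np.searchsorted(hap_a.ends, mids)]
    o_b = hap_b.origins[np.searchsorted(hap_b.ends, mids)]
    origins = np.where(active == 0, o_a, o_b).astype(np.int8)
    keep = np.flatnonzero(np.r_[origins[1:] != origins[:-1], True])
    return Haplotype(cuts[keep], origins[keep])


def _gamete(genome: list[tuple[Haplotype, Haplotype]], lengths: Sequence[float], rng) -> list[Haplotype]:
    return [simulate_gamete(h1, h2, L, rng) for (h1, h2), L in zip(genome, lengths)]


def _origins_at(hap: Haplotype, positions_cm: np.ndarray) -> np.ndarray:
    idx = np.minimum(np.searchsorted(hap.ends, positions_cm), len(hap.ends) - 1)
    return hap.origins[idx]


def default_marker_map(config: SimulationConfig) -> tuple[MarkerMap, ChromosomeTable, dict[str, np.ndarray]]:
    """Evenly spaced markers on equally sized chromosomes."""
    rows = []
    marker_cm: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    n = config.markers_per_chromosome
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        frac = (np.arange(n) + 0.5) / n
        cm = frac * config.chrom_length_cm
        bp = np.rint(frac * config.chrom_length_bp).astype(np.int64)
        bp = np.maximum(bp, np.arange(n) + 1)  # strictly increasing, >= 1
        marker_cm[chrom] = cm
        lengths[chrom] = config.chrom_length_bp
        for i in range(n):
            rows.append((f"{chrom}_m{i + 1:04d}", chrom, int(bp[i])))
    mm = MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"]))
    return mm, ChromosomeTable(lengths), marker_cm


def _cm_to_bp(cm: float, length_cm: float, length_bp: int) -> int:
    if length_cm <= 0:
        return 1
    return int(round(cm / length_cm * length_bp))


def _diploid_truth(
    line_id: str,
    chrom: str,
    h1: Haplotype,
    h2: Haplotype,
    length_cm: float,
    length_bp: int,
) -> list[TrueSegment]:
    cuts = np.unique(np.concatenate([h1.ends, h2.ends]))
    mids = (np.concatenate([[0.0], cuts[:-1]]) + cuts) / 2.0
    state = _origins_at(h1, mids).astype(int) + _origins_at(h2, mids).astype(int)
    segments: list[TrueSegment] = []
    starts = np.concatenate([[0.0], cuts[:-1]])
    i = 0
    m = len(cuts)
    while i < m:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < m and state[j + 1] > 0:
            j += 1
        piece = state[i : j + 1]
        if np.all(piece == 2):
            zyg = "homozygous"
        elif np.all(piece == 1):
            zyg = "heterozygous"
        else:
            zyg = "mixed"
        s_cm, e_cm = float(starts[i]), float(cuts[j])
        segments.append(
            TrueSegment(
                line_id=line_id,
                chromosome=chrom,
                start_cm=s_cm,
                end_cm=e_cm,
                start_bp=max(1, _cm_to_bp(s_cm, length_cm, length_bp) + 1),
                end_bp=min(length_bp, max(1, _cm_to_bp(e_cm, length_cm, length_bp))),
                zygosity=zyg,
            )
        )
        i = j + 1
    return segments


def simulate_population(config: SimulationConfig) -> SimulationResult:
    """Simulate the full breeding scheme and read genotypes at the markers."""
    rng = np.random.default_rng(config.seed)
    marker_map, chrom_table, marker_cm = default_marker_map(config)
    chroms = marker_map.chromosomes
    lengths = [config.chrom_length_cm] * len(chroms)

    line_ids = [f"L{i + 1:03d}" for i in range(config.n_lines)]
    genomes: list[list[tuple[Haplotype, Haplotype]]] = []
    for _ in line_ids:
        plant = [
            (_pure(L, 1), _pure(L, 0)) for L in lengths
        ]  # F1: one donor and one recurrent haplotype per chromosome
        for _ in range(config.n_backcrosses):
            g = _gamete(plant, lengths, rng)
            plant = [(hap, _pure(L, 0)) for hap, L in zip(g, lengths)]
        for _ in range(config.n_selfings):
            g1 = _gamete(plant, lengths, rng)
            g2 = _gamete(plant, lengths, rng)
            plant = list(zip(g1, g2))
        genomes.append(plant)

    code = np.array(["A", "H", "B"])
    calls = np.empty((config.n_lines, marker_map.n_markers), dtype="U1")
    col0 = 0
    for c, chrom in enumerate(chroms):
        cm = marker_cm[chrom]
        ncol = len(cm)
        for i, plant in enumerate(genomes):
            h1, h2 = plant[c]
            dose = _origins_at(h1, cm).astype(int) + _origins_at(h2, cm).astype(int)
            calls[i, col0 : col0 + ncol] = code[dose]
        col0 += ncol
    genotypes = pd.DataFrame(calls, index=line_ids, columns=marker_map.marker_ids)

    truth_segments: list[TrueSegment] = []
    for i, line_id in enumerate(line_ids):
        for c, chrom in enumerate(chroms):
            h1, h2 = genomes[i][c]
            truth_segments.extend(
                _diploid_truth(
                    line_id, chrom, h1, h2, config.chrom_length_cm, config.chrom_length_bp
                )
            )

    hybrids: pd.DataFrame | None = None
    if config.make_hybrids:
        hcalls = np.empty_like(calls)
        for i, plant in enumerate(genomes):
            g = _gamete(plant, lengths, rng)
            col0 = 0
            for c, chrom in enumerate(chroms):
                cm = marker_cm[chrom]
                dose = _origins_at(g[c], cm).astype(int)  # second haplotype is recurrent
                hcalls[i, col0 : col0 + len(cm)] = code[dose]
                col0 += len(cm)
        hybrids = pd.DataFrame(
            hcalls, index=[f"{l}xRP" for l in line_ids], columns=marker_map.marker_ids
        )

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        masked = genotypes.to_numpy(dtype="U1")
        masked[mask] = "U"
        genotypes = pd.DataFrame(masked, index=line_ids, columns=marker_map.marker_ids)

    return SimulationResult(
        genotypes=genotypes,
        hybrid_genotypes=hybrids,
        marker_map=marker_map,
        chromosome_table=chrom_table,
        marker_cm=marker_cm,
        truth=SimTruth(segments=tuple(truth_segments), qtls=config.planted_qtls),
        config=config,
    )


_DOSE = {"A": 0.0, "H": 0.5, "B": 1.0, "U": 0.0}


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    config: SimulationConfig,
    *,
    seed: int | None = None,
    n_null_traits: int = 0,
    include_control: bool = True,
) -> pd.DataFrame:
    """Additive phenotypes with replicate noise for the given genotype matrix.

    ``n_null_traits`` appends traits with no genetic effect (pure noise around
    the baseline), used for calibration studies.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    for q in config.planted_qtls:
        if q.marker_id not in genotypes.columns:
            raise ValueError(f"planted QTL marker {q.marker_id!r} not in marker map")

    lines = [str(l) for l in genotypes.index]
    if include_control:
        lines = lines + [config.control_line_id]
    traits: dict[str, np.ndarray] = {}
    for q in config.planted_qtls:
        dose = np.array(
            [_DOSE[c] for c in genotypes[q.marker_id]] + ([0.0] if include_control else [])
        )
        g = q.additive * dose + q.dominance * (dose == 0.5)
        traits.setdefault(q.trait_id, np.zeros(len(lines)))
        traits[q.trait_id] = traits[q.trait_id] + g
    for k in range(n_null_traits):
        traits[f"null{k + 1:04d}"] = np.zeros(len(lines))

    rows = []
    for trait_id, g in traits.items():
        noise = rng.normal(0.0, config.noise_sd, size=(len(lines), config.n_replicates))
        values = config.baseline + g[:, None] + noise
        for i, line in enumerate(lines):
            for r in range(config.n_replicates):
                rows.append((line, trait_id, r + 1, values[i, r]))
    return pd.DataFrame(rows, columns=["line_id", "trait_id", "replicate", "value"])
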
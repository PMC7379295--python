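"""Genetic map construction from bin genotypes.

Recombination fractions between adjacent bins are estimated from the fraction
of lines whose donor-vs-recurrent state differs (heterozygous calls collapse
to the donor state: in a near-homozygous BIL population and its uniformly
heterozygous hybrid derivative, an H call carries the donor breakpoint
information). Distances come from a map function (Haldane by default,
Kosambi selectable).

Linkage groups: a chromosome is split wherever adjacent bins share no donor
coverage — no line carries the donor state at both bins, so there is no
linkage information bridging the interval — or where the recombination
fraction reaches 1/2. Uncovered (all-recurrent) bins therefore form their own
zero-length groups that are positioned on the physical scale only.

The estimator makes no correction for map expansion accumulated over the
backcross/selfing generations by default; an inverse Haldane–Waddington
selfed-RIL correction r = R / (2(1 - R)) can be opted in, but the breeding
design's exact expansion factor depends on the full crossing history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bins import Bin

__all__ = [
    "donor_state",
    "estimate_rf",
    "expected_observed_rf",
    "design_rf_corrector",
    "correct_rf_selfing",
    "map_distance",
    "distance_to_rf",
    "build_map",
    "GeneticMap",
    "LinkageGroup",
]

_STATE = {"A": 0.0, "B": 1.0, "H": 1.0, "U": np.nan}


def donor_state(calls: Sequence[str]) -> np.ndarray:
    """Collapse {A,B,H,U} calls to donor-state {0, 1, nan}."""
    arr = np.asarray(list(calls), dtype="U1")
    out = np.full(arr.shape, np.nan)
    for code, val in _STATE.items():
        out[arr == code] = val
    return out


def estimate_rf(col_a: Sequence[str], col_b: Sequence[str]) -> tuple[float, int]:
    """Recombination fraction between two loci from per-line calls.

    Returns ``(rf, n_informative)`` where rf = (# lines whose non-missing
    calls differ in donor state) / (# lines non-missing at both loci), capped
    at 1/2. rf is nan when no line is informative.
    """
    a = donor_state(col_a)
    b = donor_state(col_b)
    if a.shape != b.shape:
        raise ValueError("columns differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    n = int(ok.sum())
    if n == 0:
        return (float("nan"), 0)
    rf = float(np.mean(a[ok] != b[ok]))
    return (min(rf, 0.5), n)


def correct_rf_selfing(rf: float) -> float:
    """Invert the Haldane–Waddington selfed-RIL relation R = 2r/(1+2r)."""
    if math.isnan(rf):
        return rf
    if rf >= 0.5:
        return 0.5
    return min(rf / (2.0 * (1.0 - rf)), 0.5)


def expected_observed_rf(r: float, n_backcrosses: int, n_selfings: int) -> float:
    """Expected discordance fraction between two loci in finished lines.

    Exact two-locus recursion through the breeding scheme: an F1 is
    backcrossed ``n_backcrosses`` times to the recurrent parent, then selfed
    ``n_selfings`` times by single-seed descent, with meiotic recombination
    fraction ``r`` between the loci. The returned value is the probability
    that the donor-carrier state (>= 1 donor allele, i.e. the H-collapsed
    call) differs between the loci — which is what :func:`estimate_rf`
    measures. Because backcrossing dilutes donor material and selfing can fix
    residual segments back to the recurrent allele, this is *smaller* than
    ``r`` for this design (map contraction), unlike the classic selfed-RIL
    expansion.
    """
    # haplotypes encoded 0..3: bit0 = donor at locus 1, bit1 = donor at locus 2
    gdist = np.zeros((4, 4, 4))  # parent (h1, h2) -> gamete distribution
    for h1 in range(4):
        for h2 in range(4):
            rec1 = (h1 & 1) | (h2 & 2)
            rec2 = (h2 & 1) | (h1 & 2)
            for h, w in ((h1, (1 - r) / 2), (h2, (1 - r) / 2), (rec1, r / 2), (rec2, r / 2)):
                gdist[h1, h2, h] += w

    plant = np.zeros((4, 4))
    plant[3, 0] = 1.0  # F1: one full-donor, one full-recurrent haplotype
    for _ in range(n_backcrosses):
        g = np.einsum("ab,abh->h", plant, gdist)
        plant = np.zeros((4, 4))
        plant[:, 0] = g  # cross to recurrent parent (haplotype 0)
    for _ in range(n_selfings):
        # both gametes are drawn from the same parent plant
        plant = np.einsum("ab,abh,abk->hk", plant, gdist, gdist)
    out = 0.0
    for h1 in range(4):
        for h2 in range(4):
            carrier1 = bool((h1 | h2) & 1)
            carrier2 = bool((h1 | h2) & 2)
            if carrier1 != carrier2:
                out += plant[h1, h2]
    return float(out)


def design_rf_corrector(n_backcrosses: int, n_selfings: int, n_grid: int = 256):
    """Numeric inverse of :func:`expected_observed_rf` for a fixed design.

    Returns a callable mapping an observed discordance fraction back to the
    meiotic recombination fraction (clipped to [0, 0.5]).
    """
    r_grid = np.linspace(0.0, 0.5, n_grid)
    obs = np.array([expected_observed_rf(r, n_backcrosses, n_selfings) for r in r_grid])

    def invert(rf_observed: float) -> float:
        if math.isnan(rf_observed):
            return rf_observed
        if rf_observed >= obs[-1]:
            return 0.5
        return float(np.interp(rf_observed, obs, r_grid))

    return invert


def map_distance(rf: float, map_function: str = "haldane") -> float:
    """Convert a recombination fraction to centiMorgans."""
    if math.isnan(rf):
        return float("nan")
    if rf < 0:
        raise ValueError("rf must be >= 0")
    if rf >= 0.5:
        return float("inf")
    if map_function == "haldane":
        return -50.0 * math.log(1.0 - 2.0 * rf)
    if map_function == "kosambi":
        return 25.0 * math.log((1.0 + 2.0 * rf) / (1.0 - 2.0 * rf))
    raise ValueError(f"unknown map function {map_function!r}")


def distance_to_rf(d_cm: float, map_function: str = "haldane") -> float:
    """Inverse map function: expected recombination fraction at d centiMorgans."""
    if d_cm < 0:
        raise ValueError("distance must be >= 0")
    if map_function == "haldane":
        return 0.5 * (1.0 - math.exp(-d_cm / 50.0))
    if map_function == "kosambi":
        return 0.5 * math.tanh(d_cm / 50.0)
    raise ValueError(f"unknown map function {map_function!r}")


@dataclass(frozen=True)
class LinkageGroup:
    group_id: str
    chromosome: str
    bin_ids: tuple[str, ...]
    cum_cm: tuple[float, ...]

    @property
    def length_cm(self) -> float:
        return self.cum_cm[-1] if self.cum_cm else 0.0

    @property
    def n_bins(self) -> int:
        return len(self.bin_ids)


@dataclass(frozen=True)
class GeneticMap:
    groups: tuple[LinkageGroup, ...]
    map_function: str = "haldane"

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def total_length_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))

    def position(self, bin_id: str) -> tuple[str, float]:
        """(group_id, cumulative cM) of a bin."""
        for g in self.groups:
            if bin_id in g.bin_ids:
                return (g.group_id, g.cum_cm[g.bin_ids.index(bin_id)])
        raise KeyError(bin_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for bin_id, cm in zip(g.bin_ids, g.cum_cm):
                rows.append((g.group_id, g.chromosome, bin_id, cm))
        return pd.DataFrame(rows, columns=["group_id", "chromosome", "bin_id", "cm"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, map_function: str = "haldane") -> "GeneticMap":
        groups = []
        for gid, sub in df.groupby("group_id", sort=False):
            groups.append(
                LinkageGroup(
                    group_id=str(gid),
                    chromosome=str(sub["chromosome"].iloc[0]),
                    bin_ids=tuple(sub["bin_id"].astype(str)),
                    cum_cm=tuple(float(x) for x in sub["cm"]),
                )
            )
        return cls(groups=tuple(groups), map_function=map_function)


def build_map(
    bin_genotypes: pd.DataFrame,
    bins: Sequence[Bin],
    *,
    map_function: str = "haldane",
    rf_correction: str | None = None,
    design: tuple[int, int] = (3, 10),
) -> GeneticMap:
    """Chain adjacent-bin recombination fractions into a genetic map.

    Parameters
    ----------
    bin_genotypes
        Lines x bins call matrix from the bin builder (columns ordered as
        ``bins``).
    rf_correction
        ``None`` (default): use the observed discordance fraction as-is.
        ``"selfing-ril"``: inverse Haldane–Waddington selfed-RIL relation.
        ``"design"``: exact two-locus inversion for a backcross+selfing
        design given by ``design = (n_backcrosses, n_selfings)``.
    """
    by_chrom: dict[str, list[Bin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chromosome, []).append(b)

    states = {b.bin_id: donor_state(bin_genotypes[b.bin_id].to_numpy()) for b in bins}

    if rf_correction == "design":
        invert = design_rf_corrector(*design)
    elif rf_correction not in (None, "selfing-ril"):
        raise ValueError(f"unknown rf correction {rf_correction!r}")

    groups: list[LinkageGroup] = []
    counter = 0

    def _close(chrom: str, ids: list[str], cms: list[float]) -> None:
        nonlocal counter
        counter += 1
        groups.append(
            LinkageGroup(
                group_id=f"LG{counter:02d}",
                chromosome=chrom,
                bin_ids=tuple(ids),
                cum_cm=tuple(cms),
            )
        )

    for chrom, chrom_bins in by_chrom.items():
        ids = [chrom_bins[0].bin_id]
        cms = [0.0]
        for prev, cur in zip(chrom_bins[:-1], chrom_bins[1:]):
            a = states[prev.bin_id]
            b = states[cur.bin_id]
            ok = ~(np.isnan(a) | np.isnan(b))
            n_informative = int(ok.sum())
            bridge = int(np.sum((a == 1.0) & (b == 1.0)))
            rf, _ = estimate_rf(
                bin_genotypes[prev.bin_id].to_numpy(),
                bin_genotypes[cur.bin_id].to_numpy(),
            )
            if n_informative == 0 or bridge == 0 or rf >= 0.5:
                _close(chrom, ids, cms)
                ids = [cur.bin_id]
                cms = [0.0]
                continue
            if rf_correction == "selfing-ril":
                rf = correct_rf_selfing(rf)
            elif rf_correction == "design":
                rf = invert(rf)
            ids.append(cur.bin_id)
            cms.append(cms[-1] + map_distance(rf, map_function))
        _close(chrom, ids, cms)

    return GeneticMap(groups=tuple(groups), map_function=map_function)
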
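"""Donor introgression calling from per-line SNP genotype vectors.

A backcross inbred line carries a handful of wild-species (donor) segments in
a recurrent-parent background. A segment is a maximal run of donor-informative
calls (``B`` or ``H``); missing calls (``U``) are transparent — they neither
break nor extend a run. Segment borders follow the half-way convention: an
interior border sits at the floor of the midpoint between the outermost
donor-informative marker and the nearest flanking recurrent (``A``) marker.
If a run reaches the first or last informative marker of a chromosome, the
border extends to the chromosome tip (position 1 or the chromosome length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ChromosomeTable, MarkerMap

logger = logging.getLogger(__name__)

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
MIXED = "mixed"

__all__ = [
    "IntrogressionSegment",
    "PopulationSummary",
    "call_segments",
    "call_all_segments",
    "summarize_population",
    "segments_frame",
    "segments_to_bed",
]


@dataclass(frozen=True)
class IntrogressionSegment:
    """One donor segment in one line, closed 1-based bp interval."""

    line_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    zygosity: str
    n_markers: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start_bp must be <= end_bp")
        if self.start_bp < 1:
            raise ValueError("segment start_bp must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def call_segments(
    calls: Sequence[str],
    positions: Sequence[int],
    chromosome_length: int,
    *,
    line_id: str = "",
    chromosome: str = "",
) -> list[IntrogressionSegment]:
    """Call donor segments on one chromosome of one line.

    Parameters
    ----------
    calls
        Per-marker codes in {A,B,H,U}, position-sorted.
    positions
        1-based bp marker positions, strictly increasing, within
        ``chromosome_length``.
    """
    calls_arr = np.asarray(list(calls), dtype="U1")
    pos = np.asarray(positions, dtype=np.int64)
    if calls_arr.shape != pos.shape:
        raise ValueError("calls and positions differ in length")
    if len(pos) and pos[-1] > chromosome_length:
        raise ValueError("marker position exceeds chromosome length")

    informative = calls_arr != "U"
    if not informative.any():
        logger.warning(
            "chromosome %s of line %s has no non-missing calls; no segments called",
            chromosome,
            line_id,
        )
        return []
    icalls = calls_arr[informative]
    ipos = pos[informative]
    donor = (icalls == "B") | (icalls == "H")

    segments: list[IntrogressionSegment] = []
    m = len(icalls)
    i = 0
    while i < m:
        if not donor[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and donor[j + 1]:
            j += 1
        # interior borders sit half-way between the outermost donor marker and
        # the nearest flanking recurrent marker; the start side takes the bp
        # after the floor midpoint so that adjacent segment and bin intervals
        # tile without overlap (a deterministic 1-bp convention)
        start = 1 if i == 0 else int((ipos[i - 1] + ipos[i]) // 2) + 1
        end = int(chromosome_length) if j == m - 1 else int((ipos[j] + ipos[j + 1]) // 2)
        run = icalls[i : j + 1]
        if np.all(run == "B"):
            zygosity = HOMOZYGOUS
        elif np.all(run == "H"):
            zygosity = HETEROZYGOUS
        else:
            zygosity = MIXED
        segments.append(
            IntrogressionSegment(
                line_id=str(line_id),
                chromosome=str(chromosome),
                start_bp=start,
                end_bp=end,
                zygosity=zygosity,
                n_markers=int(j - i + 1),
            )
        )
        i = j + 1
    return segments


def call_all_segments(
    genotypes: pd.DataFrame,
    marker_map: MarkerMap,
    chromosome_table: ChromosomeTable,
) -> list[IntrogressionSegment]:
    """Call segments for every line and chromosome of a genotype matrix."""
    chromosome_table.validate_covers(marker_map)
    out: list[IntrogressionSegment] = []
    chrom_col = marker_map.frame["chromosome"].to_numpy()
    values = genotypes.to_numpy(dtype="U1")
    for chrom in marker_map.chromosomes:
        sel = chrom_col == chrom
        positions = marker_map.frame.loc[sel, "position_bp"].to_numpy()
        block = values[:, sel]
        length = chromosome_table[chrom]
        for row, line_id in enumerate(genotypes.index):
            out.extend(
                call_segments(
                    block[row],
                    positions,
                    length,
                    line_id=str(line_id),
                    chromosome=chrom,
                )
            )
    return out


@dataclass(frozen=True)
class PopulationSummary:
    """Population-level introgression statistics.

    Per-line means/medians are taken over lines that carry at least one
    segment; lines without any donor segment are counted but excluded from
    those averages. ``genome_coverage_fraction`` is the union of all segments
    across lines divided by the total genome length.
    """

    n_lines_total: int
    n_lines_with_segment: int
    n_lines_without: int
    mean_segments_per_line: float
    max_segments_per_line: int
    mean_sum_length_bp: float
    median_sum_length_bp: float
    mean_segment_length_bp: float
    genome_coverage_fraction: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by a set of closed intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in ivs:
        if cur_start is None:
            cur_start, cur_end = s, e
        elif s <= cur_end + 1:
            cur_end = max(cur_end, e)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    if cur_start is not None:
        total += cur_end - cur_start + 1
    return total


def summarize_population(
    segments: Sequence[IntrogressionSegment],
    n_lines_total: int,
    chromosome_table: ChromosomeTable,
) -> PopulationSummary:
    per_line: dict[str, list[IntrogressionSegment]] = {}
    for seg in segments:
        per_line.setdefault(seg.line_id, []).append(seg)

    n_with = len(per_line)
    counts = np.array([len(v) for v in per_line.values()], dtype=float)
    sums = np.array(
        [sum(s.length_bp for s in v) for v in per_line.values()], dtype=float
    )
    lengths = np.array([s.length_bp for s in segments], dtype=float)

    covered = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append((seg.start_bp, seg.end_bp))
    for ivs in by_chrom.values():
        covered += _union_length(ivs)

    return PopulationSummary(
        n_lines_total=int(n_lines_total),
        n_lines_with_segment=n_with,
        n_lines_without=int(n_lines_total) - n_with,
        mean_segments_per_line=float(counts.mean()) if n_with else 0.0,
        max_segments_per_line=int(counts.max()) if n_with else 0,
        mean_sum_length_bp=float(sums.mean()) if n_with else 0.0,
        median_sum_length_bp=float(np.median(sums)) if n_with else 0.0,
        mean_segment_length_bp=float(lengths.mean()) if len(lengths) else 0.0,
        genome_coverage_fraction=covered / chromosome_table.total_bp,
    )


def segments_frame(segments: Sequence[IntrogressionSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "line_id": [s.line_id for s in segments],
            "chromosome": [s.chromosome for s in segments],
            "start_bp": [s.start_bp for s in segments],
            "end_bp": [s.end_bp for s in segments],
            "zygosity": [s.zygosity for s in segments],
            "n_markers": [s.n_markers for s in segments],
        }
    )


def segments_to_bed(segments: Sequence[IntrogressionSegment]) -> pd.DataFrame:
    """BED-style view (0-based half-open); conversion happens only here."""
    df = segments_frame(segments)
    return pd.DataFrame(
        {
            "chrom": df["chromosome"],
            "chromStart": df["start_bp"] - 1,
            "chromEnd": df["end_bp"],
            "name": df["line_id"] + ":" + df["zygosity"],
        }
    )
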
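"""Mapping bins: maximal runs of markers with no recombination between them.

Adjacent markers whose genotype columns are compatible in every line are
merged into one bin. A missing call is a wildcard: it matches any call, and
the bin's consensus takes the non-missing call for that line. Merging is a
greedy left-to-right scan anchored on the running consensus (the wildcard
relation is not transitive, so the scan order is part of the definition).

Bin bp intervals tile each chromosome completely: interior boundaries are the
floor midpoints between the bounding markers of adjacent bins, terminal bins
extend to the chromosome tips — the same convention the introgression caller
uses for segment borders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ChromosomeTable, MarkerMap

__all__ = ["Bin", "BinSummary", "build_bins", "bin_summary", "bin_genotype_matrix", "bins_frame", "read_bins"]


@dataclass(frozen=True)
class Bin:
    bin_id: str
    chromosome: str
    marker_ids: tuple[str, ...]
    start_bp: int
    end_bp: int
    n_snps: int
    consensus: tuple[str, ...] | None = None  # per-line call, genotype row order

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _compatible(consensus: np.ndarray, column: np.ndarray) -> bool:
    return bool(np.all((consensus == column) | (consensus == "U") | (column == "U")))


def build_bins(
    genotypes: pd.DataFrame,
    marker_map: MarkerMap,
    chromosome_table: ChromosomeTable,
) -> list[Bin]:
    """Partition the mapped markers of every chromosome into bins."""
    chromosome_table.validate_covers(marker_map)
    values = genotypes.to_numpy(dtype="U1")
    chrom_col = marker_map.frame["chromosome"].to_numpy()
    pos_col = marker_map.frame["position_bp"].to_numpy()
    marker_ids = np.asarray(marker_map.marker_ids)

    bins: list[Bin] = []
    for chrom in marker_map.chromosomes:
        sel = np.flatnonzero(chrom_col == chrom)
        block = values[:, sel]
        positions = pos_col[sel]
        ids = marker_ids[sel]

        runs: list[tuple[int, int, np.ndarray]] = []  # (first, last, consensus)
        start = 0
        consensus = block[:, 0].copy()
        for k in range(1, len(sel)):
            col = block[:, k]
            if _compatible(consensus, col):
                consensus = np.where(consensus == "U", col, consensus)
            else:
                runs.append((start, k - 1, consensus))
                start = k
                consensus = col.copy()
        runs.append((start, len(sel) - 1, consensus))

        # physical boundaries: midpoints between adjacent bins' bounding markers
        length = chromosome_table[chrom]
        starts = [1]
        ends: list[int] = []
        for (_, last, _), (nxt_first, _, _) in zip(runs[:-1], runs[1:]):
            mid = int((positions[last] + positions[nxt_first]) // 2)
            ends.append(mid)
            starts.append(mid + 1)
        ends.append(int(length))

        for k, ((first, last, consensus), s, e) in enumerate(zip(runs, starts, ends), start=1):
            bins.append(
                Bin(
                    bin_id=f"{chrom}.b{k:03d}",
                    chromosome=chrom,
                    marker_ids=tuple(ids[first : last + 1]),
                    start_bp=s,
                    end_bp=e,
                    n_snps=last - first + 1,
                    consensus=tuple(consensus),
                )
            )
    return bins


@dataclass(frozen=True)
class BinSummary:
    n_bins: int
    mean_length_bp: float
    mean_snps_per_bin: float


def bin_summary(bins: Sequence[Bin]) -> BinSummary:
    if not bins:
        raise ValueError("cannot summarize an empty bin list")
    lengths = np.array([b.length_bp for b in bins], dtype=float)
    snps = np.array([b.n_snps for b in bins], dtype=float)
    return BinSummary(
        n_bins=len(bins),
        mean_length_bp=float(lengths.mean()),
        mean_snps_per_bin=float(snps.mean()),
    )


def bin_genotype_matrix(bins: Sequence[Bin], line_ids: Sequence[str]) -> pd.DataFrame:
    """Lines x bins consensus-call matrix, same dialect as the genotype matrix."""
    data = {}
    for b in bins:
        if b.consensus is None:
            raise ValueError(f"bin {b.bin_id} has no consensus column")
        data[b.bin_id] = list(b.consensus)
    return pd.DataFrame(data, index=[str(x) for x in line_ids])


def bins_frame(bins: Sequence[Bin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_id": [b.bin_id for b in bins],
            "chromosome": [b.chromosome for b in bins],
            "start_bp": [b.start_bp for b in bins],
            "end_bp": [b.end_bp for b in bins],
            "n_snps": [b.n_snps for b in bins],
            "marker_ids": [",".join(b.marker_ids) for b in bins],
        }
    )


def read_bins(path) -> list[Bin]:
    """Read a bins table written from :func:`bins_frame` (no consensus)."""
    df = pd.read_csv(path, sep="\t", dtype={"bin_id": str, "chromosome": str})
    return [
        Bin(
            bin_id=row.bin_id,
            chromosome=row.chromosome,
            marker_ids=tuple(str(row.marker_ids).split(",")),
            start_bp=int(row.start_bp),
            end_bp=int(row.end_bp),
            n_snps=int(row.n_snps),
        )
        for row in df.itertuples()
    ]
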
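"""Tabular I/O for genotypes, marker maps, chromosome lengths and phenotypes.

Every file handled here is a plain tab-separated table. Genotype calls use a
four-letter alphabet:

====  ==========================================
code  meaning
====  ==========================================
A     homozygous for the recurrent-parent allele
B     homozygous for the donor (wild) allele
H     heterozygous
U     missing / uncalled
====  ==========================================

Source files that use a different encoding (e.g. parental letters or dashes)
are translated through an explicit recoding map at read time. Physical
coordinates are 1-based inclusive base pairs throughout the package.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPE_CODES: tuple[str, ...] = ("A", "B", "H", "U")

__all__ = [
    "GENOTYPE_CODES",
    "FormatError",
    "MarkerMap",
    "ChromosomeTable",
    "read_marker_map",
    "read_chromosome_lengths",
    "read_genotypes",
    "validate_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "line_means",
]


class FormatError(ValueError):
    """A file's structure does not match the expected table layout."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered SNP markers with chromosome assignment and physical position.

    The frame has columns ``marker_id``, ``chromosome``, ``position_bp`` and is
    the coordinate backbone for every downstream module: genotype matrices are
    validated against it and all segment/bin coordinates derive from it.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["marker_id", "chromosome", "position_bp"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise FormatError(f"marker map is missing columns: {missing}")
        df = self.frame.reset_index(drop=True)[required].copy()
        df["marker_id"] = df["marker_id"].astype(str)
        df["chromosome"] = df["chromosome"].astype(str)
        df["position_bp"] = df["position_bp"].astype(np.int64)
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise FormatError(f"duplicate marker id {dup!r} in marker map")
        if (df["position_bp"] < 1).any():
            raise FormatError("marker positions must be >= 1 (1-based bp)")
        for chrom, sub in df.groupby("chromosome", sort=False):
            pos = sub["position_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise FormatError(
                    f"marker positions on chromosome {chrom!r} are not "
                    "strictly increasing"
                )
        object.__setattr__(self, "frame", df)

    @property
    def marker_ids(self) -> list[str]:
        return self.frame["marker_id"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.frame["chromosome"]))

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def positions(self, chromosome: str) -> np.ndarray:
        sub = self.frame[self.frame["chromosome"] == str(chromosome)]
        return sub["position_bp"].to_numpy()

    def markers(self, chromosome: str) -> list[str]:
        sub = self.frame[self.frame["chromosome"] == str(chromosome)]
        return sub["marker_id"].tolist()


@dataclass(frozen=True)
class ChromosomeTable:
    """Chromosome lengths (bp) for the reference build."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {str(k): int(v) for k, v in dict(self.lengths).items()}
        if any(v < 1 for v in clean.values()):
            raise FormatError("chromosome lengths must be positive")
        object.__setattr__(self, "lengths", clean)

    def __getitem__(self, chromosome: str) -> int:
        return self.lengths[str(chromosome)]

    def __contains__(self, chromosome: str) -> bool:
        return str(chromosome) in self.lengths

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths.values()))

    def validate_covers(self, marker_map: MarkerMap) -> None:
        """Every mapped chromosome must exist and contain its markers."""
        for chrom in marker_map.chromosomes:
            if chrom not in self:
                raise FormatError(f"chromosome {chrom!r} absent from length table")
            max_pos = int(marker_map.positions(chrom).max())
            if self[chrom] < max_pos:
                raise FormatError(
                    f"chromosome {chrom!r} length {self[chrom]} < max marker "
                    f"position {max_pos}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chromosome": list(self.lengths), "length_bp": list(self.lengths.values())}
        )


def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df = df.rename(
        columns={df.columns[0]: "marker_id", df.columns[1]: "chromosome", df.columns[2]: "position_bp"}
    )
    return MarkerMap(df)


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    marker_map.frame.to_csv(path, sep="\t", index=False)


def read_chromosome_lengths(path: str | Path) -> ChromosomeTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return ChromosomeTable(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int))))


def write_chromosome_lengths(table: ChromosomeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def validate_genotypes(genotypes: pd.DataFrame, marker_map: MarkerMap) -> pd.DataFrame:
    """Check a lines x markers call matrix against the marker map.

    The matrix must contain exactly the mapped markers (any order); columns are
    returned reordered to map order. Calls outside ``GENOTYPE_CODES`` raise.
    """
    got = set(map(str, genotypes.columns))
    want = set(marker_map.marker_ids)
    if got != want:
        extra = sorted(got - want)[:5]
        missing = sorted(want - got)[:5]
        raise FormatError(
            f"genotype matrix marker set differs from marker map "
            f"(extra: {extra}, missing: {missing})"
        )
    df = genotypes.copy()
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise FormatError("duplicate line ids in genotype matrix")
    df = df[marker_map.marker_ids]
    df.index.name = "line_id"
    values = df.to_numpy(dtype="U8")
    bad = ~np.isin(values, GENOTYPE_CODES)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype call {values[i, j]!r} for line {df.index[i]!r}, marker "
            f"{df.columns[j]!r} is not one of {GENOTYPE_CODES}"
        )
    return df


def read_genotypes(
    path: str | Path,
    marker_map: MarkerMap,
    recode: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a lines x markers genotype TSV and validate it against the map.

    Layout: first row marker ids, first column line ids. ``recode`` translates
    a source dialect into the canonical {A,B,H,U} alphabet; symbols outside
    both the alphabet and the recoding map are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if recode:
        table = {str(k): str(v) for k, v in recode.items()}
        bad_targets = set(table.values()) - set(GENOTYPE_CODES)
        if bad_targets:
            raise ValueError(f"recoding map targets outside alphabet: {bad_targets}")

        def _translate(cell: str) -> str:
            if cell in GENOTYPE_CODES:
                return cell
            if cell in table:
                return table[cell]
            raise ValueError(f"genotype symbol {cell!r} not in alphabet or recoding map")

        df = df.map(_translate)
    return validate_genotypes(df, marker_map)


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="line_id")


_PHENO_COLS = ["line_id", "trait_id", "replicate", "value"]


def read_phenotypes(path: str | Path | _io.StringIO, layout: str = "long") -> pd.DataFrame:
    """Read a phenotype table into canonical long form.

    ``layout='long'`` expects columns (line_id, trait_id[, replicate], value);
    a missing replicate column is assigned 1..k per (line, trait).
    ``layout='wide'`` expects one line per row, one trait per column, a single
    implicit replicate. ``NA`` cells become missing values; they are retained
    in the table but excluded from all means downstream.
    """
    if layout == "long":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        df = df.rename(columns=dict(zip(df.columns[:2], ["line_id", "trait_id"])))
        if "value" not in df.columns:
            df = df.rename(columns={df.columns[-1]: "value"})
        if "replicate" not in df.columns:
            df["replicate"] = df.groupby(["line_id", "trait_id"]).cumcount() + 1
    elif layout == "wide":
        wide = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        wide.index = wide.index.astype(str)
        df = wide.stack(future_stack=True).rename("value").reset_index()
        df.columns = ["line_id", "trait_id", "value"]
        df["replicate"] = 1
    else:
        raise ValueError(f"unknown phenotype layout {layout!r}")
    df["line_id"] = df["line_id"].astype(str)
    df["trait_id"] = df["trait_id"].astype(str)
    df["replicate"] = df["replicate"].astype(np.int64)
    try:
        df["value"] = pd.to_numeric(df["value"])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric phenotype value: {exc}") from exc
    finite = df["value"].dropna()
    if not np.isfinite(finite).all():
        raise ValueError("phenotype values must be finite")
    if (finite < 0).any():
        raise ValueError("phenotype values are relative responses and must be >= 0")
    return df[_PHENO_COLS]


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path | None = None) -> str | None:
    """Write canonical long-form phenotypes; returns the TSV text if no path."""
    out = phenotypes[_PHENO_COLS]
    text = out.to_csv(path, sep="\t", index=False)
    return text


def line_means(phenotypes: pd.DataFrame, traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-line trait means over available replicates (missing values dropped)."""
    df = phenotypes
    if traits is not None:
        df = df[df["trait_id"].isin(list(traits))]
    means = df.pivot_table(index="line_id", columns="trait_id", values="value", aggfunc="mean")
    means.index = means.index.astype(str)
    return means
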
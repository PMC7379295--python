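"""Metabolite normalization: control-relative fold changes and log2 matrices.

Relative GC-MS responses are normalized per trait to the mean response of the
recurrent-parent control line. Zero raw responses are treated as non-detects
(missing), not literal zeros, so the log2 transform stays defined. Fold
changes are computed on line means over the available replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import line_means

logger = logging.getLogger(__name__)

__all__ = ["FoldChangeMatrix", "normalize_to_control", "heatmap_matrix", "fold_range"]


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Lines x traits fold changes relative to the control-line mean (linear)."""

    values: pd.DataFrame = field(repr=False)
    control_line_id: str
    transform: str = "linear"


def normalize_to_control(phenotypes: pd.DataFrame, control_line_id: str) -> FoldChangeMatrix:
    """Per trait, line mean divided by control-line mean.

    Traits whose control mean is missing or non-positive are dropped with a
    log entry. Raises if the control line is absent altogether.
    """
    phen = phenotypes.copy()
    phen.loc[phen["value"] == 0, "value"] = np.nan  # non-detects
    means = line_means(phen)
    control = str(control_line_id)
    if control not in means.index:
        raise ValueError(f"control line {control!r} absent from phenotype table")
    ctrl = means.loc[control]
    bad = ctrl.isna() | (ctrl <= 0)
    if bad.any():
        logger.info(
            "dropping %d trait(s) with missing/non-positive control mean: %s",
            int(bad.sum()),
            list(ctrl.index[bad])[:5],
        )
    keep = ctrl.index[~bad]
    fc = means[keep].div(ctrl[keep], axis=1)
    return FoldChangeMatrix(values=fc, control_line_id=control)


def heatmap_matrix(
    foldchanges: FoldChangeMatrix,
    line_order: list[str] | None = None,
    trait_order: list[str] | None = None,
) -> pd.DataFrame:
    """Elementwise log2 of a linear fold-change matrix, deterministically ordered.

    Rows default to sorted line ids (callers mapping lines to chromosomes can
    pass an explicit order); columns to sorted trait ids.
    """
    if foldchanges.transform != "linear":
        raise ValueError("heatmap_matrix expects a linear fold-change matrix")
    fc = foldchanges.values
    if (fc <= 0).any().any():
        raise ValueError("non-positive fold change; drop non-detects upstream")
    rows = line_order if line_order is not None else sorted(fc.index)
    cols = trait_order if trait_order is not None else sorted(fc.columns)
    return np.log2(fc.loc[rows, cols])


def fold_range(
    foldchanges: FoldChangeMatrix, *, include_control: bool = False
) -> tuple[float, float]:
    """Global (min, max) fold change over all line x trait cells.

    The control line's own row (identically 1) is excluded by default.
    """
    fc = foldchanges.values
    if not include_control and foldchanges.control_line_id in fc.index:
        fc = fc.drop(index=foldchanges.control_line_id)
    flat = fc.to_numpy(dtype=float).ravel()
    flat = flat[~np.isnan(flat)]
    if flat.size == 0:
        raise ValueError("fold-change matrix is empty")
    return (float(flat.min()), float(flat.max()))
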
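"""Curve-shape variables derived from per-block psychometric fits.

Turns raw fits into the analysis table used by all downstream statistics:
a combined lapse rate (the mean of the two asymptote deviations), validity
filtering on the fitted threshold, averaging of repeated blocks, and a PCA
composite that folds slope and both asymptotes into a single curve-shape
index.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psychometric import BlockData, FitResult


def combined_lapse(lower_asym: float, upper_asym_dev: float) -> float:
    """Average deviation of the two asymptotes from 0 and 1.

    A lower asymptote of 0.1 and an upper asymptote of 0.9 each correspond
    to a lapse rate of 0.1, so the two deviations are averaged into one
    lapse-rate summary.
    """
    return (lower_asym + upper_asym_dev) / 2.0


def filter_valid_fits(
    fits: list[FitResult], step_range: tuple[float, float] = (1.0, 7.0)
) -> tuple[list[FitResult], list[FitResult]]:
    """Partition fits by whether the fitted threshold lies on the continuum.

    A threshold outside the closed interval ``step_range`` means the category
    boundary was not captured by the stimulus range, so the block's shape
    parameters are not interpretable; such fits are excluded with a recorded
    reason.  Idempotent; kept and excluded partition the input.
    """
    lo, hi = step_range
    kept, excluded = [], []
    for fit in fits:
        m = fit.point_estimate.threshold
        if lo <= m <= hi:
            kept.append(fit)
        else:
            bad = copy.copy(fit)
            bad.excluded = True
            bad.exclusion_reason = f"threshold {m:.3f} outside [{lo}, {hi}]"
            excluded.append(bad)
    return kept, excluded


def shape_records(blocks: list[BlockData], fits: list[FitResult]) -> pd.DataFrame:
    """One row of shape parameters per (non-excluded) fitted block."""
    rows = []
    for block, fit in zip(blocks, fits):
        if fit.excluded:
            continue
        pe = fit.point_estimate
        rows.append(
            {
                "subject_id": block.subject_id,
                "continuum": block.continuum,
                "paradigm": block.paradigm,
                "block_index": block.block_index,
                "threshold": pe.threshold,
                "width": pe.width,
                "slope": fit.slope_at_threshold,
                "lower_asym": pe.lower_asym,
                "upper_asym_dev": pe.upper_asym_dev,
                "lapse": combined_lapse(pe.lower_asym, pe.upper_asym_dev),
            }
        )
    return pd.DataFrame(rows)


PARAM_COLS = ["threshold", "width", "slope", "lower_asym", "upper_asym_dev", "lapse"]


def aggregate_blocks(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average repeated blocks within each subject × continuum × paradigm cell.

    The two ABX blocks per continuum are averaged elementwise (a cell left
    with a single surviving block passes through with ``n_blocks_averaged``
    = 1); single-interval cells have one block each.  Also returns the
    per-subject grand mean over all blocks, the unit used for group effect
    sizes and discriminant classification.
    """
    cols = [c for c in PARAM_COLS if c in records.columns]
    cells = (
        records.groupby(["subject_id", "continuum", "paradigm"], as_index=False)
        .agg(**{c: (c, "mean") for c in cols}, n_blocks_averaged=("slope", "size"))
    )
    grand = records.groupby("subject_id", as_index=False).agg(
        **{c: (c, "mean") for c in cols}, n_blocks=("slope", "size")
    )
    return cells, grand


@dataclass
class PcaSummary:
    """First-principal-component summary of curve shape.

    Loadings are for the z-scored (slope, lower asymptote deviation, upper
    asymptote deviation) columns, sign-fixed so slope loads positively; the
    variance fraction is PC1's share of total variance.
    """

    loadings: np.ndarray
    variance_fraction: float
    scores: np.ndarray
    all_variance_fractions: np.ndarray


def shape_pca(records: pd.DataFrame) -> PcaSummary:
    """PCA of the z-scored slope and asymptote columns.

    Operates on the aggregated subject × continuum × paradigm records (the
    same unit as the mixed models).  Columns are standardized because slope
    and asymptote deviations live on incommensurate scales; PC1 is oriented
    so that steeper slopes score higher.
    """
    cols = ["slope", "lower_asym", "upper_asym_dev"]
    x = records[cols].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 records for PCA")
    sd = x.std(axis=0, ddof=1)
    degenerate = np.ptp(x, axis=0) == 0
    if np.any(degenerate):
        bad = [c for c, d in zip(cols, degenerate) if d]
        raise ValueError(f"constant column(s) {bad}: variance is degenerate")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    loadings = vt[0]
    if loadings[0] < 0:
        loadings = -loadings
    scores = z @ loadings
    return PcaSummary(
        loadings=loadings,
        variance_fraction=float(fractions[0]),
        scores=scores,
        all_variance_fractions=fractions,
    )


def attach_pc1(records: pd.DataFrame) -> tuple[pd.DataFrame, PcaSummary]:
    """Return a copy of ``records`` with a ``pc1`` column of PCA scores."""
    summary = shape_pca(records)
    out = records.copy()
    out["pc1"] = summary.scores
    return out, summary
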
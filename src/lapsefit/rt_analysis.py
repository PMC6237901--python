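"""Reaction-time processing and modeling.

Reaction times in categorization experiments are right-skewed and, over a
stimulus continuum that spans a category boundary, typically follow an
inverted-U profile: ambiguous center stimuli are answered more slowly than
unambiguous endpoints.  This module provides the range filter for spurious
presses and long pauses, per-subject quadratic profiles on an orthogonal
polynomial basis over continuum steps, a skewed-distribution mode summary
(shifted scaled chi-square fit), and the trial-level mixed model with the
reading-score × curvature interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reading_analysis import CoefTable, ModelSpec, fit_shape_model

#: closed inclusion bounds, in ms: below = spurious press, above = long pause
RT_BOUNDS = (200.0, 2000.0)


def filter_rts(records: pd.DataFrame, bounds: tuple[float, float] = RT_BOUNDS):
    """Partition trials at the closed reaction-time bounds.

    Returns ``(kept, removed_low, removed_high)`` plus a dict of removal
    fractions; rows with missing RT are counted separately under
    ``"missing"`` and dropped from all three partitions.
    """
    lo, hi = bounds
    rt = records["rt_ms"]
    missing = rt.isna()
    low = ~missing & (rt < lo)
    high = ~missing & (rt > hi)
    keep = ~missing & ~low & ~high
    fractions = {
        "kept": float(keep.mean()),
        "removed_low": float(low.mean()),
        "removed_high": float(high.mean()),
        "missing": float(missing.mean()),
    }
    return records[keep], records[low], records[high], fractions


def orthogonal_step_basis(steps: np.ndarray, weights: np.ndarray | None = None) -> pd.DataFrame:
    """Weighted orthogonal polynomial basis (constant, linear, quadratic).

    Built over the realized step design by Gram–Schmidt under the inner
    product weighted by trial counts, so filtered (unbalanced) designs keep
    the basis columns exactly orthogonal.  Columns are normalized to unit
    weighted norm, with the leading polynomial coefficient positive (the
    quadratic column curves upward, so a negative fitted coefficient means
    an inverted-U profile).
    """
    s = np.asarray(steps, dtype=float)
    uniq = np.unique(s)
    if uniq.size < 3:
        raise ValueError(f"need at least 3 distinct steps, got {uniq.size}")
    if weights is None:
        w = np.array([(s == u).sum() for u in uniq], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    cols = []
    for degree in range(3):
        v = uniq**degree
        for c in cols:
            v = v - np.sum(w * v * c) * c
        norm = np.sqrt(np.sum(w * v**2))
        v = v / norm
        if v[-1] < 0:  # fix sign: increasing / upward-curving orientation
            v = -v
        cols.append(v)
    return pd.DataFrame(
        {"poly0": cols[0], "poly1": cols[1], "poly2": cols[2]}, index=pd.Index(uniq, name="step")
    )


@dataclass
class QuadraticProfile:
    """Per-subject polynomial profile of reaction time over continuum steps."""

    intercept: float
    linear: float
    quadratic: float
    n_trials: int


def rt_quadratic_fit(records: pd.DataFrame) -> QuadraticProfile:
    """Least-squares quadratic profile of one subject's RTs over steps.

    Fit on the orthogonal basis over the realized (count-weighted) design;
    the quadratic coefficient is invariant to adding any constant or
    linear-in-step trend, and is negative for the expected inverted-U
    (slow center, fast endpoints) pattern.
    """
    basis = orthogonal_step_basis(records["step"].to_numpy())
    x = basis.loc[records["step"]].to_numpy()
    y = records["rt_ms"].to_numpy(dtype=float)
    coefs, *_ = np.linalg.lstsq(x, y, rcond=None)
    return QuadraticProfile(
        intercept=float(coefs[0]), linear=float(coefs[1]),
        quadratic=float(coefs[2]), n_trials=len(records),
    )


@dataclass
class RtModeFit:
    """Shifted, scaled chi-square summary of a skewed RT sample."""

    mode_ms: float
    df: float
    scale: float
    shift: float
    converged: bool


def chi2_mode(df: float, scale: float, shift: float) -> float:
    """Analytic mode of a shifted, scaled chi-square: shift + (df − 2)·scale for df > 2."""
    return shift + scale * (df - 2.0) if df > 2 else shift


def rt_mode_summary(rts: np.ndarray) -> RtModeFit:
    """Mode of a shifted scaled chi-square fit to the RTs at one step.

    Right-skewed RT distributions make the mean a poor central summary;
    instead a chi-square with free degrees of freedom ``k``, scale ``theta``
    and shift ``s`` is fit by maximum likelihood and summarized by its
    analytic mode ``s + (k - 2) * theta`` (or ``s`` for k <= 2).  If the
    fit fails, the peak of a Gaussian kernel density estimate is returned
    with ``converged=False``.
    """
    x = np.asarray(rts, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(x) == 0:
        return RtModeFit(mode_ms=float(x[0]), df=np.nan, scale=np.nan, shift=float(x[0]), converged=True)
    try:
        with np.errstate(all="ignore"):
            # moment-matched starting values: the free (df, loc, scale)
            # likelihood has trading-off parameters and scipy's default
            # starts can land in a distant basin
            loc0 = float(x.min() - 0.05 * np.ptp(x))
            mean_ex = float(x.mean() - loc0)
            scale0 = max(float(x.var() / (2.0 * mean_ex)), 1e-6)
            df0 = max(mean_ex / scale0, 0.5)
            df, loc, scale = stats.chi2.fit(x, df0, loc=loc0, scale=scale0)
        if not (np.isfinite(df) and np.isfinite(loc) and np.isfinite(scale) and scale > 0):
            raise RuntimeError("non-finite chi-square fit")
        mode = chi2_mode(df, scale, loc)
        return RtModeFit(mode_ms=float(mode), df=float(df), scale=float(scale),
                         shift=float(loc), converged=True)
    except Exception:
        kde = stats.gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), 512)
        mode = grid[np.argmax(kde(grid))]
        return RtModeFit(mode_ms=float(mode), df=np.nan, scale=np.nan,
                         shift=np.nan, converged=False)


def rt_mode_table(records: pd.DataFrame) -> pd.DataFrame:
    """Chi-square mode summaries per subject × continuum × step."""
    rows = []
    for (sid, cont, step), grp in records.groupby(["subject_id", "continuum", "step"]):
        if len(grp) < 10:
            continue
        fit = rt_mode_summary(grp["rt_ms"].to_numpy())
        rows.append({
            "subject_id": sid, "continuum": cont, "step": step, "n": len(grp),
            "mode_ms": fit.mode_ms, "df": fit.df, "scale": fit.scale,
            "shift": fit.shift, "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def rt_mixed_model(records: pd.DataFrame, subjects: pd.DataFrame) -> CoefTable:
    """Trial-level mixed model of RT on the quadratic basis × reading score.

    Fixed effects: the orthogonal linear and quadratic step polynomials,
    centered reading score, and the polynomial × reading interactions, with
    a random intercept per subject.  A negative quadratic × reading
    interaction means higher reading scores deepen the inverted-U (faster
    endpoint responses relative to the ambiguous center).
    """
    table = records.merge(subjects[["subject_id", "wj_brs"]], on="subject_id")
    basis = orthogonal_step_basis(table["step"].to_numpy())
    table = table.join(basis.loc[table["step"]].reset_index(drop=True).set_index(table.index))
    table["wj_brs_c"] = table["wj_brs"] - table["wj_brs"].mean()
    spec = ModelSpec(
        response="rt_ms",
        fixed=["poly1", "poly2", "wj_brs_c", "poly1:wj_brs_c", "poly2:wj_brs_c"],
    )
    return fit_shape_model(table, spec)
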
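"""Four-parameter logistic psychometric model and grid-based Bayesian fitting.

The psychometric function maps a stimulus position ``x`` on a 7-step phoneme
continuum to the probability of choosing the second category endpoint:

    psi(x) = gamma + (1 - gamma - lambda) * S(x; m, w)

where ``m`` is the threshold (category boundary), ``w`` the width, and
``gamma`` / ``lambda`` the deviations of the lower and upper asymptotes from
0 and 1 (the "lapse" parameters).  Width follows the convention of standard
psychometric-fitting toolboxes: ``w`` is the stimulus interval over which the
unscaled sigmoid rises from 0.05 to 0.95, so

    S(x) = 1 / (1 + exp(-2 * ln(19) * (x - m) / w))

and the slope of the full psychometric at threshold is
``(1 - gamma - lambda) * ln(19) / (2 w)``.

Fitting evaluates the binomial likelihood of per-step response counts on a
dense parameter grid under independent uniform priors, and summarizes the
posterior by its marginal means.  A prior with ``asym_max = 0`` collapses the
asymptote axes to a point and reproduces the traditional 2-parameter fit
(asymptotes fixed at 0 and 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

LN19 = math.log(19.0)

#: canonical continuum steps used throughout the experiment
STEPS = np.arange(1, 8)


class ParameterDomainError(ValueError):
    """Raised when psychometric parameters violate their domain."""


class DegenerateFitError(RuntimeError):
    """Raised when the posterior carries no numerical mass."""


@dataclass(frozen=True)
class PsychometricParams:
    """Threshold, width and asymptote deviations of the logistic psychometric.

    ``lower_asym`` (gamma) lifts the lower asymptote above 0 and
    ``upper_asym_dev`` (lambda) pulls the upper asymptote below 1; their
    sum must stay below 1 so the curve remains increasing.
    """

    threshold: float
    width: float
    lower_asym: float = 0.0
    upper_asym_dev: float = 0.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ParameterDomainError(f"width must be positive, got {self.width}")
        if not (0 <= self.lower_asym <= 0.5 and 0 <= self.upper_asym_dev <= 0.5):
            raise ParameterDomainError(
                "asymptote deviations must lie in [0, 0.5], got "
                f"gamma={self.lower_asym}, lambda={self.upper_asym_dev}"
            )
        if self.lower_asym + self.upper_asym_dev >= 1:
            raise ParameterDomainError("gamma + lambda must be < 1")


def predict_prob(params: PsychometricParams, x) -> np.ndarray | float:
    """Probability of a category-2 response at continuum position ``x``.

    Vectorized over ``x``; returns a scalar for scalar input.
    """
    z = 2.0 * LN19 * (np.asarray(x, dtype=float) - params.threshold) / params.width
    out = params.lower_asym + (1.0 - params.lower_asym - params.upper_asym_dev) * expit(z)
    return float(out) if np.isscalar(x) else out


def slope_at_threshold(params: PsychometricParams) -> float:
    """Derivative of the psychometric at its threshold, in probability/step."""
    return (1.0 - params.lower_asym - params.upper_asym_dev) * LN19 / (2.0 * params.width)


@dataclass
class BlockData:
    """Responses from one 70-trial block of one subject.

    Aggregated per-step counts drive the fit; the optional trial-level table
    (``trials``) carries trial order, responses and reaction times and is
    required for leave-one-out cross-validation and reaction-time analysis.
    """

    subject_id: str
    continuum: str
    paradigm: str
    block_index: int
    steps: np.ndarray
    n_trials: np.ndarray
    n_category2: np.ndarray
    trials: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=int)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_category2 = np.asarray(self.n_category2, dtype=int)
        if not (set(self.steps) <= set(STEPS.tolist())):
            raise ValueError(f"steps must lie in 1..7, got {sorted(set(self.steps))}")
        if np.any(self.n_category2 < 0) or np.any(self.n_category2 > self.n_trials):
            raise ValueError("need 0 <= n_category2 <= n_trials at every step")

    @classmethod
    def from_trials(
        cls,
        trials: pd.DataFrame,
        subject_id: str,
        continuum: str,
        paradigm: str,
        block_index: int,
    ) -> "BlockData":
        """Build a block from a trial table with ``step`` and ``response`` columns."""
        grouped = trials.groupby("step")["response"].agg(["count", "sum"])
        return cls(
            subject_id=subject_id,
            continuum=continuum,
            paradigm=paradigm,
            block_index=block_index,
            steps=grouped.index.to_numpy(),
            n_trials=grouped["count"].to_numpy(),
            n_category2=grouped["sum"].to_numpy(),
            trials=trials.reset_index(drop=True),
        )

    @property
    def total_trials(self) -> int:
        return int(self.n_trials.sum())


@dataclass(frozen=True)
class PriorConfig:
    """Uniform priors and grid resolution for the Bayesian fit.

    ``asym_max`` bounds both asymptote deviations (uniform on
    [0, asym_max]); 0 fixes the asymptotes at 0 and 1, recovering the
    2-parameter model.  Threshold and width priors are flat over wide ranges
    (the stimulus range widened by 50% per side, and half the step spacing up
    to three times the stimulus range) so they contribute almost nothing to
    the posterior.
    """

    asym_max: float = 0.1
    threshold_range: tuple[float, float] = (-2.0, 10.0)
    width_range: tuple[float, float] = (0.5, 18.0)
    grid_points: int = 41
    grid_points_asym: int = 21

    def __post_init__(self) -> None:
        if not (0.0 <= self.asym_max <= 0.5):
            raise ParameterDomainError(f"asym_max must be in [0, 0.5], got {self.asym_max}")
        if self.grid_points < 2 or self.grid_points_asym < 2:
            raise ParameterDomainError("grids need at least 2 points per free axis")


@dataclass
class FitResult:
    """Posterior summary of a single-block psychometric fit."""

    point_estimate: PsychometricParams
    slope_at_threshold: float
    marginals: Mapping[str, tuple[np.ndarray, np.ndarray]]
    log_evidence: float
    psi_bar: np.ndarray  # posterior-predictive mean response probability at steps 1..7
    prior: PriorConfig
    excluded: bool = False
    exclusion_reason: str | None = None
    meta: dict = field(default_factory=dict)


def block_log_likelihood(block: BlockData, params: PsychometricParams) -> float:
    """Binomial log-likelihood of a block's per-step counts under ``params``.

    Additive over steps; returns ``-inf`` (never raises) when the model
    assigns probability exactly 0 or 1 against observed counts.
    """
    psi = np.asarray(predict_prob(params, block.steps.astype(float)))
    k = block.n_category2
    n = block.n_trials
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(k > 0, k * np.log(psi), 0.0) + np.where(
            n - k > 0, (n - k) * np.log1p(-psi), 0.0
        )
    total = float(np.sum(const + term))
    return total if np.isfinite(total) else -np.inf


# ---------------------------------------------------------------------------
# grid machinery


def _trapezoid_mass(axis: np.ndarray) -> np.ndarray:
    """Prior mass attached to each node of a 1-D axis under a uniform prior.

    Trapezoid-rule cell widths, normalized to sum to 1, so non-uniform node
    spacing still integrates the flat prior correctly.
    """
    if axis.size == 1:
        return np.array([1.0])
    mass = np.empty_like(axis)
    mass[1:-1] = (axis[2:] - axis[:-2]) / 2.0
    mass[0] = (axis[1] - axis[0]) / 2.0
    mass[-1] = (axis[-1] - axis[-2]) / 2.0
    return mass / mass.sum()


@dataclass(frozen=True)
class _GridTables:
    """Pre-computed log-probability tables shared by every fit under one prior."""

    m: np.ndarray          # (MW,) threshold at each (m, w) grid node
    w: np.ndarray          # (MW,)
    gamma: np.ndarray      # (A,) lower asymptote at each asymptote-pair node
    lam: np.ndarray        # (A,)
    m_axis: np.ndarray
    w_axis: np.ndarray
    asym_axis: np.ndarray
    log_prior: np.ndarray  # (A, MW) log prior mass at each node
    psi: np.ndarray        # (A, MW, 7) response probability at steps 1..7
    log_psi: np.ndarray
    log_1m_psi: np.ndarray
    slope: np.ndarray      # (A, MW) slope at threshold for each node
    log_slope: np.ndarray  # (A, MW) log of the slope table, for the geometric mean


@lru_cache(maxsize=32)
def _grid_tables(prior: PriorConfig) -> _GridTables:
    m_axis = np.linspace(*prior.threshold_range, prior.grid_points)
    # geometric width spacing resolves small widths, where the slope varies
    # fastest; trapezoid node masses keep the prior itself flat
    w_axis = np.geomspace(*prior.width_range, prior.grid_points)
    if prior.asym_max == 0.0:
        asym_axis = np.array([0.0])
    else:
        asym_axis = np.linspace(0.0, prior.asym_max, prior.grid_points_asym)

    mm, ww = np.meshgrid(m_axis, w_axis, indexing="ij")
    m_flat, w_flat = mm.ravel(), ww.ravel()
    mw_mass = np.outer(_trapezoid_mass(m_axis), _trapezoid_mass(w_axis)).ravel()

    gg, ll = np.meshgrid(asym_axis, asym_axis, indexing="ij")
    a_mass2 = np.outer(_trapezoid_mass(asym_axis), _trapezoid_mass(asym_axis))
    keep = (gg + ll) < 1.0
    g_flat, l_flat = gg[keep], ll[keep]
    a_mass = a_mass2[keep]
    a_mass = a_mass / a_mass.sum()

    with np.errstate(divide="ignore"):
        log_prior = np.log(a_mass)[:, None] + np.log(mw_mass)[None, :]

    z = 2.0 * LN19 * (STEPS[None, :] - m_flat[:, None]) / w_flat[:, None]  # (MW, 7)
    s = expit(z)
    s_comp = expit(-z)

    scale = (1.0 - g_flat - l_flat)[:, None, None]  # (A, 1, 1)
    psi = g_flat[:, None, None] + scale * s[None, :, :]
    one_m_psi = l_flat[:, None, None] + scale * s_comp[None, :, :]
    with np.errstate(divide="ignore"):
        log_psi = np.log(psi)
        log_1m_psi = np.log(one_m_psi)

    slope = (1.0 - g_flat[:, None] - l_flat[:, None]) * LN19 / (2.0 * w_flat[None, :])
    return _GridTables(
        m=m_flat, w=w_flat, gamma=g_flat, lam=l_flat,
        m_axis=m_axis, w_axis=w_axis, asym_axis=asym_axis,
        log_prior=log_prior,
        psi=psi, log_psi=log_psi, log_1m_psi=log_1m_psi, slope=slope,
        log_slope=np.log(slope),
    )


def _grid_log_likelihood(tables: _GridTables, block: BlockData) -> np.ndarray:
    """Log-likelihood of a block's counts at every grid node, shape (A, MW)."""
    idx = block.steps - 1
    k = block.n_category2.astype(float)
    nk = (block.n_trials - block.n_category2).astype(float)
    with np.errstate(invalid="ignore"):
        ll = np.einsum("amj,j->am", tables.log_psi[:, :, idx], k, optimize=True)
        ll += np.einsum("amj,j->am", tables.log_1m_psi[:, :, idx], nk, optimize=True)
    np.nan_to_num(ll, copy=False, nan=-np.inf)
    return ll


def _binom_const(block: BlockData) -> float:
    n, k = block.n_trials, block.n_category2
    return float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))


def _summarize_posterior(
    tables: _GridTables, log_post: np.ndarray, prior: PriorConfig, binom_const: float
) -> FitResult:
    top = np.max(log_post)
    if not np.isfinite(top):
        raise DegenerateFitError("posterior mass is numerically zero everywhere")
    post = np.exp(log_post - top)
    z = post.sum()
    post /= z

    pa = post.sum(axis=1)  # (A,)
    pmw = post.sum(axis=0)  # (MW,)

    n_m = tables.m_axis.size
    n_w = tables.w_axis.size
    pm = pmw.reshape(n_m, n_w).sum(axis=1)
    pw = pmw.reshape(n_m, n_w).sum(axis=0)

    m_hat = float(tables.m_axis @ pm)
    w_hat = float(tables.w_axis @ pw)
    g_hat = float(tables.gamma @ pa)
    l_hat = float(tables.lam @ pa)

    # marginals on the asymptote axes
    n_asym = tables.asym_axis.size
    pg = np.zeros(n_asym)
    pl = np.zeros(n_asym)
    g_idx = np.searchsorted(tables.asym_axis, tables.gamma)
    l_idx = np.searchsorted(tables.asym_axis, tables.lam)
    np.add.at(pg, g_idx, pa)
    np.add.at(pl, l_idx, pa)

    # slope is a positive scale-like quantity with a skewed posterior; its
    # point summary is the posterior geometric mean (the Bayes estimator
    # under squared log-scale error), which is far less sensitive to the
    # heavy slope ~ 1/w tails than the arithmetic mean or plug-in estimates
    slope_hat = float(np.exp(np.sum(post * tables.log_slope)))
    psi_bar = np.einsum("am,amj->j", post, tables.psi, optimize=True)

    log_evidence = binom_const + top + math.log(z)
    return FitResult(
        point_estimate=PsychometricParams(m_hat, w_hat, g_hat, l_hat),
        slope_at_threshold=slope_hat,
        marginals={
            "threshold": (tables.m_axis, pm),
            "width": (tables.w_axis, pw),
            "lower_asym": (tables.asym_axis, pg),
            "upper_asym_dev": (tables.asym_axis, pl),
        },
        log_evidence=log_evidence,
        psi_bar=psi_bar,
        prior=prior,
    )


def fit_block(block: BlockData, prior: PriorConfig | None = None) -> FitResult:
    """Fit the psychometric to one block by grid-posterior Bayesian inference.

    The posterior is the binomial likelihood times independent uniform priors
    evaluated on a dense 4-D grid (asymptote axes collapse to a point when
    ``asym_max = 0``).  Point estimates are the marginal posterior means; the
    reported slope is the posterior geometric mean of the slope-at-threshold
    functional, and ``psi_bar`` is the posterior-predictive mean response
    probability at each step (used for held-out likelihood scoring).
    Deterministic for a given block, prior, and grid resolution.
    """
    if prior is None:
        prior = PriorConfig()
    if block.steps.size < 2:
        raise ValueError("need at least 2 distinct continuum steps to fit")
    tables = _grid_tables(prior)
    log_post = _grid_log_likelihood(tables, block) + tables.log_prior
    return _summarize_posterior(tables, log_post, prior, _binom_const(block))


def heldout_trial_likelihood(fit: FitResult, step: int, response: int) -> float:
    """Model probability of an observed response under the fitted posterior.

    Uses the posterior-predictive mean ``psi_bar``: the probability of a
    category-2 response at ``step``, or its complement for a category-1
    response.  A degenerate zero probability is returned as 0.0 (the caller
    may flag it), never raised.
    """
    if not (1 <= step <= 7):
        raise ValueError(f"step must be in 1..7, got {step}")
    p = float(fit.psi_bar[int(step) - 1])
    return p if response == 1 else 1.0 - p
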
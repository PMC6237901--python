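"""Statistics linking psychometric curve shape to reading ability.

The analysis treats reading ability (a standardized composite score, mean
100, SD 15) as a continuous predictor of curve-shape outcomes (slope,
combined lapse, PC1) in linear mixed-effects models with a random intercept
per subject.  Two-level factors (stimulus continuum, task paradigm) enter
with deviation coding (±0.5) so main effects are evaluated at the grand
mean; continuous predictors are centered whenever interactions are present.
Model simplification is backward elimination by likelihood-ratio test.

The module also provides the categorical-group analyses (Cohen's d,
leave-one-out discriminant classification), an FDR-corrected correlation
screen against a battery of test scores, Baron–Kenny mediation with a
subject-level bootstrap, and the endpoint-accuracy stationarity model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import LeaveOneOut
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class ModelSpec:
    """A mixed-model formula: response, fixed terms, and the grouping column.

    Fixed terms name numeric columns of the analysis table; an interaction is
    written ``"a:b"`` and is the elementwise product of the named columns
    (which should be centered / deviation-coded upstream).
    """

    response: str
    fixed: list[str]
    group: str = "subject_id"

    def interactions(self) -> list[str]:
        return [t for t in self.fixed if ":" in t]

    def main_effects(self) -> list[str]:
        return [t for t in self.fixed if ":" not in t]


@dataclass
class CoefTable:
    """Fitted coefficients plus the stepwise-simplification trace."""

    terms: pd.DataFrame          # name, beta, se, p
    loglik: float
    trace: list[dict] = field(default_factory=list)
    spec: ModelSpec | None = None

    def coef(self, name: str) -> float:
        return float(self.terms.set_index("name").loc[name, "beta"])

    def se(self, name: str) -> float:
        return float(self.terms.set_index("name").loc[name, "se"])

    def pvalue(self, name: str) -> float:
        return float(self.terms.set_index("name").loc[name, "p"])


class CollinearityError(ValueError):
    """The fixed-effects design matrix is rank deficient."""


def _term_column(table: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    col = np.ones(len(table))
    for p in parts:
        col = col * table[p].to_numpy(dtype=float)
    return col


def _design(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    x = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for term in spec.fixed:
        x[term] = _term_column(table, term)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # name the first term whose removal restores full rank
        for term in spec.fixed:
            reduced = x.drop(columns=[term])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise CollinearityError(f"term '{term}' is collinear with the rest of the design")
        raise CollinearityError("design matrix is rank deficient")
    return x


def fit_shape_model(table: pd.DataFrame, spec: ModelSpec) -> CoefTable:
    """Fit a linear mixed model with a random intercept per subject.

    Maximum-likelihood fit (so nested models are comparable by LRT);
    coefficient p-values are Wald z-tests as reported by the fitting
    routine.  Deterministic given the data.
    """
    counts = table[spec.group].value_counts()
    if (counts < 2).all():
        warnings.warn(
            "no subject has repeated observations; the random intercept is unidentifiable",
            stacklevel=2,
        )
    x = _design(table, spec)
    y = table[spec.response].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # near-zero random-intercept variance triggers benign singular-covariance chatter
        warnings.simplefilter("ignore", UserWarning)
        model = sm.MixedLM(y, x, groups=table[spec.group].to_numpy())
        res = model.fit(reml=False)
    k = x.shape[1]
    terms = pd.DataFrame(
        {
            "name": list(x.columns),
            "beta": np.asarray(res.params)[:k],
            "se": np.asarray(res.bse)[:k],
            "p": np.asarray(res.pvalues)[:k],
        }
    )
    return CoefTable(terms=terms, loglik=float(res.llf), spec=spec)


def _lrt_pvalue(full: CoefTable, reduced: CoefTable, df: int = 1) -> float:
    lr = 2.0 * (full.loglik - reduced.loglik)
    return float(stats.chi2.sf(max(lr, 0.0), df))


def stepwise_simplify(table: pd.DataFrame, full_spec: ModelSpec, alpha: float = 0.05) -> CoefTable:
    """Backward elimination of fixed effects by likelihood-ratio test.

    Repeatedly refits the model with each droppable term removed and drops
    the term with the largest LRT p-value above ``alpha``; interaction terms
    are eliminated before the main effects they contain, and the random
    intercept is never dropped.  Returns the parsimonious model with a trace
    of every removal.
    """
    spec = ModelSpec(full_spec.response, list(full_spec.fixed), full_spec.group)
    current = fit_shape_model(table, spec)
    trace: list[dict] = []
    while True:
        protected = set()
        for inter in spec.interactions():
            protected.update(inter.split(":"))
        interactions = spec.interactions()
        mains = [t for t in spec.main_effects() if t not in protected]
        if not interactions and not mains:
            break

        def _lrt(term: str):
            reduced_spec = ModelSpec(spec.response, [t for t in spec.fixed if t != term], spec.group)
            reduced = fit_shape_model(table, reduced_spec)
            return term, _lrt_pvalue(current, reduced), reduced, reduced_spec

        # interactions are considered before the main effects they contain
        picked = None
        for pool in (interactions, mains):
            if not pool:
                continue
            candidates = [_lrt(t) for t in pool]
            best = max(candidates, key=lambda c: c[1])
            if best[1] > alpha:
                picked = best
                break
        if picked is None:
            break
        term, p, reduced, reduced_spec = picked
        trace.append({"dropped": term, "lrt_p": p})
        spec, current = reduced_spec, reduced
    current.trace = trace
    current.spec = spec
    return current


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Standardized mean difference with the pooled (n−1-weighted) SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / pooled)


def loo_discriminant_accuracy(
    features: np.ndarray, labels: np.ndarray, method: str = "linear"
) -> float:
    """Leave-one-subject-out accuracy of an LDA or QDA classifier."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least 2 classes with at least 2 members each")
    make = (
        LinearDiscriminantAnalysis
        if method == "linear"
        else lambda: QuadraticDiscriminantAnalysis(store_covariance=False)
    )
    hits = 0
    for train, test in LeaveOneOut().split(x):
        clf = make()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(x[train], y[train])
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                "singular within-class covariance; regularization needed"
            ) from err
        hits += int(clf.predict(x[test])[0] == y[test][0])
    return hits / len(y)


def correlation_screen_fdr(
    params: pd.DataFrame, battery: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of shape parameters against test-battery scores.

    Benjamini–Hochberg correction is applied across the whole parameter ×
    measure matrix; the mask marks adjusted p < ``alpha``.  Cells with a
    constant column are flagged NaN and excluded from the correction.
    """
    r = pd.DataFrame(index=params.columns, columns=battery.columns, dtype=float)
    praw = pd.DataFrame(index=params.columns, columns=battery.columns, dtype=float)
    for pc in params.columns:
        for bc in battery.columns:
            paired = pd.concat([params[pc], battery[bc]], axis=1).dropna()
            if len(paired) < 3 or paired.iloc[:, 0].std() == 0 or paired.iloc[:, 1].std() == 0:
                r.loc[pc, bc] = np.nan
                praw.loc[pc, bc] = np.nan
                continue
            rr, pp = stats.pearsonr(paired.iloc[:, 0], paired.iloc[:, 1])
            r.loc[pc, bc] = rr
            praw.loc[pc, bc] = pp
    mask = pd.DataFrame(False, index=params.columns, columns=battery.columns)
    flat = praw.to_numpy().ravel()
    ok = np.isfinite(flat)
    if ok.any():
        rejected = np.zeros_like(flat, dtype=bool)
        rejected[ok] = multipletests(flat[ok], alpha=alpha, method="fdr_bh")[0]
        mask.iloc[:, :] = rejected.reshape(praw.shape)
    return r, mask


@dataclass
class MediationResult:
    """Baron–Kenny decomposition of a total effect into direct and indirect paths."""

    total_effect: float       # c: x -> y
    direct_effect: float      # c': x -> y controlling the mediator
    path_a: float             # x -> mediator
    path_b: float             # mediator -> y controlling x
    indirect_effect: float    # a * b
    percent_mediation: float | None
    ci: tuple[float, float]
    p_value: float
    n_boot: int
    seed: int


def _ols_coef(y: np.ndarray, cols: list[np.ndarray], which: int) -> float:
    x = sm.add_constant(np.column_stack(cols))
    return float(sm.OLS(y, x).fit().params[which + 1])


def mediation_analysis(
    x: np.ndarray,
    mediator: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> MediationResult:
    """Product-of-coefficients mediation with a percentile bootstrap.

    Three regressions with identical covariates: y ~ x (total effect c),
    mediator ~ x (path a), and y ~ x + mediator (direct effect c' and path
    b).  The indirect effect a·b equals c − c' exactly in this linear
    setting; its CI and p-value come from resampling observations with
    replacement under a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != x.size:
        cov = cov.T
    if x.size < 10:
        raise ValueError("need at least 10 complete cases")

    def paths(xi, mi, yi, ci):
        extra = [] if ci is None else [ci]
        c = _ols_coef(yi, [xi] + extra, 0)
        a = _ols_coef(mi, [xi] + extra, 0)
        c_prime = _ols_coef(yi, [xi, mi] + extra, 0)
        b = _ols_coef(yi, [xi, mi] + extra, 1)
        return c, a, b, c_prime

    c, a, b, c_prime = paths(x, m, y, cov)
    indirect = a * b

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = x.size
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ci = None if cov is None else cov[idx]
        _, ai, bi, _ = paths(x[idx], m[idx], y[idx], ci)
        boots[i] = ai * bi
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())
    percent = 100.0 * indirect / c if abs(c) > 1e-12 else None
    return MediationResult(
        total_effect=c, direct_effect=c_prime, path_a=a, path_b=b,
        indirect_effect=indirect, percent_mediation=percent,
        ci=(float(lo), float(hi)), p_value=float(min(p, 1.0)),
        n_boot=n_boot, seed=seed,
    )


def endpoint_accuracy_table(trials: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Trial-level endpoint correctness, merged with subject covariates.

    Restricted to continuum steps 1 and 7, where the stimulus is an
    unambiguous endpoint token: a trial is correct when the response matches
    the endpoint (category 1 at step 1, category 2 at step 7).  Centers
    trial number, reading score and age, and deviation-codes continuum and
    paradigm.
    """
    ends = trials[trials["step"].isin([1, 7])].copy()
    if len(ends) == 0:
        raise ValueError("no endpoint (step 1 or 7) trials present")
    ends["correct"] = np.where(ends["step"] == 7, ends["response"], 1 - ends["response"]).astype(float)
    ends = ends.merge(subjects, on="subject_id")
    ends["trial_number_c"] = ends["trial_number"] - ends["trial_number"].mean()
    ends["wj_brs_c"] = ends["wj_brs"] - ends["wj_brs"].mean()
    ends["age_c"] = ends["age"] - ends["age"].mean()
    ends["continuum_dev"] = np.where(ends["continuum"] == "static_sha_sa", 0.5, -0.5)
    ends["paradigm_dev"] = np.where(ends["paradigm"] == "abx", 0.5, -0.5)
    return ends


def endpoint_accuracy_model(
    trials: pd.DataFrame, subjects: pd.DataFrame, simplify: bool = True
) -> CoefTable:
    """Stationarity model of endpoint accuracy over the course of a block.

    A linear (identity-link) mixed probability model of correctness on
    centered trial number, centered reading score, continuum, paradigm, age
    and ADHD, with a random intercept per subject, simplified by the same
    backward-elimination machinery as the shape models.  A negative trial
    number coefficient indicates accuracy declining as the block wears on.
    """
    table = endpoint_accuracy_table(trials, subjects)
    spec = ModelSpec(
        response="correct",
        fixed=["trial_number_c", "wj_brs_c", "continuum_dev", "paradigm_dev", "age_c", "adhd"],
    )
    if simplify:
        return stepwise_simplify(table, spec)
    return fit_shape_model(table, spec)
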
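"""Binary logistic regression, stepwise AIC selection, and cross-cohort
cut-point validation.

Model fitting is maximum likelihood via ``statsmodels`` (Newton iterations,
relative log-likelihood tolerance 1e-8, 100 iterations max). On top of that
sit the study-workflow operations: greedy bidirectional stepwise selection
by AIC on a fixed complete-case set, likelihood-ratio (ANOVA-style)
comparison of nested models, and transport of a Youden-optimal cut point
from the model's source cohort to an external cohort, scored with a
Yates-corrected chi-squared test and the phi coefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import Cohort, exclude_incomplete
from .roc_analysis import roc_curve, youden_cut_point
from .stats_univariate import categorical_test

__all__ = [
    "LogisticModelResult",
    "CrossValidationResult",
    "SeparationError",
    "fit_logistic",
    "stepwise_aic",
    "lrt_anova",
    "transport_cut_point",
    "phi_coefficient",
]

_Z95 = 1.959963984540054  # norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: the MLE does not exist."""


@dataclass
class LogisticModelResult:
    """A fitted binary logistic model and its Wald summaries."""

    outcome: str
    variables: list[str]
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    odds_ratios: dict[str, tuple[float, float, float]]  # OR, lo95, hi95
    log_likelihood: float
    aic: float
    n_used: int
    linear_predictor: np.ndarray = dc_field(repr=False, default=None)
    record_ids: list[str] = dc_field(repr=False, default_factory=list)

    def predict_linear(self, cohort: Cohort) -> np.ndarray:
        """Linear predictor (log-odds) for each record; NaN when a predictor
        is missing."""
        eta = np.full(len(cohort), np.nan)
        for i, rec in enumerate(cohort):
            vals = [getattr(rec, v) for v in self.variables]
            if any(v is None for v in vals):
                continue
            eta[i] = self.intercept + sum(
                self.coefficients[v] * x for v, x in zip(self.variables, vals))
        return eta

    def summary_rows(self) -> list[dict]:
        rows = [{"term": "(intercept)", "coefficient": self.intercept,
                 "se": self.standard_errors["(intercept)"],
                 "odds_ratio": None, "ci_low": None, "ci_high": None,
                 "p": self.p_values["(intercept)"]}]
        for v in self.variables:
            orr, lo, hi = self.odds_ratios[v]
            rows.append({"term": v, "coefficient": self.coefficients[v],
                         "se": self.standard_errors[v], "odds_ratio": orr,
                         "ci_low": lo, "ci_high": hi, "p": self.p_values[v]})
        return rows


@dataclass
class CrossValidationResult:
    """Cut-point transport from a source-cohort model to a target cohort."""

    source_label: str
    target_label: str
    cut_point: float
    table: list[list[int]]  # rows: predicted died / survived; cols: observed
    chi2: float | None
    p_value: float | None
    phi: float | None
    n_used: int


def _design(cohort: Cohort, predictors: Sequence[str], outcome: str
            ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    complete, _ = exclude_incomplete(cohort, list(predictors))
    y = np.array([1.0 if getattr(r, outcome) == "died" else 0.0
                  for r in complete])
    x = np.array([[float(getattr(r, p)) for p in predictors]
                  for r in complete]) if predictors else np.empty((len(complete), 0))
    ids = [r.patient_id for r in complete]
    return x, y, ids


def fit_logistic(cohort: Cohort, predictors: Sequence[str],
                 outcome: str = "icu_outcome") -> LogisticModelResult:
    """Maximum-likelihood binary logistic fit on complete cases.

    Raises :class:`SeparationError` when the predictors (quasi-)perfectly
    separate the outcome, and ``ValueError`` for a rank-deficient design or
    fewer than 10 complete cases.
    """
    predictors = list(predictors)
    x, y, ids = _design(cohort, predictors, outcome)
    if y.size < 10:
        raise ValueError(f"only {y.size} complete cases; need >= 10")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        culprit = _rank_culprit(design, predictors)
        raise ValueError(f"rank-deficient design: predictor {culprit!r} is "
                         "constant or collinear")
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            res = model.fit(disp=0, maxiter=100, tol=1e-8)
        except (PerfectSeparationError, PerfectSeparationWarning,
                np.linalg.LinAlgError) as err:
            raise SeparationError(
                f"separation while fitting {predictors}: {err}") from None
    params = np.asarray(res.params)
    if np.abs(params[1:]).size and np.abs(
            params[1:] * (x.std(axis=0) + 1e-12)).max() > 30:
        worst = predictors[int(np.abs(params[1:] * x.std(axis=0)).argmax())]
        raise SeparationError(
            f"coefficient for {worst!r} diverged; data are separated")

    se = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    coeffs = dict(zip(predictors, params[1:]))
    ses = {"(intercept)": float(se[0])}
    ses.update(zip(predictors, se[1:]))
    pd_ = {"(intercept)": float(pvals[0])}
    pd_.update(zip(predictors, pvals[1:]))
    ors = {v: (math.exp(coeffs[v]),
               math.exp(coeffs[v] - _Z95 * ses[v]),
               math.exp(coeffs[v] + _Z95 * ses[v])) for v in predictors}
    eta = design @ params
    return LogisticModelResult(
        outcome=outcome, variables=predictors, intercept=float(params[0]),
        coefficients={k: float(v) for k, v in coeffs.items()},
        standard_errors=ses, p_values=pd_, odds_ratios=ors,
        log_likelihood=float(res.llf), aic=float(res.aic), n_used=int(y.size),
        linear_predictor=eta, record_ids=ids)


def _rank_culprit(design: np.ndarray, predictors: Sequence[str]) -> str:
    for j, name in enumerate(predictors, start=1):
        if np.allclose(design[:, j], design[0, j]):
            return name
    return "/".join(predictors)


def stepwise_aic(cohort: Cohort, candidates: Sequence[str],
                 outcome: str = "icu_outcome",
                 direction: str = "both") -> LogisticModelResult:
    """Greedy stepwise selection minimizing AIC, starting from the
    intercept-only model.

    The record set is fixed to complete cases over *all* candidates before
    the search so that nested models share the same likelihood scale and
    their AICs are comparable. Candidates are scanned in declared order and
    the single best AIC improvement (add or, for ``direction='both'``, drop)
    is taken each step; exact ties favour the smaller model. The result is
    therefore deterministic and independent of record order.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if direction not in ("both", "forward"):
        raise ValueError(f"unknown direction {direction!r}")
    base, _ = exclude_incomplete(cohort, list(candidates))

    def fit(preds: tuple[str, ...]) -> LogisticModelResult:
        if preds:
            return fit_logistic(base, list(preds), outcome)
        # intercept-only fit (fit_logistic requires predictors)
        y = np.array([1.0 if getattr(r, outcome) == "died" else 0.0
                      for r in base])
        res = sm.Logit(y, np.ones((y.size, 1))).fit(disp=0, maxiter=100,
                                                    tol=1e-8)
        p0 = float(res.params[0])
        return LogisticModelResult(
            outcome=outcome, variables=[], intercept=p0,
            coefficients={}, standard_errors={"(intercept)": float(res.bse[0])},
            p_values={"(intercept)": float(res.pvalues[0])}, odds_ratios={},
            log_likelihood=float(res.llf), aic=float(res.aic),
            n_used=int(y.size), linear_predictor=np.full(y.size, p0),
            record_ids=[r.patient_id for r in base])

    current: tuple[str, ...] = ()
    current_fit = fit(current)
    while True:
        moves: list[tuple[int, tuple[str, ...], LogisticModelResult]] = []
        for cand in candidates:
            if cand in current:
                continue
            trial = current + (cand,)
            try:
                moves.append((len(trial), trial, fit(trial)))
            except (SeparationError, ValueError):
                continue
        if direction == "both":
            for v in current:
                trial = tuple(p for p in current if p != v)
                try:
                    moves.append((len(trial), trial, fit(trial)))
                except (SeparationError, ValueError):
                    continue
        best = None
        for size, trial, trial_fit in moves:
            if trial_fit.aic < current_fit.aic - 1e-9:
                key = (trial_fit.aic, size)
                if best is None or key < best[0]:
                    best = (key, trial, trial_fit)
        if best is None:
            return current_fit
        _, current, current_fit = best


def lrt_anova(nested: LogisticModelResult, full: LogisticModelResult
              ) -> tuple[float, int, float]:
    """Likelihood-ratio (ANOVA) comparison of nested logistic models.

    Returns ``(deviance_difference, df, p)`` where the deviance difference
    is ``2 * (ll_full - ll_nested)`` on ``df`` extra parameters.
    """
    if not set(nested.variables) <= set(full.variables):
        raise ValueError("models are not nested")
    if nested.n_used != full.n_used:
        raise ValueError("nested comparison requires the same records")
    df = len(full.variables) - len(nested.variables)
    dev = 2.0 * (full.log_likelihood - nested.log_likelihood)
    if df == 0:
        return float(dev), 0, 1.0
    dev = max(dev, 0.0)
    return float(dev), df, float(sps.chi2.sf(dev, df))


def phi_coefficient(table: Sequence[Sequence[int]]) -> float | None:
    """Phi for a 2x2 table: (ad - bc) / sqrt of the margin product.

    Returns ``None`` (with a warning) when any margin is zero.
    """
    (a, b), (c, d) = [[float(v) for v in row] for row in table]
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        warnings.warn("phi undefined for a table with a zero margin",
                      stacklevel=2)
        return None
    return (a * d - b * c) / math.sqrt(math.prod(margins))


def transport_cut_point(model: LogisticModelResult, source: Cohort,
                        target: Cohort) -> CrossValidationResult:
    """Validate a source-cohort model on an external target cohort.

    The Youden-optimal cut point of the model's linear predictor on the
    source cohort is applied unchanged to the target's linear predictor
    (predicted death when above the cut); agreement with the observed
    outcome is summarized as a 2x2 table with a Yates-corrected chi-squared
    test (Fisher when expected counts are small) and the phi coefficient.
    """
    eta_src = model.predict_linear(source)
    y_src = [1 if r.icu_outcome == "died" else 0 for r in source]
    roc = roc_curve(np.where(np.isnan(eta_src), None, eta_src).tolist(),
                    y_src, name=f"model[{source.label}]")
    cut = youden_cut_point(roc).cut_point

    eta_tgt = model.predict_linear(target)
    keep = ~np.isnan(eta_tgt)
    y_tgt = np.array([1 if r.icu_outcome == "died" else 0
                      for r in target])[keep]
    pred = (eta_tgt[keep] > cut).astype(int)
    table = [[int(((pred == 1) & (y_tgt == 1)).sum()),
              int(((pred == 1) & (y_tgt == 0)).sum())],
             [int(((pred == 0) & (y_tgt == 1)).sum()),
              int(((pred == 0) & (y_tgt == 0)).sum())]]
    try:
        chi2, p, _ = categorical_test(table, method="auto")
    except ValueError:
        chi2 = p = None
    return CrossValidationResult(
        source_label=source.label, target_label=target.label,
        cut_point=float(cut), table=table, chi2=chi2, p_value=p,
        phi=phi_coefficient(table), n_used=int(keep.sum()))
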
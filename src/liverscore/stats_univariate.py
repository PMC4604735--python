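"""Univariate outcome-association battery.

Continuous admission variables are compared between ICU survivors and
non-survivors with Welch's unequal-variance t test (parametric presentation)
or the Mann-Whitney U test (non-parametric presentation); categorical
variables use a 2x2 chi-squared test with Yates' continuity correction,
falling back to Fisher's exact test when any expected cell count is below 5.
:func:`univariate_table` applies a per-variable plan to a cohort with
pairwise (per-variable complete-case) deletion and emits table-style rows.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort import Cohort, FieldSummary, summarize_field

__all__ = [
    "UnivariateResult",
    "VariablePlan",
    "welch_t",
    "mann_whitney",
    "categorical_test",
    "univariate_table",
    "default_variable_plan",
    "format_p",
    "results_to_csv",
]

#: largest number of group labelings enumerated for the exact Mann-Whitney p
_EXACT_ENUMERATION_LIMIT = 200_000


def welch_t(group_a: Sequence[float], group_b: Sequence[float]
            ) -> tuple[float, float]:
    """Welch's unequal-variance t test, two-sided.

    Uses the Welch-Satterthwaite degrees of freedom. Requires at least two
    values per group and nonzero variance in at least one group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("welch_t: both groups have zero variance")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group *a* via midranks (tie correction built in)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return r_a - a.size * (a.size + 1) / 2.0


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]
                 ) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties, two-sided.

    For eight or more observations per group the p-value uses the normal
    approximation with tie correction and a 0.5 continuity correction;
    smaller samples are handled by exact enumeration over all
    C(n1+n2, n1) group labelings of the pooled values (capped at
    200 000 labelings, beyond which the normal approximation is used).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney needs non-empty groups")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    mean_u = n1 * n2 / 2.0

    small = min(n1, n2) < 8
    if small and math.comb(n1 + n2, n1) <= _EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([a, b])
        dev = abs(u - mean_u)
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            total += 1
            u_star = _u_statistic(pooled[list(idx)],
                                  np.delete(pooled, list(idx)))
            if abs(u_star - mean_u) >= dev - 1e-12:
                hits += 1
        return float(u), hits / total

    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u == 0:  # all values tied
        return float(u), 1.0
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    return float(u), float(2.0 * sps.norm.sf(z))


def categorical_test(table: Sequence[Sequence[int]], method: str = "auto"
                     ) -> tuple[float, float, str]:
    """2x2 association test: Yates-corrected chi-squared or Fisher exact.

    ``method='auto'`` follows the usual convention of substituting Fisher's
    exact test whenever any expected cell count is below 5. Fisher's
    two-sided p is the probability-mass sum over tables at least as extreme
    as the observed one. Returns ``(statistic, p, test_used)``; the Fisher
    statistic is the sample odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("categorical_test: zero margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if method == "auto":
        method = "fisher" if (expected < 5).any() else "chi2_yates"
    if method == "fisher":
        odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
        return float(odds), float(p), "fisher"
    if method == "chi2_yates":
        chi2, p, _, _ = sps.chi2_contingency(t, correction=True)
        return float(chi2), float(p), "chi2_yates"
    if method == "chi2_plain":
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
        return float(chi2), float(p), "chi2_plain"
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# table-building

@dataclass
class VariablePlan:
    """How one variable is summarized and tested.

    ``test`` is ``welch_t``, ``mann_whitney`` or ``categorical``; for
    categorical variables ``positive_levels`` lists the level(s) counted as
    the event (e.g. ``("mild", "severe")`` for "any ascites").
    """

    name: str
    field: str
    summary: str  # mean_range | median_iqr | count_percent
    test: str
    positive_levels: tuple | None = None


@dataclass
class UnivariateResult:
    variable: str
    survivor_summary: FieldSummary
    death_summary: FieldSummary
    test: str
    statistic: float | None
    p_value: float | None


def _split_by_outcome(cohort: Cohort) -> tuple[Cohort, Cohort]:
    surv = [r for r in cohort if r.icu_outcome == "survived"]
    died = [r for r in cohort if r.icu_outcome == "died"]
    return (Cohort(cohort.label + "/survivors", surv),
            Cohort(cohort.label + "/deaths", died))


def univariate_table(cohort: Cohort, plan: Sequence[VariablePlan]
                     ) -> list[UnivariateResult]:
    """One tested, summarized row per planned variable.

    Deletion is pairwise: each row uses every record with that variable
    present, so per-row n varies with missingness, as in cohort summary
    tables.
    """
    survivors, deaths = _split_by_outcome(cohort)
    out: list[UnivariateResult] = []
    for item in plan:
        s_sum = summarize_field(survivors, item.field, item.summary,
                                level=item.positive_levels)
        d_sum = summarize_field(deaths, item.field, item.summary,
                                level=item.positive_levels)
        stat = p = None
        test_name = item.test
        if item.test == "categorical":
            levels = item.positive_levels or ()
            tab = [[sum(1 for r in grp
                        if getattr(r, item.field) in levels),
                    sum(1 for r in grp
                        if getattr(r, item.field) is not None
                        and getattr(r, item.field) not in levels)]
                   for grp in (survivors, deaths)]
            try:
                stat, p, test_name = categorical_test(tab, method="auto")
            except ValueError:
                stat = p = None
        else:
            sv = [getattr(r, item.field) for r in survivors
                  if getattr(r, item.field) is not None]
            dv = [getattr(r, item.field) for r in deaths
                  if getattr(r, item.field) is not None]
            try:
                if item.test == "welch_t":
                    stat, p = welch_t(sv, dv)
                elif item.test == "mann_whitney":
                    stat, p = mann_whitney(sv, dv)
                else:
                    raise ValueError(f"unknown test {item.test!r}")
            except ValueError as err:
                if "unknown test" in str(err):
                    raise
                stat = p = None
        out.append(UnivariateResult(item.name, s_sum, d_sum, test_name,
                                    stat, p))
    return out


def default_variable_plan(include_encephalopathy: bool = True
                          ) -> list[VariablePlan]:
    """The standard admission-variable plan (summary kinds follow the usual
    cohort-table presentation: symmetric variables as mean (range),
    right-skewed labs as median (IQR))."""
    plan = [
        VariablePlan("Age", "age", "mean_range", "welch_t"),
        VariablePlan("Gender, male", "sex", "count_percent", "categorical",
                     ("male",)),
        VariablePlan("Alcoholic aetiology", "alcoholic_aetiology",
                     "count_percent", "categorical", (True,)),
        VariablePlan("Ascites, any", "ascites", "count_percent",
                     "categorical", ("mild", "severe")),
        VariablePlan("Sodium", "sodium", "mean_range", "welch_t"),
        VariablePlan("Potassium", "potassium", "mean_range", "welch_t"),
        VariablePlan("Urea", "urea", "median_iqr", "mann_whitney"),
        VariablePlan("Lactate", "lactate", "median_iqr", "mann_whitney"),
        VariablePlan("Creatinine", "creatinine", "median_iqr", "mann_whitney"),
        VariablePlan("WCC", "wcc", "mean_range", "welch_t"),
        VariablePlan("Bilirubin", "bilirubin", "median_iqr", "mann_whitney"),
        VariablePlan("PT ratio", "pt_ratio", "median_iqr", "mann_whitney"),
        VariablePlan("Albumin", "albumin", "mean_range", "welch_t"),
        VariablePlan("Platelets", "platelets", "mean_range", "welch_t"),
        VariablePlan("PaO2", "pao2", "median_iqr", "mann_whitney"),
        VariablePlan("PaO2/FiO2 ratio", "pf_ratio", "median_iqr",
                     "mann_whitney"),
    ]
    if include_encephalopathy:
        plan.insert(3, VariablePlan("Encephalopathy, any", "encephalopathy",
                                    "count_percent", "categorical",
                                    (1, 2, 3, 4)))
    return plan


def format_p(p: float | None, floor: float = 0.001) -> str:
    if p is None:
        return "NA"
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.3g}"


def results_to_csv(results: Sequence[UnivariateResult], path) -> None:
    """Write table-style rows: variable, group summaries, test, p."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["variable", "summary_survivor", "summary_death",
                         "test", "p"])
        for r in results:
            writer.writerow([r.variable, r.survivor_summary.formatted(),
                             r.death_summary.formatted(), r.test,
                             format_p(r.p_value)])
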
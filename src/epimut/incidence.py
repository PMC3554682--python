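"""Disease incidence tables and significance tests.

Incidence is affected/evaluated per lineage x generation x sex x disease.
For an individual disease the denominator counts only animals with a
determinate call (present or absent); the derived "total disease" (one or
more diseases) and "multiple disease" (more than one) rows use all listed
animals in the stratum as denominator, so they are minimal incidences.
Treated-vs-control incidence is tested by logistic regression on a
treatment indicator (Wald test on the log odds ratio), falling back to
Fisher's exact test when a zero cell makes the logistic fit non-estimable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import ABSENT, DiseaseMatrix, ND, PRESENT
from .simulate import CohortTable

__all__ = [
    "TestResult",
    "incidence_percent",
    "build_incidence",
    "logistic_incidence_test",
    "group_mean_test",
    "litter_representation_check",
    "stars",
]

logger = logging.getLogger(__name__)

TOTAL_DISEASE = "total_disease"
MULTIPLE_DISEASE = "multiple_disease"


@dataclass(frozen=True)
class TestResult:
    label: str
    estimate: float
    statistic: float
    p: float
    method: str
    flag: str = ""


def stars(p: float) -> str:
    """Figure-legend significance code: * p<0.05, ** p<0.01, *** p<0.001."""
    if not math.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def incidence_percent(affected: int, evaluated: int) -> int:
    """Integer percent incidence, round-half-up (7/9 -> 78, 5/9 -> 56)."""
    if evaluated == 0:
        raise ValueError("no animals evaluated")
    if not (0 <= affected <= evaluated):
        raise ValueError(f"affected={affected} outside [0, evaluated={evaluated}]")
    return int(math.floor(100.0 * affected / evaluated + 0.5))


def build_incidence(
    matrix: DiseaseMatrix, grouping: tuple[str, ...] = ("lineage", "generation", "sex")
) -> pd.DataFrame:
    """Affected/evaluated/percent per stratum per disease, plus derived rows.

    Individual-disease denominators exclude not_determined animals; the
    total-disease and multiple-disease denominators are all listed animals
    in the stratum.
    """
    joined = matrix.statuses.join(matrix.meta)
    n_dis = matrix.n_diseases
    rows = []
    for keys, grp in joined.groupby(list(grouping), sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        if len(grp) == 0:
            logger.warning("empty stratum %s: row omitted", keys)
            continue
        for disease in matrix.statuses.columns:
            col = grp[disease]
            evaluated = int((col != ND).sum())
            affected = int((col == PRESENT).sum())
            if evaluated == 0:
                # e.g. ovarian endpoints in males: structurally not determined
                logger.debug("disease %s never determined in stratum %s", disease, keys)
                continue
            rows.append(
                (*keys, disease, affected, evaluated, incidence_percent(affected, evaluated))
            )
        totals = n_dis.loc[grp.index]
        n_all = len(grp)
        rows.append(
            (*keys, TOTAL_DISEASE, int((totals >= 1).sum()), n_all,
             incidence_percent(int((totals >= 1).sum()), n_all))
        )
        rows.append(
            (*keys, MULTIPLE_DISEASE, int((totals > 1).sum()), n_all,
             incidence_percent(int((totals > 1).sum()), n_all))
        )
    return pd.DataFrame(rows, columns=[*grouping, "disease", "affected", "evaluated", "percent"])


def logistic_incidence_test(
    affected_t: int, n_t: int, affected_c: int, n_c: int, label: str = ""
) -> TestResult:
    """Treated-vs-control incidence via logistic regression.

    Fits intercept + treatment indicator by maximum likelihood (IRLS) and
    reports the odds ratio with a two-sided Wald p. A zero cell causes
    separation, so the result falls back to Fisher's exact test on the 2x2
    table, flagged ``zero_cell``; when both groups are all-affected or both
    all-unaffected the comparison is flagged ``non_estimable``.
    """
    if n_t < 1 or n_c < 1:
        raise ValueError("both groups need at least one animal")
    if not (0 <= affected_t <= n_t and 0 <= affected_c <= n_c):
        raise ValueError("affected counts outside [0, n]")
    a, b = affected_t, n_t - affected_t
    c, d = affected_c, n_c - affected_c
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        return TestResult(label, float("nan"), float("nan"), float("nan"),
                          "logistic", flag="non_estimable")
    if 0 in (a, b, c, d):
        orat, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return TestResult(label, float(orat), float("nan"), float(p),
                          "fisher_exact", flag="zero_cell")

    import statsmodels.api as sm

    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = sm.add_constant(np.concatenate([np.ones(n_t), np.zeros(n_c)]))
    fit = sm.Logit(y, x).fit(disp=0)
    beta = fit.params[1]
    return TestResult(
        label,
        estimate=float(np.exp(beta)),
        statistic=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        method="logistic",
    )


def group_mean_test(values_a, values_b, label: str = "") -> TestResult:
    """Two-sample Welch t-test on continuous endpoints (organ weights etc.)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        # degenerate (e.g. perfectly balanced litter counts): no evidence of
        # a difference when the constant values agree, certain one otherwise
        equal = a.mean() == b.mean()
        return TestResult(label, estimate=float(a.mean() - b.mean()),
                          statistic=0.0 if equal else float("inf"),
                          p=1.0 if equal else 0.0, method="welch_t", flag="zero_variance")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        label, estimate=float(a.mean() - b.mean()), statistic=float(t), p=float(p),
        method="welch_t",
    )


def litter_representation_check(
    matrix: DiseaseMatrix, cohort: CohortTable
) -> pd.DataFrame:
    """Litter-representation bias check, per disease and treated lineage.

    For each disease, counts the animals per litter actually evaluated
    (determinate call) in control vs each treated lineage and compares the
    per-litter counts with a Welch t-test; reports mean ± SEM and p. A group
    with a single litter is flagged not-testable.
    """
    joined = matrix.statuses.join(matrix.meta).join(
        cohort.animals.set_index("animal_id")["litter_id"], rsuffix="_c"
    )
    rows = []
    treated = [l for l in joined["lineage"].unique() if l != "control"]
    for disease in matrix.statuses.columns:
        det = joined[joined[disease] != ND]
        ctrl_counts = det[det["lineage"] == "control"].groupby("litter_id").size()
        for lin in treated:
            t_counts = det[det["lineage"] == lin].groupby("litter_id").size()
            label = f"{disease}: control vs {lin}"
            if len(ctrl_counts) < 2 or len(t_counts) < 2:
                rows.append((disease, lin, np.nan, np.nan, np.nan, np.nan, np.nan,
                             "not_testable"))
                continue
            res = group_mean_test(t_counts, ctrl_counts, label=label)
            rows.append(
                (
                    disease,
                    lin,
                    float(ctrl_counts.mean()),
                    float(ctrl_counts.sem()),
                    float(t_counts.mean()),
                    float(t_counts.sem()),
                    res.p,
                    "",
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "disease", "lineage", "control_mean", "control_sem",
            "treated_mean", "treated_sem", "p", "flag",
        ],
    )
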
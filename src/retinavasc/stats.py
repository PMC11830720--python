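"""Cohort group-comparison workflow.

Continuous variables are routed by a distribution gate: when every group
passes Shapiro-Wilk normality and Levene's homogeneity test (both at
alpha = 0.05), one-way ANOVA with unadjusted LSD pairwise t-tests (pooled
within-group variance) is used and descriptives are mean ± SD; otherwise
Kruskal-Wallis with pairwise Mann-Whitney U and median (P25, P75)
descriptives. Categorical variables get a chi-square contingency test.
Screened variables enter a single-block binary logistic regression, and
each marker's discrimination is summarized by the empirical ROC with the
Youden-optimal operating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "TestReport",
    "RocResult",
    "route_variable",
    "compare_groups",
    "logistic_screen",
    "roc_analysis",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: Canonical cohort group labels of the clinical design.
CANONICAL_GROUPS = ("non-diabetic", "pre-diabetes", "t2dm-no-dr", "t2dm-npdr")


@dataclass
class TestReport:
    variable: str
    route: str  # anova+lsd | kruskal+mannwhitney | chi-square
    omnibus_stat: float
    omnibus_p: float
    pairwise_p: pd.DataFrame  # symmetric matrix, NaN diagonal
    descriptives: Dict[str, str]
    group_sizes: Dict[str, int] = field(default_factory=dict)


@dataclass
class RocResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    direction: int  # +1: larger score -> positive; -1: orientation flipped
    fpr: np.ndarray = field(default_factory=lambda: np.array([]))
    tpr: np.ndarray = field(default_factory=lambda: np.array([]))


def _grouped(values_by_group: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    out = {}
    for g, v in values_by_group.items():
        arr = np.asarray(pd.Series(v).dropna(), dtype=float)
        if arr.size:
            out[g] = arr
    return out


def route_variable(values_by_group: Dict[str, Sequence], categorical: bool = False) -> str:
    """Choose the comparison route for one variable.

    Parametric only when every group passes Shapiro-Wilk at alpha = 0.05
    AND Levene's test accepts variance homogeneity; groups with fewer
    than 3 observations force the nonparametric route with a warning.
    """
    if categorical:
        return "chi-square"
    groups = _grouped({g: np.asarray(v, dtype=float) for g, v in values_by_group.items()})
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if any(v.size < 3 for v in groups.values()):
        logger.warning("a group has < 3 observations; using nonparametric route")
        return "kruskal+mannwhitney"
    for g, v in groups.items():
        if np.ptp(v) == 0:
            return "kruskal+mannwhitney"
        if sps.shapiro(v).pvalue < ALPHA:
            return "kruskal+mannwhitney"
    if sps.levene(*groups.values()).pvalue < ALPHA:
        return "kruskal+mannwhitney"
    return "anova+lsd"


def _lsd_pairwise(groups: Dict[str, np.ndarray]) -> pd.DataFrame:
    """Fisher LSD: pairwise t-tests with the pooled ANOVA error variance."""
    names = list(groups)
    n_total = sum(v.size for v in groups.values())
    k = len(names)
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / (n_total - k)
    df = n_total - k
    p = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = groups[a], groups[b]
            se = np.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
            t = (va.mean() - vb.mean()) / se
            pv = 2.0 * sps.t.sf(abs(t), df)
            p.loc[a, b] = p.loc[b, a] = pv
    return p


def _mwu_pairwise(groups: Dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    p = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pv = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
            p.loc[a, b] = p.loc[b, a] = pv
    return p


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    categorical: bool = False,
) -> TestReport:
    """Omnibus + pairwise comparison of one variable across groups."""
    if group_col not in table.columns or variable not in table.columns:
        raise ValueError(f"table must contain '{group_col}' and '{variable}'")
    by_group = {g: sub[variable] for g, sub in table.groupby(group_col, observed=True)}

    if categorical:
        contingency = pd.crosstab(table[group_col], table[variable])
        stat, p, _, _ = sps.chi2_contingency(contingency)
        names = list(contingency.index)
        pw = pd.DataFrame(np.nan, index=names, columns=names)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                sub = contingency.loc[[a, b]]
                sub = sub.loc[:, sub.sum(axis=0) > 0]
                pv = sps.chi2_contingency(sub)[1] if sub.shape[1] > 1 else 1.0
                pw.loc[a, b] = pw.loc[b, a] = pv
        desc = {
            g: ", ".join(f"{v}: {c}" for v, c in contingency.loc[g].items())
            for g in names
        }
        return TestReport(variable, "chi-square", float(stat), float(p), pw, desc,
                          {g: int(contingency.loc[g].sum()) for g in names})

    groups = _grouped(by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if all(np.ptp(v) == 0 for v in groups.values()) and len(
        {v[0] for v in groups.values()}
    ) == 1:
        raise ValueError(f"variable '{variable}' is constant; comparison degenerate")

    route = route_variable(groups)
    if route == "anova+lsd":
        stat, p = sps.f_oneway(*groups.values())
        if np.isnan(p) and abs(stat) < 1e-9:
            p = 1.0  # degenerate zero between-group variance
        pw = _lsd_pairwise(groups)
        desc = {g: f"{v.mean():.4g} ± {v.std(ddof=1):.4g}" for g, v in groups.items()}
    else:
        stat, p = sps.kruskal(*groups.values())
        pw = _mwu_pairwise(groups)
        desc = {
            g: f"{np.median(v):.4g} ({np.percentile(v, 25):.4g}, {np.percentile(v, 75):.4g})"
            for g, v in groups.items()
        }
    return TestReport(variable, route, float(stat), float(p), pw, desc,
                      {g: int(v.size) for g, v in groups.items()})


def logistic_screen(
    table: pd.DataFrame,
    predictors: Sequence[str],
    outcome_col: str = "outcome",
    positive_label=1,
) -> pd.DataFrame:
    """Single-block binary logistic regression over the screened predictors.

    Returns one row per predictor with beta, Wald chi2, SE, p, OR and its
    95% Wald CI. Perfect separation (or non-convergence) flags the fit
    and suppresses coefficients rather than reporting unstable numbers.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("no predictors given")
    cols = predictors + [outcome_col]
    sub = table[cols].dropna()
    y = (sub[outcome_col] == positive_label).astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome has a single class after dropping missing rows")
    X = sub[predictors].to_numpy(dtype=float)
    if np.any(np.ptp(X, axis=0) == 0):
        bad = [p for p, r in zip(predictors, np.ptp(X, axis=0)) if r == 0]
        raise ValueError(f"constant predictor(s): {bad}")
    Xc = sm.add_constant(X, has_constant="add")

    flagged = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        if not converged or not np.all(np.isfinite(fit.bse)) or np.any(
            np.abs(fit.params) > 50
        ):
            flagged = True
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        flagged = True
        fit = None

    rows = []
    for j, name in enumerate(predictors, start=1):
        if flagged or fit is None:
            rows.append(
                {"variable": name, "beta": np.nan, "wald_chi2": np.nan, "se": np.nan,
                 "p": np.nan, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "converged": False, "separation_flag": True}
            )
            continue
        beta = fit.params[j]
        se = fit.bse[j]
        wald = (beta / se) ** 2
        p = sps.chi2.sf(wald, df=1)
        rows.append(
            {
                "variable": name,
                "beta": beta,
                "wald_chi2": wald,
                "se": se,
                "p": p,
                "or": np.exp(beta),
                "ci_low": np.exp(beta - 1.96 * se),
                "ci_high": np.exp(beta + 1.96 * se),
                "converged": True,
                "separation_flag": False,
            }
        )
    return pd.DataFrame(rows)


def roc_analysis(scores: Sequence[float], labels: Sequence) -> RocResult:
    """Empirical ROC with trapezoidal AUC and the Youden operating point.

    For markers negatively associated with the outcome the orientation is
    flipped so the reported AUC is >= 0.5; ``direction`` records the
    flip. Sensitivity/specificity are taken at the threshold maximizing
    Youden's J = sensitivity + specificity - 1.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    y01 = (y == classes.max()).astype(int)

    direction = 1
    fpr, tpr, thr = roc_curve(y01, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    if auc < 0.5:
        direction = -1
        fpr, tpr, thr = roc_curve(y01, -scores, drop_intermediate=False)
        auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    sens = float(tpr[best])
    spec = float(1.0 - fpr[best])
    threshold = float(thr[best]) * direction
    return RocResult(auc, sens, spec, threshold, direction, fpr, tpr)
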
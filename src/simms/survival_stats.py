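"""Cox proportional-hazards estimation for genes and gene-pair interactions.

Node weights come from univariate Cox fits on median-dichotomized risk
groups. Edge weights come from a three-covariate Cox model over the two
gene groups and their XNOR term, which flags patients whose two interacting
genes fall in the same risk group (co-dysregulation):

    h(t) = h0(t) exp(b1*X_G1 + b2*X_G2 + b3*X_G1.G2),  X_G1.G2 = XNOR(G1, G2)

The interaction weight used downstream is b3. Significance is the two-sided
Wald test throughout. Kaplan–Meier curves and log-rank tests wrap lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ._cox import CoxFit, cox_fit
from .preprocess import SurvivalTable

__all__ = [
    "CoxResult",
    "InteractionResult",
    "xnor",
    "fit_cox_univariate",
    "fit_cox_interaction",
    "fit_cox_multivariate",
    "km_logrank",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class CoxResult:
    """One Cox coefficient with its hazard-ratio views and Wald test."""

    coefficient: float  # natural-log hazard-ratio scale
    se: float
    wald_p: float
    converged: bool = True
    n: int = 0
    n_events: int = 0

    @property
    def hr(self) -> float:
        return float(np.exp(self.coefficient))

    @property
    def log2_hr(self) -> float:
        return self.coefficient / _LN2

    @property
    def ci95(self) -> tuple[float, float]:
        delta = 1.959963984540054 * self.se
        return (float(np.exp(self.coefficient - delta)),
                float(np.exp(self.coefficient + delta)))

    @classmethod
    def non_estimable(cls, n: int = 0, n_events: int = 0) -> "CoxResult":
        """Flagged placeholder for fits that cannot be estimated; downstream
        filters drop it via wald_p = 1."""
        return cls(coefficient=0.0, se=np.inf, wald_p=1.0, converged=False,
                   n=n, n_events=n_events)


@dataclass(frozen=True)
class InteractionResult:
    """Three-covariate interaction fit; ``interaction`` is the b3 view."""

    beta1: CoxResult
    beta2: CoxResult
    beta3: CoxResult

    @property
    def interaction(self) -> CoxResult:
        return self.beta3


def xnor(g1, g2):
    """XNOR of two binary risk groups: 1 when a patient's two interacting
    genes fall in the same group."""
    a = np.asarray(g1)
    b = np.asarray(g2)
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("risk groups must be binary (0/1)")
    out = (a == b).astype(int)
    if isinstance(g1, pd.Series):
        return pd.Series(out, index=g1.index)
    return out if out.ndim else int(out)


def _wald_p(beta: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _result(fit: CoxFit, j: int) -> CoxResult:
    beta = float(fit.beta[j])
    se = float(fit.se[j])
    if not fit.converged or not np.isfinite(se):
        return CoxResult.non_estimable(fit.n, fit.n_events)
    return CoxResult(coefficient=beta, se=se, wald_p=_wald_p(beta, se),
                     converged=True, n=fit.n, n_events=fit.n_events)


def _align(survival: SurvivalTable, *series: pd.Series):
    ids = list(series[0].index)
    for s in series[1:]:
        if list(s.index) != ids:
            raise ValueError("risk-group vectors are not sample-aligned")
    surv = survival.subset(ids)
    return [np.asarray(s, dtype=float) for s in series], surv


def fit_cox_univariate(
    group: pd.Series, survival: SurvivalTable, ties: str = "efron"
) -> CoxResult:
    """Univariate Cox fit of a binary risk group against survival.

    A group that never varies or a cohort without events is not estimable
    and raises; monotone-likelihood fits (e.g. perfect separation of event
    order) come back flagged with ``wald_p = 1`` so downstream significance
    filters exclude them without aborting a genome-wide scan.
    """
    (g,), surv = _align(survival, group)
    if not np.isin(g, (0, 1)).all():
        raise ValueError("risk group must be binary (0/1)")
    if g.min() == g.max():
        raise ValueError("risk group is constant; hazard ratio undefined")
    if surv.event.sum() == 0:
        raise ValueError("no events in survival data")
    fit = cox_fit(g[:, None], surv.time.values, surv.event.values, ties=ties)
    return _result(fit, 0)


def fit_cox_interaction(
    g1: pd.Series, g2: pd.Series, survival: SurvivalTable, ties: str = "efron"
) -> InteractionResult:
    """Gene-pair interaction Cox model with XNOR co-dysregulation term.

    A collinear design (any of the three columns constant, or the pair of
    gene groups identical so the XNOR column is all ones) makes the
    interaction non-estimable; the affected coefficients are flagged rather
    than raising, since pathway-wide scans hit such pairs routinely.
    """
    (a, b), surv = _align(survival, g1, g2)
    inter = xnor(a.astype(int), b.astype(int)).astype(float)
    if surv.event.sum() == 0:
        raise ValueError("no events in survival data")
    X = np.column_stack([a, b, inter])
    # rank-deficient designs (constant column or duplicated pattern) are
    # not estimable as a 3-parameter model
    centered = X - X.mean(axis=0)
    if (centered == 0).all(axis=0).any() or np.linalg.matrix_rank(centered) < 3:
        na = CoxResult.non_estimable(len(a), int(surv.event.sum()))
        return InteractionResult(na, na, na)
    fit = cox_fit(X, surv.time.values, surv.event.values, ties=ties)
    return InteractionResult(_result(fit, 0), _result(fit, 1), _result(fit, 2))


def fit_cox_multivariate(
    X: pd.DataFrame, survival: SurvivalTable, ties: str = "efron"
) -> list[CoxResult]:
    """Multivariate Cox fit over arbitrary covariate columns."""
    surv = survival.subset(list(X.index))
    fit = cox_fit(X.values.astype(float), surv.time.values, surv.event.values,
                  ties=ties)
    return [_result(fit, j) for j in range(X.shape[1])]


@dataclass
class LogrankSummary:
    """Across-group log-rank test with per-group KM curves."""

    statistic: float
    p_value: float
    df: int
    km_curves: dict  # group label -> DataFrame(time, survival, ci_lower, ci_upper)


def km_logrank(groups: pd.Series, survival: SurvivalTable) -> LogrankSummary:
    """Log-rank chi-square across labeled risk groups plus KM estimates.

    Greenwood confidence intervals come from lifelines' KaplanMeierFitter.
    """
    surv = survival.subset(list(groups.index))
    labels = pd.Series(groups, index=groups.index)
    uniq = sorted(labels.unique(), key=str)
    if len(uniq) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(surv.time.values, labels.values,
                                    surv.event.values)
    curves = {}
    for lab in uniq:
        mask = (labels == lab).values
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time.values[mask], surv.event.values[mask])
        ci = kmf.confidence_interval_survival_function_
        curves[lab] = pd.DataFrame({
            "time": kmf.survival_function_.index,
            "survival": kmf.survival_function_["KM_estimate"].values,
            "ci_lower": ci.iloc[:, 0].values,
            "ci_upper": ci.iloc[:, 1].values,
        }).reset_index(drop=True)
    return LogrankSummary(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=len(uniq) - 1,
        km_curves=curves,
    )
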
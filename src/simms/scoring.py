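"""Module-dysregulation scores and per-patient subnetwork risk scores.

Each subnetwork is weighted on training data: nodes by the univariate Cox
log2 hazard ratio of the gene's median-dichotomized abundance, edges by the
XNOR-interaction coefficient of the gene pair. Three scoring models exist:

* **N** — nodes only: assumes independent additive gene effects,
* **E** — edges only: only dysregulated interactions carry signal,
* **NE** — both.

The module-dysregulation score (MDS) ranks subnetworks by outcome
association strength::

    MDS(k) = sum_i |log2 HR_i| + sum_j |log2 HR_j|     (Wald P < alpha terms)

while a patient's risk score uses SIGNED log2 hazard ratios times the
patient's scaled abundance (nodes) or abundance product (edges)::

    risk(SN, t) = sum_i log2(HR_i) * X_ti  +  sum_j log2(HR_j) * X_tjx * X_tjy

The asymmetry is intentional: MDS measures strength, risk needs direction.
The risk-score filter (Wald P < 0.5 by default) only drops weights from
fits the Cox model could not estimate stably.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway_db import Edge, Subnetwork, SubnetworkDB
from .preprocess import ExpressionMatrix, SurvivalTable, dichotomize
from .survival_stats import (
    CoxResult,
    fit_cox_interaction,
    fit_cox_univariate,
    km_logrank,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MODELS",
    "SubnetworkWeights",
    "ModuleScore",
    "estimate_weights",
    "mds",
    "rank_subnetworks",
    "patient_risk",
    "risk_matrix",
    "evaluate_subnetwork",
]

MODELS = ("N", "E", "NE")

Weight = tuple[float, float]  # (log2_hr, wald_p)


def _check_model(model: str) -> str:
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    return model


@dataclass
class SubnetworkWeights:
    """Training-derived node/edge weights for one subnetwork.

    ``node_medians`` freezes the training dichotomization thresholds so the
    exact training risk-group definition can be reused later.
    """

    subnetwork_id: str
    node_weights: dict[str, Weight] = field(default_factory=dict)
    edge_weights: dict[Edge, Weight] = field(default_factory=dict)
    node_medians: dict[str, float] = field(default_factory=dict)
    n_unmeasured: int = 0

    @property
    def empty(self) -> bool:
        return not self.node_weights and not self.edge_weights


@dataclass(frozen=True)
class ModuleScore:
    subnetwork_id: str
    model: str
    mds: float

    def __post_init__(self) -> None:
        if self.mds < 0:
            raise ValueError("MDS is a sum of absolute values; must be >= 0")


def _weight(res: CoxResult) -> Weight:
    return (res.log2_hr, res.wald_p)


def estimate_weights(
    db: SubnetworkDB,
    expression: ExpressionMatrix,
    survival: SurvivalTable,
    model: str = "NE",
    ties: str = "efron",
) -> dict[str, SubnetworkWeights]:
    """Fit Cox weights for every subnetwork on (pooled) training data.

    Node weights: univariate Cox on the gene's training-median dichotomized
    abundance. Edge weights (models E/NE): the XNOR-interaction coefficient
    b3 from the gene-pair Cox model. Genes absent from the expression matrix
    get no weight; a subnetwork with no measurable member is flagged empty.
    Per-gene fits are cached across subnetworks sharing genes.
    """
    _check_model(model)
    expr = expression.values
    surv = survival.subset(list(expr.columns))

    gene_cache: dict[str, tuple[float, pd.Series, CoxResult | None]] = {}

    def gene_fit(gene: str):
        if gene not in gene_cache:
            vals = expr.loc[gene]
            med = float(vals.median())
            grp = dichotomize(vals, med)
            if grp.min() == grp.max():
                res = None  # degenerate split; no weight
            else:
                res = fit_cox_univariate(grp, surv, ties=ties)
            gene_cache[gene] = (med, grp, res)
        return gene_cache[gene]

    edge_cache: dict[Edge, CoxResult] = {}
    out: dict[str, SubnetworkWeights] = {}
    for sn in db:
        w = SubnetworkWeights(sn.subnetwork_id)
        measured = [g for g in sorted(sn.nodes) if g in expr.index]
        w.n_unmeasured = len(sn.nodes) - len(measured)
        if w.n_unmeasured:
            logger.info("%s: %d gene(s) not measured in %s",
                        sn.subnetwork_id, w.n_unmeasured, expression.dataset_id)
        for g in measured:
            med, _, res = gene_fit(g)
            w.node_medians[g] = med
            if model in ("N", "NE") and res is not None:
                w.node_weights[g] = _weight(res)
        if model in ("E", "NE"):
            for e in sorted(sn.edges):
                a, b = e
                if a not in expr.index or b not in expr.index:
                    continue
                if e not in edge_cache:
                    _, ga, ra = gene_fit(a)
                    _, gb, rb = gene_fit(b)
                    if ra is None or rb is None:
                        edge_cache[e] = CoxResult.non_estimable()
                    else:
                        edge_cache[e] = fit_cox_interaction(
                            ga, gb, surv, ties=ties
                        ).interaction
                res = edge_cache[e]
                if res.converged:
                    w.edge_weights[e] = _weight(res)
        if w.empty:
            logger.warning("%s: no measurable genes; weights empty",
                           sn.subnetwork_id)
        out[sn.subnetwork_id] = w
    return out


def mds(weights: SubnetworkWeights, model: str = "NE",
        alpha: float = 0.05) -> ModuleScore:
    """Module-dysregulation score: sum of |log2 HR| over significant terms.

    Terms (nodes and/or edges per the model) enter only with Wald P below
    ``alpha``; a subnetwork with no qualifying term scores 0.
    """
    _check_model(model)
    total = 0.0
    if model in ("N", "NE"):
        total += sum(abs(l2) for l2, p in weights.node_weights.values()
                     if p < alpha)
    if model in ("E", "NE"):
        total += sum(abs(l2) for l2, p in weights.edge_weights.values()
                     if p < alpha)
    return ModuleScore(weights.subnetwork_id, model, total)


def rank_subnetworks(scores: list[ModuleScore], top_n: int) -> list[str]:
    """Rank candidate prognostic features by descending MDS (ties by id)."""
    models = {s.model for s in scores}
    if len(models) > 1:
        raise ValueError(f"scores mix models: {sorted(models)}")
    if top_n > len(scores):
        warnings.warn(
            f"top_n={top_n} exceeds {len(scores)} available subnetworks; "
            "returning all", stacklevel=2)
    ordered = sorted(scores, key=lambda s: (-s.mds, s.subnetwork_id))
    return [s.subnetwork_id for s in ordered[:top_n]]


def patient_risk(
    weights: SubnetworkWeights,
    expression: ExpressionMatrix,
    model: str = "NE",
    p_filter: float = 0.5,
) -> pd.Series:
    """Per-patient subnetwork risk score (signed log2 HR times abundance).

    Node terms: log2(HR_i) * X_ti; edge terms: log2(HR_j) * X_tjx * X_tjy,
    summed over weights whose Wald P is below ``p_filter`` (a loose screen
    that only removes unstable fits). Genes missing from the patient
    platform contribute zero, keeping scores comparable across platforms;
    the missing count is logged.
    """
    _check_model(model)
    expr = expression.values
    risk = pd.Series(0.0, index=expr.columns, name=weights.subnetwork_id)
    n_missing = 0
    if model in ("N", "NE"):
        for g, (l2, p) in weights.node_weights.items():
            if p >= p_filter:
                continue
            if g not in expr.index:
                n_missing += 1
                continue
            risk += l2 * expr.loc[g]
    if model in ("E", "NE"):
        for (a, b), (l2, p) in weights.edge_weights.items():
            if p >= p_filter:
                continue
            if a not in expr.index or b not in expr.index:
                n_missing += 1
                continue
            risk += l2 * expr.loc[a] * expr.loc[b]
    if n_missing:
        logger.info("%s: %d weighted term(s) unmeasured on this platform",
                    weights.subnetwork_id, n_missing)
    return risk


def risk_matrix(
    weights: dict[str, SubnetworkWeights],
    expression: ExpressionMatrix,
    model: str = "NE",
    p_filter: float = 0.5,
    subnetwork_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Samples × subnetworks matrix of risk scores (Y_ij)."""
    ids = subnetwork_ids if subnetwork_ids is not None else sorted(weights)
    cols = {sid: patient_risk(weights[sid], expression, model, p_filter)
            for sid in ids}
    out = pd.DataFrame(cols, index=expression.values.columns)
    out.attrs["model"] = model
    out.attrs["p_filter"] = p_filter
    return out


@dataclass
class SubnetworkEvaluation:
    """Validation-cohort assessment of one subnetwork's training risk model."""

    groups: pd.Series  # validation sample -> group index
    cox: CoxResult | None  # median mode: high vs low
    quartile_cox: dict[str, CoxResult] | None  # Q2..Q4, each vs Q1
    logrank_p: float | None
    thresholds: list[float]
    flagged: str | None = None


def _assign_groups(scores: pd.Series, thresholds: list[float]) -> pd.Series:
    """Group index by frozen thresholds: count of thresholds strictly below
    the score (score == threshold falls low, matching dichotomize)."""
    arr = np.asarray(scores, dtype=float)
    grp = np.zeros(len(arr), dtype=int)
    for t in thresholds:
        grp += (arr > t).astype(int)
    return pd.Series(grp, index=scores.index)


def evaluate_subnetwork(
    training_risk: pd.Series,
    validation_risk: pd.Series,
    validation_survival: SurvivalTable,
    grouping: str = "median",
) -> SubnetworkEvaluation:
    """Transfer training risk thresholds to a validation cohort and test.

    Thresholds (median, or quartile cuts) are computed on TRAINING scores
    only and applied to validation scores; the resulting validation groups
    are tested with Cox models (quartile mode: Q2–Q4 each against Q1) and an
    across-group log-rank test. Degenerate group assignments (all samples on
    one side) are flagged, not raised.
    """
    if grouping not in ("median", "quartile"):
        raise ValueError("grouping must be 'median' or 'quartile'")
    tr = np.asarray(training_risk, dtype=float)
    if np.ptp(tr) == 0:
        raise ValueError("training risk scores are constant")
    if grouping == "median":
        thresholds = [float(np.median(tr))]
    else:
        thresholds = [float(np.quantile(tr, q)) for q in (0.25, 0.5, 0.75)]
    groups = _assign_groups(validation_risk, thresholds)
    surv = validation_survival.subset(list(groups.index))

    if groups.nunique() < 2:
        return SubnetworkEvaluation(groups, None, None, None, thresholds,
                                    flagged="all validation samples in one group")
    lr = km_logrank(groups, surv)
    if grouping == "median":
        cox = fit_cox_univariate(groups, surv)
        return SubnetworkEvaluation(groups, cox, None, lr.p_value, thresholds)
    qcox: dict[str, CoxResult] = {}
    for q in (1, 2, 3):
        in_contrast = groups.isin([0, q])
        if groups[in_contrast].nunique() < 2:
            continue  # empty quartile: HR omitted for that contrast
        g = (groups[in_contrast] == q).astype(int)
        qcox[f"Q{q + 1}"] = fit_cox_univariate(g, surv.subset(list(g.index)))
    return SubnetworkEvaluation(groups, None, qcox, lr.p_value, thresholds)
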
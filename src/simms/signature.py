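"""Multi-subnetwork signature construction and validation.

Candidate subnetworks (ranked by MDS) are combined into one prognostic
model: coefficients come from an L1-penalized Cox fit with cross-validated
penalty choice (or AIC stepwise selection), and a patient's combined risk is

    risk_i = sum_j beta_j * Y_ij

over the selected subnetworks, where Y_ij is the patient's subnetwork risk
score. The median and quartile cut points of the combined score are frozen
on the training cohort and transferred unchanged to validation cohorts.

Signature size is calibrated against an empirical null: random subnetwork
sets of each candidate size are fitted the same way and the performance of
the top-MDS set is compared with the size-matched null distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._cox import cox_fit, cox_loglik
from .preprocess import SurvivalTable, dichotomize
from .scoring import _assign_groups
from .survival_stats import CoxResult, fit_cox_univariate, km_logrank

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureModel",
    "NullDistribution",
    "random_classifier_null",
    "training_performance",
    "choose_n_subnetworks",
    "select_l1",
    "select_stepwise",
    "combined_risk",
    "validate_signature",
]

_LN2 = np.log(2.0)


@dataclass
class SignatureModel:
    """Selected subnetworks with coefficients and frozen training thresholds."""

    selected: dict[str, float]  # subnetwork id -> beta
    training_median: float
    training_quartiles: tuple[float, float, float]  # Q1 < Q2 < Q3 cut points
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.selected.values()))):
            raise ValueError("non-finite signature coefficients")
        q1, q2, q3 = self.training_quartiles
        if not (q1 <= q2 <= q3):
            raise ValueError("training quartile cut points out of order")

    @property
    def m(self) -> int:
        return len(self.selected)

    def to_files(self, coef_path: str | Path, meta_path: str | Path) -> None:
        pd.DataFrame(
            {"subnetwork_id": list(self.selected),
             "beta": list(self.selected.values())}
        ).to_csv(coef_path, sep="\t", index=False)
        with open(meta_path, "w") as fh:
            json.dump({
                "training_median": self.training_median,
                "training_quartiles": list(self.training_quartiles),
                "provenance": self.provenance,
            }, fh, indent=2)

    @classmethod
    def from_files(cls, coef_path: str | Path, meta_path: str | Path
                   ) -> "SignatureModel":
        coefs = pd.read_csv(coef_path, sep="\t", comment="#")
        with open(meta_path) as fh:
            meta = json.load(fh)
        return cls(
            selected=dict(zip(coefs["subnetwork_id"].astype(str),
                              coefs["beta"].astype(float))),
            training_median=float(meta["training_median"]),
            training_quartiles=tuple(meta["training_quartiles"]),
            provenance=meta.get("provenance", {}),
        )


@dataclass
class NullDistribution:
    """Per-size samples of |log2 HR| from random subnetwork-set classifiers."""

    samples: dict[int, np.ndarray]
    reps: int
    seed: int
    n_resampled: int = 0

    def quantile_of(self, size: int, value: float) -> float:
        """Fraction of the size-matched null the value exceeds."""
        null = self.samples[size]
        return float(np.mean(null < value))


def _classifier_log2_hr(Y: pd.DataFrame, survival: SurvivalTable
                        ) -> float | None:
    """|log2 HR| of a subnetwork-set classifier.

    Fits a multivariate Cox model on the risk columns, median-dichotomizes
    the fitted combined score, and returns the absolute log2 hazard ratio of
    the resulting two-group univariate fit. None when the fit is singular
    (constant columns are excluded first; a fully constant set is singular).
    """
    keep = Y.columns[Y.std(axis=0) > 0]
    if len(keep) == 0:
        return None
    X = Y[keep]
    surv = survival.subset(list(X.index))
    fit = cox_fit(X.values, surv.time.values, surv.event.values)
    if not fit.converged:
        return None
    combined = pd.Series(X.values @ fit.beta, index=X.index)
    grp = dichotomize(combined, float(combined.median()))
    if grp.min() == grp.max():
        return None
    res = fit_cox_univariate(grp, surv)
    if not res.converged:
        return None
    return abs(res.log2_hr)


def random_classifier_null(
    risk: pd.DataFrame,
    survival: SurvivalTable,
    sizes: list[int],
    reps: int = 200,
    seed: int = 0,
) -> NullDistribution:
    """Empirical null: performance of randomly sampled subnetwork sets.

    For each size, ``reps`` uniform random subsets of the risk-matrix
    columns are scored with :func:`_classifier_log2_hr`. Singular draws are
    resampled (counted); reproducible under the seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_cols = risk.shape[1]
    if max(sizes) > n_cols:
        raise ValueError(f"size {max(sizes)} exceeds {n_cols} subnetworks")
    rng = np.random.default_rng(seed)
    cols = np.array(risk.columns)
    samples: dict[int, np.ndarray] = {}
    n_resampled = 0
    for size in sizes:
        vals = []
        attempts = 0
        while len(vals) < reps and attempts < 50 * reps:
            attempts += 1
            pick = rng.choice(cols, size=size, replace=False)
            v = _classifier_log2_hr(risk[list(pick)], survival)
            if v is None:
                n_resampled += 1
                continue
            vals.append(v)
        if len(vals) < reps:
            raise RuntimeError(
                f"null sampling at size {size}: too many singular fits")
        samples[size] = np.array(vals)
    if n_resampled:
        logger.info("null sampling: %d singular draw(s) resampled", n_resampled)
    return NullDistribution(samples=samples, reps=reps, seed=seed,
                            n_resampled=n_resampled)


def training_performance(
    risk: pd.DataFrame,
    survival: SurvivalTable,
    ranked_ids: list[str],
    sizes: list[int],
) -> dict[int, float]:
    """Training |log2 HR| of the top-MDS classifier at each candidate size."""
    out: dict[int, float] = {}
    for size in sizes:
        v = _classifier_log2_hr(risk[ranked_ids[:size]], survival)
        out[size] = v if v is not None else 0.0
    return out


def choose_n_subnetworks(
    null: NullDistribution, performance: dict[int, float]
) -> int:
    """Signature size whose training performance most exceeds its null.

    Picks the size with the largest exceedance quantile against the
    size-matched null distribution; exact ties go to the smallest size.
    """
    sizes = sorted(performance)
    missing = [s for s in sizes if s not in null.samples]
    if missing:
        raise KeyError(f"null distribution missing sizes {missing}")
    best_size, best_q = None, -1.0
    for size in sizes:
        q = null.quantile_of(size, performance[size])
        if q > best_q:
            best_size, best_q = size, q
    return best_size


def _thresholds(combined: pd.Series):
    arr = np.asarray(combined, dtype=float)
    return (float(np.median(arr)),
            tuple(float(np.quantile(arr, q)) for q in (0.25, 0.5, 0.75)))


def _event_folds(event: np.ndarray, folds: int, seed: int):
    """Fold assignment stratified by event status (no event-free folds)."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(event)), event))


def select_l1(
    risk: pd.DataFrame,
    survival: SurvivalTable,
    folds: int = 10,
    seed: int = 0,
    l1_ratio: float = 1.0,
    n_alphas: int = 50,
) -> SignatureModel:
    """L1-penalized Cox over subnetwork risk features, CV-tuned penalty.

    The coordinate-descent regularization path comes from scikit-survival's
    Coxnet; the penalty is chosen by cross-validated partial-likelihood
    deviance (Verweij–van Houwelingen: ll(all data; beta_k) − ll(train
    folds; beta_k), summed over folds) with folds stratified by event
    status. Nonzero coefficients at the optimum form the signature;
    ``l1_ratio`` < 1 gives an elastic net.
    """
    if risk.shape[1] < 2:
        raise ValueError("need at least 2 candidate subnetworks")
    surv = survival.subset(list(risk.index))
    X = risk.values.astype(float)
    time = surv.time.values
    event = surv.event.values
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=n_alphas,
                                  alpha_min_ratio=0.01, normalize=False)
    path.fit(X, y)
    alphas = path.alphas_

    cv_ll = np.zeros(len(alphas))
    for tr_idx, _ in _event_folds(event, folds, seed):
        m = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas,
                                   normalize=False)
        m.fit(X[tr_idx], Surv.from_arrays(event=event[tr_idx].astype(bool),
                                          time=time[tr_idx]))
        # the path may stop early on a fold; reuse its last solution for
        # the remaining (smaller) penalties
        n_avail = m.coef_.shape[1]
        for k in range(len(alphas)):
            beta = m.coef_[:, min(k, n_avail - 1)]
            ll_all = cox_loglik(beta, X, time, event)
            ll_tr = cox_loglik(beta, X[tr_idx], time[tr_idx], event[tr_idx])
            cv_ll[k] += ll_all - ll_tr
    best_k = int(np.argmax(cv_ll))
    beta = path.coef_[:, best_k]
    nz = np.flatnonzero(beta != 0.0)
    if nz.size == 0:
        raise ValueError(
            "L1 optimum shrank every coefficient to zero; widen the penalty "
            "grid (smaller alpha_min_ratio) or pass stronger candidates")
    selected = {risk.columns[j]: float(beta[j]) for j in nz}
    combined = pd.Series(X @ beta, index=risk.index)
    median, quartiles = _thresholds(combined)
    return SignatureModel(
        selected=selected,
        training_median=median,
        training_quartiles=quartiles,
        provenance={"method": "l1", "folds": folds, "seed": seed,
                    "l1_ratio": l1_ratio, "alpha": float(alphas[best_k])},
    )


def _aic(ll: float, n_params: int) -> float:
    return -2.0 * ll + 2.0 * n_params


def select_stepwise(
    risk: pd.DataFrame,
    survival: SurvivalTable,
    direction: str = "backward",
) -> SignatureModel:
    """AIC stepwise Cox selection (backward elimination or forward)."""
    if direction not in ("backward", "forward"):
        raise ValueError("direction must be 'backward' or 'forward'")
    surv = survival.subset(list(risk.index))
    time, event = surv.time.values, surv.event.values
    all_cols = list(risk.columns)

    def fit_cols(cols: list[str]):
        if not cols:
            # null model: partial likelihood at beta = 0
            ll0 = cox_loglik(np.zeros(1), np.zeros((len(time), 1)), time, event)
            return None, _aic(ll0, 0)
        f = cox_fit(risk[cols].values, time, event)
        if not f.converged:
            return None, np.inf
        return f, _aic(f.loglik, len(cols))

    current = list(all_cols) if direction == "backward" else []
    fit, aic = fit_cols(current)
    improved = True
    while improved:
        improved = False
        if direction == "backward":
            moves = [[c for c in current if c != drop] for drop in current]
        else:
            moves = [current + [add] for add in all_cols if add not in current]
        best = None
        for cols in moves:
            f, a = fit_cols(cols)
            if a < aic - 1e-10:
                if best is None or a < best[2]:
                    best = (cols, f, a)
        if best is not None:
            current, fit, aic = best
            improved = True
    if not current:
        selected: dict[str, float] = {}
        combined = pd.Series(0.0, index=risk.index)
    else:
        selected = dict(zip(current, (float(b) for b in fit.beta)))
        combined = pd.Series(risk[current].values @ fit.beta, index=risk.index)
    median, quartiles = _thresholds(combined)
    return SignatureModel(
        selected=selected,
        training_median=median,
        training_quartiles=quartiles,
        provenance={"method": direction, "aic": float(aic)},
    )


def combined_risk(model: SignatureModel, risk: pd.DataFrame) -> pd.Series:
    """Combined patient risk: sum of beta_j * Y_ij over selected subnetworks."""
    missing = [c for c in model.selected if c not in risk.columns]
    if missing:
        raise KeyError(f"risk matrix missing selected subnetworks: {missing}")
    cols = list(model.selected)
    beta = np.array([model.selected[c] for c in cols])
    return pd.Series(risk[cols].values @ beta, index=risk.index,
                     name="combined_risk")


@dataclass
class SignatureValidation:
    """Held-out assessment of a signature under frozen training thresholds."""

    groups: pd.Series
    cox: CoxResult | None  # median grouping: high vs low
    quartile_cox: dict[str, CoxResult]  # quartile grouping: Q2..Q4 vs Q1
    logrank_p: float | None
    flagged: str | None = None


def validate_signature(
    model: SignatureModel,
    risk: pd.DataFrame,
    survival: SurvivalTable,
    grouping: str = "median",
) -> SignatureValidation:
    """Assign validation patients to risk groups by the TRAINING thresholds
    and test group separation (Cox hazard ratios, log-rank)."""
    if grouping not in ("median", "quartile"):
        raise ValueError("grouping must be 'median' or 'quartile'")
    combined = combined_risk(model, risk)
    thresholds = ([model.training_median] if grouping == "median"
                  else list(model.training_quartiles))
    groups = _assign_groups(combined, thresholds)
    surv = survival.subset(list(groups.index))
    if groups.nunique() < 2:
        return SignatureValidation(groups, None, {}, None,
                                   flagged="all samples in one risk group")
    lr = km_logrank(groups, surv)
    if grouping == "median":
        cox = fit_cox_univariate(groups, surv)
        return SignatureValidation(groups, cox, {}, lr.p_value)
    qcox: dict[str, CoxResult] = {}
    for q in (1, 2, 3):
        mask = groups.isin([0, q])
        sub = groups[mask]
        if sub.nunique() < 2:
            continue  # empty group: HR omitted for that contrast
        g = (sub == q).astype(int)
        qcox[f"Q{q + 1}"] = fit_cox_univariate(g, surv.subset(list(g.index)))
    return SignatureValidation(groups, None, qcox, lr.p_value)
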
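"""Synthetic cohorts and toy subnetwork databases with known ground truth.

The generator emulates the statistical shape of the data the pipeline
consumes — per-dataset z-scaled abundance matrices and right-censored
survival — with effects injected on the dichotomized scale the estimator
actually fits: a driver gene contributes ``effect`` to the log2 hazard when
its (standard-normal) abundance is above zero, so a per-gene ``effect`` of
1.0 is a true dichotomized hazard ratio of 2. Event times are exponential
given the per-patient hazard, which keeps event fractions analytically
checkable; censoring is exponential and/or administrative.

Driver modules occupy consecutive gene blocks from the start of the gene
panel (module k of size s covers genes ``g{k*s+1}..g{(k+1)*s}``), matching
the block layout of :func:`simulate_subnetwork_db` so a simulated cohort
and a simulated database pair up without bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway_db import Subnetwork, SubnetworkDB, _edge
from .preprocess import ExpressionMatrix, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "DriverModule",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_subnetwork_db",
    "gene_id",
    "module_genes",
]

_LN2 = np.log(2.0)


def gene_id(i: int) -> str:
    """Stable zero-padded gene identifier (0-based index)."""
    return f"g{i + 1:05d}"


def module_genes(module_index: int, genes_per_module: int) -> list[str]:
    """Gene block owned by one module under the shared block layout."""
    start = module_index * genes_per_module
    return [gene_id(i) for i in range(start, start + genes_per_module)]


@dataclass(frozen=True)
class DriverModule:
    """A block of outcome-driving genes sharing one per-gene effect size."""

    n_genes: int
    effect: float  # per-gene log2 hazard ratio of the above-median group

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("driver module needs at least one gene")
        if not np.isfinite(self.effect):
            raise ValueError("driver effect must be finite")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults describe a mid-sized expression study: 500 patients, a
    200-gene panel with one 10-gene driver module of per-gene dichotomized
    log2 hazard ratio 1.0, moderate within-module co-expression (rho = 0.3),
    exponential baseline hazard 0.1 per study-time unit and exponential
    censoring at half that rate (roughly two observed events per censored
    patient under the null).
    """

    n_samples: int = 500
    n_genes: int = 200
    driver_subnetworks: list[DriverModule] = field(
        default_factory=lambda: [DriverModule(n_genes=10, effect=1.0)])
    baseline_hazard: float = 0.1
    censoring_rate: float | None = 0.05
    censoring_time: float | None = None
    correlation: float = 0.3
    n_modalities: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("simulation seed is mandatory")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.censoring_rate is None and self.censoring_time is None:
            raise ValueError("need a censoring rate or administrative time")
        total = sum(d.n_genes for d in self.driver_subnetworks)
        if total > self.n_genes:
            raise ValueError(
                f"driver modules need {total} genes but panel has "
                f"{self.n_genes}")


@dataclass
class GroundTruth:
    """What the generator injected, for recovery checks."""

    driver_genes: list[list[str]]  # per driver module
    effects: list[float]
    modalities: list[str]
    event_fraction: float
    seed: int


def _modality_matrix(cfg: SimulationConfig, rng: np.random.Generator
                     ) -> np.ndarray:
    """Genes × samples standard-normal values, equicorrelated within each
    driver module (x = sqrt(rho)*shared + sqrt(1-rho)*own)."""
    x = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    if cfg.correlation > 0:
        start = 0
        for drv in cfg.driver_subnetworks:
            shared = rng.standard_normal(cfg.n_samples)
            block = slice(start, start + drv.n_genes)
            x[block] = (np.sqrt(cfg.correlation) * shared
                        + np.sqrt(1.0 - cfg.correlation) * x[block])
            start += drv.n_genes
    return x


def simulate_cohort(cfg: SimulationConfig
                    ) -> tuple[list[ExpressionMatrix], SurvivalTable,
                               GroundTruth]:
    """Draw one cohort: per-modality expression, survival, ground truth.

    The per-patient log2-scale linear predictor sums ``effect * 1[x > 0]``
    over every driver gene in every modality, so with two modalities each
    driver gene contributes its effect once per modality. Event times are
    exponential with hazard ``h0 * exp(predictor * ln 2)``; censoring is
    independent. Bit-identical under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_ids = [f"s{i + 1:05d}" for i in range(cfg.n_samples)]
    feature_ids = [gene_id(i) for i in range(cfg.n_genes)]
    labels = (["mRNA"] if cfg.n_modalities == 1
              else ["mRNA", "CNA"][:cfg.n_modalities]
              + [f"mod{k + 1}" for k in range(2, cfg.n_modalities)])

    matrices: list[ExpressionMatrix] = []
    predictor = np.zeros(cfg.n_samples)
    driver_genes: list[list[str]] = []
    start = 0
    for drv in cfg.driver_subnetworks:
        driver_genes.append(feature_ids[start:start + drv.n_genes])
        start += drv.n_genes
    for label in labels:
        x = _modality_matrix(cfg, rng)
        start = 0
        for drv in cfg.driver_subnetworks:
            block = x[start:start + drv.n_genes]
            predictor += drv.effect * (block > 0).sum(axis=0)
            start += drv.n_genes
        matrices.append(ExpressionMatrix(
            label, pd.DataFrame(x, index=feature_ids, columns=sample_ids)))

    hazard = cfg.baseline_hazard * np.exp(predictor * _LN2)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = np.full(cfg.n_samples, np.inf)
    if cfg.censoring_rate:
        t_cens = rng.exponential(1.0 / cfg.censoring_rate, cfg.n_samples)
    if cfg.censoring_time is not None:
        t_cens = np.minimum(t_cens, cfg.censoring_time)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    frac = float(event.mean())
    if frac == 0.0:
        raise ValueError(
            f"no events: baseline hazard {cfg.baseline_hazard} too small "
            f"against censoring (rate {cfg.censoring_rate}, "
            f"time {cfg.censoring_time})")
    if frac == 1.0:
        logger.warning("cohort has no censored samples; censoring config "
                       "may be ineffective")
    surv = SurvivalTable(pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(sample_ids)))
    truth = GroundTruth(
        driver_genes=driver_genes,
        effects=[d.effect for d in cfg.driver_subnetworks],
        modalities=labels,
        event_fraction=frac,
        seed=cfg.seed,
    )
    return matrices, surv, truth


def simulate_subnetwork_db(
    n_modules: int,
    genes_per_module: int,
    seed: int,
    overlap_spec: dict[tuple[int, int], int] | None = None,
    extra_edges: int = 2,
    module_sizes: list[int] | None = None,
) -> SubnetworkDB:
    """Random connected interaction modules over the block gene layout.

    Each module is a uniform random spanning tree over its gene block plus
    ``extra_edges`` additional random edges (so default modules pass the
    three-edge filter). ``overlap_spec`` maps a module pair ``(i, j)`` with
    i < j to a shared gene count: module j's first genes are replaced by
    module i's, producing partial duplicates for redundancy-filter tests.
    ``module_sizes`` overrides the uniform size with per-module gene counts
    over consecutive blocks (e.g. one large driver module followed by small
    null modules). Pre-filter output: redundancy is deliberately not
    removed here.
    """
    if n_modules < 1 or genes_per_module < 2:
        raise ValueError("need >= 1 module and >= 2 genes per module")
    if module_sizes is not None and len(module_sizes) != n_modules:
        raise ValueError("module_sizes must list one size per module")
    sizes = module_sizes or [genes_per_module] * n_modules
    starts = np.r_[0, np.cumsum(sizes)]
    overlap_spec = overlap_spec or {}
    for (i, j), k in overlap_spec.items():
        if not (0 <= i < j < n_modules):
            raise ValueError(f"overlap pair ({i}, {j}) out of range")
        if k > min(sizes[i], sizes[j]):
            raise ValueError(
                f"cannot share {k} genes; modules have {sizes[i]}/{sizes[j]}")
    rng = np.random.default_rng(seed)
    subnetworks = []
    for m in range(n_modules):
        genes = [gene_id(i) for i in range(starts[m], starts[m] + sizes[m])]
        for (i, j), k in overlap_spec.items():
            if j == m:
                donor = [gene_id(x)
                         for x in range(starts[i], starts[i] + sizes[i])]
                genes = donor[:k] + genes[k:]
        genes = list(dict.fromkeys(genes))
        perm = [genes[i] for i in rng.permutation(len(genes))]
        edges = set()
        for idx in range(1, len(perm)):  # random spanning tree
            parent = perm[int(rng.integers(0, idx))]
            edges.add(_edge(parent, perm[idx]))
        attempts = 0
        while len(edges) < len(perm) - 1 + extra_edges and attempts < 100:
            a, b = rng.choice(genes, size=2, replace=False)
            if a != b:
                edges.add(_edge(a, b))
            attempts += 1
        pid = f"M{m + 1:03d}"
        subnetworks.append(Subnetwork(f"{pid}.1", pid, frozenset(genes),
                                      frozenset(edges)))
    return SubnetworkDB(subnetworks, provenance={
        "generator": "simulate_subnetwork_db", "seed": seed,
        "n_modules": n_modules, "genes_per_module": genes_per_module,
        "filtered": False,
    })
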
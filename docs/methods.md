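# Methods

## The model

The package treats a pathway not as a gene list but as an interaction
graph, and each connected component of that graph — a *subnetwork module*
— as one candidate prognostic feature. The statistical machinery has three
layers.

**Node and edge weights.** On training data, every gene's abundance is
z-scored within its dataset and median-dichotomized into a binary risk
group `X_G ∈ {0, 1}`. A gene's *node weight* is the log2 hazard ratio from
a univariate Cox proportional-hazards fit of that group. An interaction's
*edge weight* comes from the three-covariate model

    h(t) = h0(t) · exp(β1·X_G1 + β2·X_G2 + β3·X_G1.G2),

where `X_G1.G2 = XNOR(X_G1, X_G2)` is 1 exactly when the two interacting
genes fall in the same risk group — a co-dysregulation indicator. The edge
weight is β3 (in log2 units). All fits use the Efron tie correction
(Breslow available by flag) and two-sided Wald tests.

**Module-dysregulation score (MDS).** A subnetwork's association strength
is the sum of absolute log2 hazard ratios over its significant terms:

    MDS(k) = Σ_i |log2 HR_i| + Σ_j |log2 HR_j|      (terms with Wald P < α, default 0.05)

Model N keeps the node sum only, Model E the edge sum only, Model N+E
both, so MDS(N+E) = MDS(N) + MDS(E) identically. Subnetworks are ranked by
MDS to shortlist candidate features.

**Patient risk scores.** A patient's score for a subnetwork uses *signed*
weights times the patient's scaled abundance:

    risk(SN, t) = Σ_i log2(HR_i)·X_ti + Σ_j log2(HR_j)·X_tjx·X_tjy

summed over terms with Wald P < 0.5. The node/edge asymmetry between the
two formulas is intentional: MDS measures strength regardless of
direction, the risk score needs direction. The loose 0.5 screen exists
only to drop weights from fits the Cox model could not estimate stably;
both thresholds are exposed parameters. Genes a validation platform does
not measure contribute zero, keeping scores comparable across platforms
(the unmeasured count is logged).

**Signatures.** Risk columns of the top-ranked subnetworks feed an
L1-penalized Cox model (optionally elastic-net, or AIC stepwise in either
direction). The penalty is chosen by cross-validated partial-likelihood
deviance (Verweij–van Houwelingen) with folds stratified by event status
so no fold is event-free. The combined risk of patient *i* is
`Σ_j β_j·Y_ij` over selected subnetworks. The median and quartile cut
points of the combined training score are frozen into the model; held-out
cohorts are grouped by those cut points only and tested by Cox hazard
ratios (quartile mode: Q2–Q4 each against Q1) and the log-rank test.
Signature size can be calibrated against an empirical null built from
uniformly random subnetwork sets of each candidate size, scored by the
absolute log2 HR of their median-dichotomized fitted combined score; the
chosen size maximizes the exceedance quantile of the top-ranked set over
the size-matched null (ties to the smallest size). The size grid and the
draws per size are configuration: a cluster-scale study would use a grid
like 5, 10, …, 250 with 200,000 draws per size, while the desk default is
200 draws on a small grid.

**Multi-modal fusion.** Weights are estimated independently per modality
(e.g. mRNA and copy number); the per-patient risk matrices are summed
element-wise. No rescaling is applied by default — both modalities are
already on the signed log2-HR-weighted z-score scale — but per-modality
z-scaling is available for heterogeneous platforms.

## Database construction

Interactions arrive as tab-delimited `pathway  gene_a  gene_b` triples (a
deliberately neutral format; parsing vendor pathway XML is out of scope)
or as GMT genesets for node-only workflows. Self-loops are dropped (a
self-interaction has no dichotomized-pair interpretation) and duplicate
undirected pairs collapse. Each pathway's connected components become
subnetworks; ids are `<pathway>.<ordinal>` by descending node count with
ties broken by smallest node id, so numbering is input-order stable.

Filtering removes modules with fewer than 3 edges, then walks survivors in
deterministic order (descending node+edge count, ties by id) and removes
the smaller of any pair whose *two-way* overlap of pooled nodes-and-edges
exceeds 80% in **both** directions. One-way containment of a small module
in a large one is not redundancy. Size ties eliminate the
lexicographically larger id. The elimination order when more than two
modules mutually overlap is not dictated by the method itself; the greedy
largest-first order used here was fixed purely for reproducibility, and
the filter is idempotent and input-order invariant under it.

## Numerical choices

- **Cox solver.** Mass fits (one per gene, one per edge, one per null
  draw) run through an internal Newton–Raphson maximizer of the partial
  likelihood, vectorized over risk sets, with step-halving. It matches
  lifelines' `CoxPHFitter` to 1e-6 on coefficients, standard errors and
  log-likelihood (asserted in the test suite) and R's `survival::coxph`
  for both Efron and Breslow ties. lifelines is used directly for
  Kaplan–Meier curves and log-rank tests.
- **Monotone likelihood.** A coefficient walking past |β| = 15 (e.g.
  complete separation of event order by a binary covariate) marks the fit
  non-converged; such results carry Wald P = 1 so downstream filters drop
  them without aborting a genome-wide scan. Constant covariates and
  rank-deficient interaction designs are flagged the same way.
- **Ties and thresholds.** Observations censored at time t remain in the
  risk set for deaths at t. Values exactly at a dichotomization threshold
  fall in the low group, so a median split never puts more than half the
  samples high. Z-scores use the n−1 standard deviation; constant or
  incomplete features are dropped with a warning rather than poisoning a
  matrix.
- **Degenerate validation.** If frozen thresholds put every validation
  sample in one group (e.g. a shifted cohort), the evaluation is flagged
  rather than raised; empty quartiles omit their hazard-ratio contrast.

## The synthetic-data generator

`simulate_cohort` draws standard-normal gene values (equicorrelated with
ρ = 0.3 by default within driver modules — moderate co-expression of a
real pathway module), and injects effects **on the dichotomized scale**:
each driver gene adds its effect to the patient's log2 hazard when its
value is above zero. A per-gene effect of 1.0 is therefore a true
dichotomized hazard ratio of 2 — the same quantity the estimator fits, so
recovery checks need no attenuation bookkeeping between continuous and
binary scales. Event times are exponential with hazard
`h0·exp(predictor·ln 2)` (defaults: h0 = 0.1 per study-time unit against
exponential censoring at rate 0.05, giving a two-thirds event fraction
under the null, typical of a mature survival cohort); a Weibull-like
administrative cutoff can be layered on. With several modalities each
contributes the effect independently, so a per-gene effect of 0.3 in each
of two modalities is a combined 0.6. `simulate_subnetwork_db` builds
random connected modules (spanning tree plus extra edges) over the same
consecutive gene blocks the cohort uses, so module `M001.1` is the first
driver module with no extra bookkeeping; an overlap spec can force shared
genes between modules to exercise the redundancy filter.

What the generator deliberately does **not** emulate: platform artifacts
(probe effects, batch structure), realistic copy-number segment
correlation, non-proportional hazards, and informative censoring. Passing
tests therefore demonstrate correctness of the estimators and the
pipeline's contracts under the stated generative model, not robustness to
those real-data failure modes.

One marginal-effect subtlety is worth stating: in a 10-gene driver module
the *marginal* per-gene hazard ratio is attenuated below the conditional
HR 2 because the other nine drivers act as omitted covariates
(non-collapsibility of the Cox model). Exact HR recovery is therefore
checked with a lone driver gene; multi-gene modules are checked for
direction, ranking and selection instead.

## Open design points resolved here

- "Two-way overlap above 80%" is read as both directional fractions
  strictly > 0.8.
- The MDS significance filter acts per term (it qualifies the summed
  hazard ratios), not as a gate on whole subnetworks.
- The edge weight is β3, the interaction coefficient, not either main
  effect.
- Pooling multiple validation cohorts before evaluation and per-cohort
  evaluation are both supported; the CLI pools by default.
- Stepwise selection uses AIC; the L1 route is the default.

## Problem sizes

The test suite and the reproduction script run simulations at desk scale
chosen to make the Monte-Carlo assertions stable: n = 400–2000 patients,
panels of 20–800 genes, 10–20 seeds per experiment, and 200 random draws
per null size. These sizes are the package's own defaults for
verification runs; every routine accepts larger values.
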
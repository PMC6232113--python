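# simms

Subnetwork-based prognostic biomarkers from pathway interaction data and
censored survival outcomes.

Single-gene survival markers ignore that genes act through pathways.
`simms` fragments a pathway interaction database into *subnetwork
modules* (connected components of each pathway's protein–protein
interaction graph) and treats every module as one candidate biomarker. On
a training cohort it weights each gene by the log2 hazard ratio of its
median-dichotomized abundance (univariate Cox model) and each interaction
by the coefficient of an XNOR co-dysregulation term in a gene-pair Cox
model

    h(t) = h0(t) · exp(β1·X_G1 + β2·X_G2 + β3·XNOR(X_G1, X_G2)),

then summarizes a module's outcome association as the
**module-dysregulation score**

    MDS(k) = Σ_i |log2 HR_i| + Σ_j |log2 HR_j|        (Wald P < 0.05 terms)

under three scoring models — N (nodes only), E (edges only), N+E (both).
A patient's per-module **risk score** uses signed weights against the
patient's z-scored profile, `Σ_i log2(HR_i)·X_ti + Σ_j
log2(HR_j)·X_tjx·X_tjy`; top-ranked modules combine into a multivariate
signature `risk_i = Σ_j β_j·Y_ij` via cross-validated L1-penalized Cox
regression (or AIC stepwise). Median/quartile cut points of the training
risk are frozen into the signature and transferred unchanged to held-out
cohorts, where group separation is tested with Cox hazard ratios and the
log-rank test. Risk matrices from different molecular modalities (mRNA,
copy number, ...) fuse by element-wise summation into multi-modal pathway
activation scores. An empirical null of randomly sampled module sets
calibrates the signature size.

The package is for computational biologists building and validating
pathway-level survival signatures, and ships a synthetic-data generator
with known ground truth so the whole pipeline is testable without any
clinical download.

## Worked example

```python
from simms import (SimulationConfig, DriverModule, simulate_cohort,
                   simulate_subnetwork_db, zscore, estimate_weights, mds,
                   rank_subnetworks, risk_matrix, select_l1,
                   validate_signature)
from simms.preprocess import ExpressionMatrix

# 600 patients, 100 genes, one 10-gene driver module whose genes each
# carry a true dichotomized hazard ratio of 2
cfg = SimulationConfig(n_samples=600, n_genes=100,
                       driver_subnetworks=[DriverModule(10, 1.0)], seed=7)
mats, surv, truth = simulate_cohort(cfg)
expr = zscore(mats[0])
db = simulate_subnetwork_db(10, 10, seed=7)   # module M001.1 = the driver

train, val = expr.sample_ids[:300], expr.sample_ids[300:]
expr_tr = ExpressionMatrix("train", expr.values[train])
expr_va = ExpressionMatrix("val", expr.values[val])

weights = estimate_weights(db, expr_tr, surv.subset(train), model="N")
scores = sorted((mds(w, "N") for w in weights.values()),
                key=lambda s: -s.mds)
for s in scores[:3]:
    print(f"{s.subnetwork_id}  MDS = {s.mds:.2f}")

ranked = rank_subnetworks(list(scores), 5)
risk_tr = risk_matrix(weights, expr_tr, "N", subnetwork_ids=ranked)
risk_va = risk_matrix(weights, expr_va, "N", subnetwork_ids=ranked)
model = select_l1(risk_tr, surv.subset(train), folds=10, seed=7)
print("selected:", {k: round(v, 3) for k, v in model.selected.items()})

res = validate_signature(model, risk_va, surv.subset(val), grouping="median")
print(f"validation HR = {res.cox.hr:.2f} "
      f"(95% CI {res.cox.ci95[0]:.2f}-{res.cox.ci95[1]:.2f}), "
      f"log-rank P = {res.logrank_p:.2e}")
```

Output:

```
M001.1  MDS = 12.51
M004.1  MDS = 0.80
M009.1  MDS = 0.54
selected: {'M001.1': 0.163}
validation HR = 5.08 (95% CI 3.86-6.68), log-rank P = 4.32e-35
```

The driver module dominates the MDS ranking (12.51 vs ≤ 0.80 for null
modules — the score sums |log2 HR| over its significantly prognostic
genes), the L1 step keeps only the driver, and patients above the frozen
training median risk experience events at five times the hazard of those
below it in the held-out half of the cohort.

## Command line

The same pipeline as subcommands, TSV in/TSV out, with provenance headers
(version, parameters, seed, input checksums) on every output:

```bash
simms build-db --interactions pid_edges.tsv --overlap 0.8 --min-edges 3 --out db.tsv
simms train    --db db.tsv --expr expr.tsv --surv surv.tsv --model N --out weights.tsv
simms score    --weights weights.tsv --expr val_expr.tsv --model N --out risk.tsv
simms select   --risk risk.tsv --surv surv.tsv --method l1 --folds 10 --seed 42 --out model
simms evaluate --model model --risk val_risk.tsv --surv val_surv.tsv --grouping quartile
simms fuse     --risk mrna_risk.tsv --risk cna_risk.tsv --out fused.tsv
simms null     --risk risk.tsv --surv surv.tsv --sizes 5,10,15 --reps 200 --seed 42 --out null.tsv
simms simulate --config sim.yaml --out-dir cohort/
```

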
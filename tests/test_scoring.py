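"""Module-dysregulation scores, risk scores, and threshold transfer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simms.pathway_db import SubnetworkDB
from simms.preprocess import ExpressionMatrix, SurvivalTable, zscore
from simms.scoring import (
    ModuleScore,
    SubnetworkWeights,
    estimate_weights,
    evaluate_subnetwork,
    mds,
    patient_risk,
    rank_subnetworks,
    risk_matrix,
)
from simms.synthetic_data import (
    DriverModule,
    SimulationConfig,
    simulate_cohort,
    simulate_subnetwork_db,
)

from .conftest import make_subnetwork, make_survival


def _weights(sid="SN1", nodes=None, edges=None):
    w = SubnetworkWeights(sid)
    w.node_weights = dict(nodes or {})
    w.edge_weights = dict(edges or {})
    return w


LOG2_HR2, LOG2_HR4, LOG2_HR8 = 1.0, 2.0, 3.0


class TestMds:
    def test_node_arithmetic(self):
        # nodes with HR 2 and HR 4, both significant: |1| + |2| = 3
        w = _weights(nodes={"a": (LOG2_HR2, 0.01), "b": (LOG2_HR4, 0.01)})
        assert mds(w, "N").mds == pytest.approx(3.0)

    def test_alpha_filter_excludes_nonsignificant(self):
        w = _weights(nodes={"a": (LOG2_HR2, 0.01), "b": (LOG2_HR4, 0.01),
                            "c": (LOG2_HR8, 0.2)})
        assert mds(w, "N").mds == pytest.approx(3.0)

    def test_ne_adds_edge_terms(self):
        # protective edge HR 0.5 contributes |log2 0.5| = 1
        w = _weights(nodes={"a": (LOG2_HR2, 0.01), "b": (LOG2_HR4, 0.01)},
                     edges={("a", "b"): (-1.0, 0.01)})
        assert mds(w, "NE").mds == pytest.approx(4.0)

    def test_model_restriction(self):
        w = _weights(nodes={"a": (1.0, 0.01)}, edges={("a", "b"): (2.0, 0.01)})
        assert mds(w, "N").mds == pytest.approx(1.0)
        assert mds(w, "E").mds == pytest.approx(2.0)

    def test_empty_qualifying_set_scores_zero(self):
        w = _weights(nodes={"a": (5.0, 0.9)})
        assert mds(w, "NE").mds == 0.0

    @settings(deadline=None, max_examples=200)
    @given(st.lists(
        st.tuples(st.floats(-4, 4), st.floats(0.001, 1.0),
                  st.booleans()),
        min_size=0, max_size=12))
    def test_additivity_over_nodes_and_edges(self, terms):
        """MDS under the combined model is exactly the node-model score
        plus the edge-model score, for any weight configuration."""
        w = SubnetworkWeights("SN1")
        for i, (l2, p, is_node) in enumerate(terms):
            if is_node:
                w.node_weights[f"g{i}"] = (l2, p)
            else:
                w.edge_weights[(f"a{i}", f"b{i}")] = (l2, p)
        assert mds(w, "NE").mds == mds(w, "N").mds + mds(w, "E").mds


class TestRankSubnetworks:
    def test_descending_order(self):
        scores = [ModuleScore("A", "N", 3.0), ModuleScore("B", "N", 5.0),
                  ModuleScore("C", "N", 0.0)]
        assert rank_subnetworks(scores, 2) == ["B", "A"]

    def test_tie_breaks_by_id(self):
        scores = [ModuleScore("B", "N", 2.0), ModuleScore("A", "N", 2.0)]
        assert rank_subnetworks(scores, 1) == ["A"]

    def test_top_zero_empty(self):
        assert rank_subnetworks([ModuleScore("A", "N", 1.0)], 0) == []

    def test_overlong_request_warns_and_returns_all(self):
        with pytest.warns(UserWarning, match="top_n"):
            out = rank_subnetworks([ModuleScore("A", "N", 1.0)], 5)
        assert out == ["A"]

    def test_mixed_models_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            rank_subnetworks([ModuleScore("A", "N", 1.0),
                              ModuleScore("B", "E", 1.0)], 1)


class TestPatientRisk:
    def _expr(self, data, samples=("p1",)):
        return ExpressionMatrix("v", pd.DataFrame(
            data, index=list(data.keys()), columns=list(samples),
            dtype=float) if isinstance(data, dict) else data)

    def test_node_arithmetic_signed(self):
        w = _weights(nodes={"A": (1.0, 0.01), "B": (-1.0, 0.01)})
        expr = ExpressionMatrix("v", pd.DataFrame(
            {"p1": [2.0, 1.0]}, index=["A", "B"]))
        risk = patient_risk(w, expr, model="N")
        assert risk["p1"] == pytest.approx(2 * 1 + 1 * (-1))

    def test_edge_arithmetic_product(self):
        w = _weights(edges={("A", "B"): (0.5, 0.01)})
        expr = ExpressionMatrix("v", pd.DataFrame(
            {"p1": [2.0, 3.0]}, index=["A", "B"]))
        risk = patient_risk(w, expr, model="E")
        assert risk["p1"] == pytest.approx(0.5 * 2 * 3)

    def test_zero_expression_zero_risk(self):
        w = _weights(nodes={"A": (1.5, 0.01)}, edges={("A", "B"): (1.0, 0.01)})
        expr = ExpressionMatrix("v", pd.DataFrame(
            {"p1": [0.0, 0.0]}, index=["A", "B"]))
        assert patient_risk(w, expr, model="NE")["p1"] == 0.0

    def test_linear_in_expression(self):
        rng = np.random.default_rng(0)
        w = _weights(nodes={g: (rng.normal(), 0.01) for g in "ABCD"})
        x1 = pd.DataFrame(rng.normal(size=(4, 3)), index=list("ABCD"),
                          columns=["p1", "p2", "p3"])
        x2 = pd.DataFrame(rng.normal(size=(4, 3)), index=list("ABCD"),
                          columns=["p1", "p2", "p3"])
        a, b = 2.0, -0.7
        lhs = patient_risk(w, ExpressionMatrix("v", a * x1 + b * x2), "N")
        rhs = (a * patient_risk(w, ExpressionMatrix("v", x1), "N")
               + b * patient_risk(w, ExpressionMatrix("v", x2), "N"))
        np.testing.assert_allclose(lhs.values, rhs.values, atol=1e-12)

    def test_p_filter_monotone_inclusion(self):
        rng = np.random.default_rng(1)
        w = _weights(nodes={f"g{i}": (rng.normal(), rng.uniform())
                            for i in range(20)})
        for lo, hi in [(0.05, 0.2), (0.2, 0.5), (0.5, 1.0)]:
            n_lo = sum(p < lo for _, p in w.node_weights.values())
            n_hi = sum(p < hi for _, p in w.node_weights.values())
            assert n_hi >= n_lo

    def test_missing_gene_contributes_zero(self):
        w = _weights(nodes={"A": (1.0, 0.01), "ZZZ": (9.0, 0.01)})
        expr = ExpressionMatrix("v", pd.DataFrame({"p1": [2.0]}, index=["A"]))
        assert patient_risk(w, expr, "N")["p1"] == pytest.approx(2.0)


class TestEstimateWeights:
    @pytest.fixture(scope="class")
    def trained(self):
        cfg = SimulationConfig(n_samples=400, n_genes=40,
                               driver_subnetworks=[DriverModule(10, 1.0)],
                               correlation=0.0, seed=21)
        mats, surv, truth = simulate_cohort(cfg)
        db = simulate_subnetwork_db(4, 10, seed=21)
        expr = zscore(mats[0])
        return db, expr, surv, truth

    def test_model_n_has_no_edge_weights(self, trained):
        db, expr, surv, _ = trained
        weights = estimate_weights(db, expr, surv, model="N")
        assert all(not w.edge_weights for w in weights.values())
        assert all(w.node_weights for w in weights.values())

    def test_model_ne_weights_keys_are_members(self, trained):
        db, expr, surv, _ = trained
        weights = estimate_weights(db, expr, surv, model="NE")
        for sn in db:
            w = weights[sn.subnetwork_id]
            assert set(w.node_weights) <= sn.nodes
            assert set(w.edge_weights) <= sn.edges

    def test_unmeasured_subnetwork_flagged_empty(self, trained):
        db, expr, surv, _ = trained
        ghost = make_subnetwork("GH.1", ["zz1", "zz2", "zz3", "zz4"],
                                [("zz1", "zz2"), ("zz2", "zz3"),
                                 ("zz3", "zz4"), ("zz4", "zz1")])
        db2 = SubnetworkDB(list(db) + [ghost])
        weights = estimate_weights(db2, expr, surv, model="NE")
        assert weights["GH.1"].empty
        assert weights["GH.1"].n_unmeasured == 4

    def test_driver_genes_all_adverse(self, trained):
        """Every driver gene's marginal hazard ratio exceeds 1 (the
        marginal per-gene HR is attenuated below the conditional HR 2 by
        the other nine drivers, so only direction and ordering are exact)."""
        db, expr, surv, truth = trained
        weights = estimate_weights(db, expr, surv, model="N")
        drivers = truth.driver_genes[0]
        hrs = [2 ** weights["M001.1"].node_weights[g][0] for g in drivers]
        assert all(h > 1.2 for h in hrs)

    def test_lone_driver_hr_recovered(self):
        """With a single driver gene (true dichotomized HR 2), the
        univariate estimate at n=1000 lands in [1.6, 2.5]."""
        cfg = SimulationConfig(n_samples=1000, n_genes=20,
                               driver_subnetworks=[DriverModule(1, 1.0)],
                               correlation=0.0, seed=31)
        mats, surv, truth = simulate_cohort(cfg)
        expr = zscore(mats[0])
        db = simulate_subnetwork_db(2, 10, seed=31)
        weights = estimate_weights(db, expr, surv, model="N")
        gene = truth.driver_genes[0][0]
        hr = 2 ** weights["M001.1"].node_weights[gene][0]
        assert 1.6 < hr < 2.5

    def test_medians_frozen_per_gene(self, trained):
        db, expr, surv, _ = trained
        weights = estimate_weights(db, expr, surv, model="N")
        for sn in db:
            w = weights[sn.subnetwork_id]
            for g, med in w.node_medians.items():
                assert med == pytest.approx(float(expr.values.loc[g].median()))


class TestEvaluateSubnetwork:
    def test_threshold_transfer_identity(self):
        rng = np.random.default_rng(5)
        train = pd.Series(rng.normal(size=40),
                          index=[f"s{i}" for i in range(40)])
        surv = make_survival(rng.exponential(1, 40), np.ones(40, int),
                             list(train.index))
        res = evaluate_subnetwork(train, train, surv, grouping="median")
        # validation identical to training: groups are the training split
        expected = (train > train.median()).astype(int)
        pd.testing.assert_series_equal(res.groups, expected,
                                       check_names=False)

    def test_shifted_validation_flagged_degenerate(self):
        train = pd.Series([0.0, 1, 2, 3], index=list("abcd"))
        val = train + 100.0
        surv = make_survival([1, 2, 3, 4], [1, 1, 1, 0], list("abcd"))
        res = evaluate_subnetwork(train, val, surv, grouping="median")
        assert res.flagged is not None
        assert res.cox is None

    def test_quartile_mode_contrasts_against_q1(self):
        rng = np.random.default_rng(6)
        n = 80
        train = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        surv = make_survival(rng.exponential(1, n), np.ones(n, int),
                             list(train.index))
        res = evaluate_subnetwork(train, train, surv, grouping="quartile")
        assert set(res.quartile_cox) == {"Q2", "Q3", "Q4"}
        assert res.groups.value_counts().tolist() == [20, 20, 20, 20]

    def test_true_signal_validates(self):
        """A 10-gene driver module with per-gene log2 HR 1 yields a
        significant high-vs-low validation hazard ratio in 10/10 seeds."""
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_samples=1000, n_genes=20,
                                   driver_subnetworks=[DriverModule(10, 1.0)],
                                   correlation=0.0, seed=100 + seed)
            mats, surv, truth = simulate_cohort(cfg)
            expr = zscore(mats[0])
            db = simulate_subnetwork_db(2, 10, seed=100 + seed)
            train_ids = expr.sample_ids[:500]
            val_ids = expr.sample_ids[500:]
            expr_tr = ExpressionMatrix("tr", expr.values[train_ids])
            expr_va = ExpressionMatrix("va", expr.values[val_ids])
            weights = estimate_weights(db, expr_tr, surv.subset(train_ids),
                                       model="N")
            r_tr = patient_risk(weights["M001.1"], expr_tr, "N")
            r_va = patient_risk(weights["M001.1"], expr_va, "N")
            res = evaluate_subnetwork(r_tr, r_va, surv.subset(val_ids))
            hits += res.cox.hr > 1 and res.cox.wald_p < 0.05
        assert hits == 10


def test_risk_matrix_shape_and_alignment():
    cfg = SimulationConfig(n_samples=100, n_genes=30,
                           driver_subnetworks=[DriverModule(10, 0.5)],
                           seed=9)
    mats, surv, _ = simulate_cohort(cfg)
    expr = zscore(mats[0])
    db = simulate_subnetwork_db(3, 10, seed=9)
    weights = estimate_weights(db, expr, surv, model="N")
    rm = risk_matrix(weights, expr, model="N")
    assert rm.shape == (100, 3)
    assert list(rm.columns) == sorted(w for w in weights)
    assert list(rm.index) == expr.sample_ids
    assert np.isfinite(rm.values).all()
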
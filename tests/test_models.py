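"""Weighted node-model fitting, prediction and sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from seqpaf import (
    CausalGraph,
    FitError,
    FittedNetwork,
    NodeModel,
    NodeSpec,
    WeightedDataset,
    fit_node_models,
    make_case_control_weights,
    predict_category_probs,
    sample_node,
    simulate_population,
)

B = ("0", "1")


class TestCaseControlWeights:
    def test_incidence_weighting(self):
        w = make_case_control_weights(np.array([1, 0, 0]), 0.0035, 0.9965)
        assert np.allclose(w, [0.0035, 0.9965, 0.9965])

    def test_unit_weights_and_all_controls(self):
        assert np.allclose(make_case_control_weights(np.array([1, 0]), 1, 1), [1, 1])
        assert np.allclose(make_case_control_weights(np.zeros(4), 0.1, 0.9), 0.9)

    def test_rejects_non_binary_disease(self):
        with pytest.raises(ValueError):
            make_case_control_weights(np.array([0, 2]), 0.5, 0.5)
        with pytest.raises(ValueError):
            make_case_control_weights(np.array([0, 1]), -0.1, 0.5)


def _binary_parent_graph():
    return CausalGraph(
        nodes=[
            NodeSpec("P", "confounder", "binary", B),
            NodeSpec("X", "risk_factor", "binary", B, "0"),
            NodeSpec("Y", "outcome", "binary", B),
        ],
        parents={"X": ("P",), "Y": ("X",)},
    )


class TestFitNodeModels:
    def test_logistic_recovers_closed_form_logits(self):
        # P(X=1|P=0)=0.2, P(X=1|P=1)=0.8  =>  intercept=logit(.2), coef=logit(.8)-logit(.2)
        rng = np.random.default_rng(5)
        n = 60_000
        p = rng.random(n) < 0.5
        x = rng.random(n) < np.where(p, 0.8, 0.2)
        y = rng.random(n) < 0.1
        df = pd.DataFrame(
            {"P": p.astype(int).astype(str), "X": x.astype(int).astype(str),
             "Y": y.astype(int).astype(str)}
        )
        g = _binary_parent_graph()
        net = fit_node_models(WeightedDataset.from_dataframe(df, g), g)
        m = net.node_models["X"]
        assert m.params[0] == pytest.approx(logit(0.2), abs=0.06)
        assert m.params[1] == pytest.approx(logit(0.8) - logit(0.2), abs=0.09)
        assert m.converged

    def test_root_marginal_matches_weighted_frequencies(self):
        df = pd.DataFrame({"P": ["0", "1", "1"], "X": ["0", "0", "1"], "Y": ["0", "1", "0"]})
        g = _binary_parent_graph()
        ds = WeightedDataset.from_dataframe(df, g, weights=np.array([1.0, 2.0, 1.0]))
        net = fit_node_models(ds, g)
        probs = net.root_marginals["P"].table["prob"].to_numpy()
        assert np.allclose(probs, [0.25, 0.75])
        assert set(net.node_models) == {"X", "Y"}  # exactly the non-root nodes

    def test_proportional_odds_recovers_known_shift(self, po_sim=None):
        lv3 = ("a", "b", "c")
        g = CausalGraph(
            nodes=[
                NodeSpec("P", "confounder", "binary", B),
                NodeSpec("X", "risk_factor", "ordinal", lv3, "a"),
                NodeSpec("Y", "outcome", "binary", B),
            ],
            parents={"X": ("P",), "Y": ("X",)},
        )
        true = NodeModel.proportional_odds("X", lv3, ("P",), {"P": B}, (-0.5, 1.0), {("P", "1"): 1.0})
        net_true = FittedNetwork(
            graph=g,
            node_models={
                "X": true,
                "Y": NodeModel.logistic("Y", B, ("X",), {"X": lv3}, -1.0, {("X", "c"): 0.5}),
            },
            root_marginals={"P": NodeModel.marginal("P", B, (0.5, 0.5))},
        )
        data = simulate_population(net_true, n=50_000, seed=7)
        fit = fit_node_models(data, g)
        m = fit.node_models["X"]
        # parameter recovery within 3 asymptotic SEs
        for est, truth, se in zip(m.params, [-0.5, 1.0, 1.0], m.bse):
            assert abs(est - truth) < 3 * se

    def test_weighted_fit_matches_statsmodels_ordinal_at_unit_weights(self):
        pytest.importorskip("statsmodels")
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        lv3 = ("a", "b", "c")
        g = CausalGraph(
            nodes=[
                NodeSpec("P", "confounder", "binary", B),
                NodeSpec("X", "risk_factor", "ordinal", lv3, "a"),
                NodeSpec("Y", "outcome", "binary", B),
            ],
            parents={"X": ("P",), "Y": ("X",)},
        )
        rng = np.random.default_rng(3)
        n = 5000
        p = (rng.random(n) < 0.5).astype(int)
        eta = 0.8 * p
        u = rng.random(n)
        c1, c2 = expit(-0.3 - eta), expit(0.9 - eta)
        x = np.where(u < c1, "a", np.where(u < c2, "b", "c"))
        y = (rng.random(n) < 0.2).astype(int)
        df = pd.DataFrame({"P": p.astype(str), "X": x, "Y": y.astype(str)})
        ds = WeightedDataset.from_dataframe(df, g)
        mine = fit_node_models(ds, g).node_models["X"]
        ref = OrderedModel(
            pd.Series(pd.Categorical(df["X"], categories=list(lv3), ordered=True)),
            p[:, None].astype(float),
            distr="logit",
        ).fit(method="bfgs", disp=False)
        beta_ref = ref.params[0]
        cut1_ref = ref.params[1]
        cut2_ref = cut1_ref + np.exp(ref.params[2])
        assert mine.params[2] == pytest.approx(beta_ref, abs=1e-3)
        assert mine.params[0] == pytest.approx(cut1_ref, abs=1e-3)
        assert mine.params[1] == pytest.approx(cut2_ref, abs=1e-3)

    def test_weight_scale_invariance(self):
        g = _binary_parent_graph()
        rng = np.random.default_rng(9)
        n = 2000
        df = pd.DataFrame(
            {
                "P": rng.integers(0, 2, n).astype(str),
                "X": rng.integers(0, 2, n).astype(str),
                "Y": rng.integers(0, 2, n).astype(str),
            }
        )
        w = rng.random(n) + 0.5
        f1 = fit_node_models(WeightedDataset.from_dataframe(df, g, w), g)
        f2 = fit_node_models(WeightedDataset.from_dataframe(df, g, 7.3 * w), g)
        for node in f1.node_models:
            assert np.allclose(
                f1.node_models[node].params, f2.node_models[node].params, atol=1e-6
            )

    def test_empty_cell_reported_with_node_name(self):
        g = _binary_parent_graph()
        df = pd.DataFrame({"P": ["0"] * 50, "X": ["0", "1"] * 25, "Y": ["0", "1"] * 25})
        with pytest.raises(FitError, match="empty category cells"):
            fit_node_models(WeightedDataset.from_dataframe(df, g), g)

    def test_separation_is_an_error(self):
        g = _binary_parent_graph()
        n = 200
        p = np.tile(["0", "1"], n // 2)
        x = p  # X == P deterministic -> separation
        df = pd.DataFrame({"P": p, "X": x, "Y": np.tile(["0", "1"], n // 2)})
        with pytest.raises(FitError, match="X"):
            fit_node_models(WeightedDataset.from_dataframe(df, g), g)


class TestPrediction:
    def test_null_logistic_is_fifty_fifty(self):
        m = NodeModel.logistic("X", B, ("P",), {"P": B}, 0.0, {})
        assert np.allclose(predict_category_probs(m, {"P": "1"}), [0.5, 0.5])

    def test_marginal_table_ignores_parents(self):
        m = NodeModel.marginal("X", B, (0.3, 0.7))
        assert np.allclose(predict_category_probs(m, {}), [0.3, 0.7])

    def test_proportional_odds_closed_form(self):
        m = NodeModel.proportional_odds(
            "X", ("a", "b", "c"), ("P",), {"P": B}, (-1.0, 1.0), {}
        )
        probs = predict_category_probs(m, {"P": "0"})
        e1, e2 = expit(-1.0), expit(1.0)
        assert np.allclose(probs, [e1, e2 - e1, 1 - e2], atol=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_level_and_missing_parent_raise(self):
        m = NodeModel.logistic("X", B, ("P",), {"P": B}, 0.0, {})
        with pytest.raises(ValueError):
            predict_category_probs(m, {"P": "banana"})
        with pytest.raises(KeyError):
            predict_category_probs(m, {})

    def test_probabilities_sum_to_one_for_all_parent_configs(self):
        m = NodeModel.proportional_odds(
            "X", ("a", "b", "c"), ("P", "Q"), {"P": B, "Q": ("u", "v", "w")},
            (-0.5, 0.7), {("P", "1"): 1.3, ("Q", "w"): -0.8},
        )
        for p in B:
            for q in ("u", "v", "w"):
                assert predict_category_probs(m, {"P": p, "Q": q}).sum() == pytest.approx(1.0)


class TestSampling:
    def test_degenerate_model_always_draws_reference(self):
        m = NodeModel.marginal("X", B, (1.0, 0.0))
        rng = np.random.default_rng(0)
        assert all(sample_node(m, {}, rng) == "0" for _ in range(20))

    def test_fair_binary_frequency_within_binomial_bound(self):
        m = NodeModel.logistic("X", B, (), {}, 0.0, {})
        rng = np.random.default_rng(42)
        n = 10_000
        draws = sum(sample_node(m, {}, rng) == "1" for _ in range(n))
        se = 0.5 / np.sqrt(n)
        assert abs(draws / n - 0.5) < 4 * se

    def test_sampling_is_deterministic_under_seeding(self):
        m = NodeModel.marginal("X", ("a", "b", "c"), (0.2, 0.3, 0.5))
        seq1 = [sample_node(m, {}, np.random.default_rng(7)) for _ in range(5)]
        seq2 = [sample_node(m, {}, np.random.default_rng(7)) for _ in range(5)]
        assert seq1 == seq2


def test_model_json_round_trip():
    m = NodeModel.proportional_odds(
        "X", ("a", "b", "c"), ("P",), {"P": B}, (-0.5, 0.7), {("P", "1"): 1.3}
    )
    m2 = NodeModel.from_dict(m.to_dict())
    assert np.allclose(m.params, m2.params)
    assert m2.levels == m.levels and m2.coef_names == m.coef_names
    df = pd.DataFrame({"P": ["0", "1"]})
    assert np.allclose(m.predict_probs(df), m2.predict_probs(df))


def test_network_json_round_trip(tmp_path, chain_net):
    path = tmp_path / "net.json"
    chain_net.save(path)
    net2 = FittedNetwork.load(path)
    assert set(net2.node_models) == set(chain_net.node_models)
    df = pd.DataFrame({"C": ["0", "1"], "A": ["1", "0"]})
    assert np.allclose(
        net2.node_models["Y"].predict_probs(df), chain_net.node_models["Y"].predict_probs(df)
    )
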
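"""PAF / SAF / joint PAF estimators and their algebraic identities."""

import numpy as np
import pandas as pd
import pytest

from seqpaf import (
    OUTCOME_EXPECTED,
    CounterfactualDataset,
    ExactEngine,
    WeightedDataset,
    do_intervene,
    estimate_joint_paf,
    estimate_paf,
    estimate_saf,
    results_to_frame,
    sequential_path,
    simulate_population,
)


def _stub_datasets(y_obs, y_prev, y_next, weights=None):
    """Hand-built nested counterfactual datasets over a 1-risk-factor frame."""
    n = len(y_obs)
    w = np.ones(n) if weights is None else np.asarray(weights, float)

    def mk(y, intervened):
        df = pd.DataFrame(
            {
                "A": pd.Categorical(["0"] * n, categories=["0", "1"]),
                "Y": pd.Categorical([str(v) for v in y], categories=["0", "1"]),
            }
        )
        return CounterfactualDataset(df=df, weights=w, intervened=frozenset(intervened))

    return mk(y_obs, []), mk(y_prev, ["B"]), mk(y_next, ["B", "A"])


def _stub_network():
    from conftest import mediation_net

    return mediation_net(0.5)  # any net with outcome "Y" levels ("0","1")


class TestEstimateSAF:
    def test_identical_counterfactuals_give_zero(self):
        obs, prev, nxt = _stub_datasets([1, 1, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0])
        res = estimate_saf(_stub_network(), prev, nxt, obs)
        assert res.estimate == 0.0

    def test_direct_arithmetic(self):
        # observed sum 50, D_S sum 30, D_{S+j} sum 18 -> (30-18)/50
        y_obs = [1] * 50 + [0] * 50
        y_prev = [1] * 30 + [0] * 70
        y_next = [1] * 18 + [0] * 82
        obs, prev, nxt = _stub_datasets(y_obs, y_prev, y_next)
        res = estimate_saf(_stub_network(), prev, nxt, obs)
        assert res.estimate == pytest.approx(0.24)
        assert res.risk_factor == "A" and res.prior_set == {"B"}

    def test_full_elimination_of_remaining_cases(self):
        y_obs = [1] * 20 + [0] * 20
        y_prev = [1] * 10 + [0] * 30
        obs, prev, nxt = _stub_datasets(y_obs, y_prev, [0] * 40)
        res = estimate_saf(_stub_network(), prev, nxt, obs)
        assert res.estimate == pytest.approx(10 / 20)

    def test_zero_prevalence_denominator_raises(self):
        obs, prev, nxt = _stub_datasets([0, 0], [0, 0], [0, 0])
        with pytest.raises(ZeroDivisionError):
            estimate_saf(_stub_network(), prev, nxt, obs)

    def test_mismatched_sets_raise(self):
        obs, prev, nxt = _stub_datasets([1, 0], [1, 0], [0, 0])
        with pytest.raises(ValueError, match="exactly one"):
            estimate_saf(_stub_network(), nxt, prev, obs)

    def test_monotone_data_gives_nonnegative_saf(self):
        y_obs = [1] * 10 + [0] * 10
        y_prev = [1] * 8 + [0] * 12
        y_next = [1] * 5 + [0] * 15  # componentwise <= prev
        obs, prev, nxt = _stub_datasets(y_obs, y_prev, y_next)
        assert estimate_saf(_stub_network(), prev, nxt, obs).estimate >= 0


class TestPAF:
    def test_matches_oracle_on_chain(self, chain_net):
        data = simulate_population(chain_net, 100_000, 21)
        res = estimate_paf(chain_net, data, "A", rng=1, outcome_mode=OUTCOME_EXPECTED,
                           n_batches=20)
        exact = ExactEngine(chain_net, data=data).paf("A")
        assert abs(res.estimate - exact) < 3 * res.mc_se

    def test_null_effect_gives_paf_near_zero(self, chain_net):
        # clone the network but zero A's effect on Y
        import copy

        net = copy.deepcopy(chain_net)
        net.node_models["Y"].params[2] = 0.0  # A[1] coefficient
        data = simulate_population(net, 50_000, 22)
        res = estimate_paf(net, data, "A", rng=2, outcome_mode=OUTCOME_EXPECTED, n_batches=20)
        assert abs(res.estimate) < 3 * res.mc_se + 1e-3

    def test_population_already_at_reference_gives_exact_zero(self, chain_net):
        # A has no descendants besides Y, expected-outcome mode -> exactly 0
        data = simulate_population(chain_net, 5000, 23)
        df = data.df.copy()
        df["A"] = pd.Categorical(["0"] * len(df), categories=["0", "1"])
        # Y must be consistent with its conditional expectation given A=0 for
        # exact zero; use the expected-outcome column as the observed outcome
        probs = chain_net.node_models["Y"].predict_probs(df)[:, 1]
        df["Y"] = probs
        ds = WeightedDataset.__new__(WeightedDataset)
        ds.df, ds.weights = df, data.weights
        res = estimate_paf(chain_net, ds, "A", rng=3, outcome_mode=OUTCOME_EXPECTED)
        assert res.estimate == pytest.approx(0.0, abs=1e-14)


class TestSequentialPath:
    def test_length_one_reproduces_paf_exactly(self, net3rf):
        data = simulate_population(net3rf, 20_000, 31)
        a = estimate_paf(net3rf, data, "B", rng=123)
        b = sequential_path(net3rf, data, ["B"], rng=123)[0]
        assert a.estimate == b.estimate  # identical rng substream contract

    def test_telescoping_to_joint_paf_is_exact_per_path(self, net3rf):
        data = simulate_population(net3rf, 20_000, 32)
        order = ["B", "A", "D"]
        results = sequential_path(
            net3rf, data, order, rng=5, outcome_mode=OUTCOME_EXPECTED, keep_datasets=True
        )
        total = sum(r.estimate for r in results)
        final = results[-1].meta["dataset"]
        w, y = data.weights, data.outcome_indicator(net3rf.graph)
        from seqpaf.models import outcome_values

        y_final = outcome_values(final.df["Y"], ("0", "1"))
        direct = (np.sum(w * y) - np.sum(w * y_final)) / np.sum(w * y)
        assert total == pytest.approx(direct, abs=1e-12)

    def test_duplicate_order_rejected(self, net3rf):
        data = simulate_population(net3rf, 100, 33)
        with pytest.raises(ValueError, match="duplicates"):
            sequential_path(net3rf, data, ["A", "A"], rng=1)

    def test_mediated_first_position_saf_differs_from_direct_only(self, net3rf):
        """With an A -> B edge, SAF_A at position 1 under the full network differs
        from the direct-effects-only PAF_A; the signed difference matches the
        oracle difference."""
        from seqpaf import project_direct_effects, root_table_from_data

        data = simulate_population(net3rf, 60_000, 34)
        root = root_table_from_data(data, net3rf.graph)
        proj = project_direct_effects(net3rf, root)
        full = estimate_paf(net3rf, data, "A", rng=6, outcome_mode=OUTCOME_EXPECTED,
                            n_batches=20)
        direct = estimate_paf(proj, data, "A", rng=7, outcome_mode=OUTCOME_EXPECTED,
                              n_batches=20)
        ex_full = ExactEngine(net3rf, data=data).paf("A")
        ex_direct = ExactEngine(proj, data=data).paf("A")
        assert ex_full - ex_direct > 0.005  # mediation raises the full-network PAF
        diff = full.estimate - direct.estimate
        se = np.hypot(full.mc_se, direct.mc_se)
        assert abs(diff - (ex_full - ex_direct)) < 3 * se


class TestJointPAF:
    def test_singleton_matches_paf_in_distribution(self, net3rf):
        data = simulate_population(net3rf, 50_000, 41)
        j = estimate_joint_paf(net3rf, data, ["A"], rng=8, outcome_mode=OUTCOME_EXPECTED,
                               n_batches=20)
        p = estimate_paf(net3rf, data, "A", rng=9, outcome_mode=OUTCOME_EXPECTED,
                         n_batches=20)
        assert abs(j.estimate - p.estimate) < 3 * np.hypot(j.mc_se, p.mc_se)

    def test_full_set_approaches_one_when_reference_risk_is_zero(self):
        """If risk factors are the only parents of Y and P(Y=1 | all at ref) = 0,
        eliminating everything removes essentially all cases."""
        from seqpaf import CausalGraph, FittedNetwork, NodeModel, NodeSpec

        B = ("0", "1")
        g = CausalGraph(
            nodes=[
                NodeSpec("A", "risk_factor", "binary", B, "0"),
                NodeSpec("B", "risk_factor", "binary", B, "0"),
                NodeSpec("Y", "outcome", "binary", B),
            ],
            parents={"Y": ("A", "B")},
        )
        net = FittedNetwork(
            graph=g,
            node_models={
                "Y": NodeModel.logistic("Y", B, ("A", "B"), {"A": B, "B": B}, -25.0,
                                        {("A", "1"): 24.0, ("B", "1"): 24.0})
            },
            root_marginals={
                "A": NodeModel.marginal("A", B, (0.5, 0.5)),
                "B": NodeModel.marginal("B", B, (0.5, 0.5)),
            },
        )
        data = simulate_population(net, 50_000, 42)
        res = estimate_joint_paf(net, data, ["A", "B"], rng=10, outcome_mode=OUTCOME_EXPECTED)
        assert res.estimate > 0.999

    def test_sum_over_every_order_equals_joint_exact_oracle(self, net3rf):
        import itertools

        data = simulate_population(net3rf, 10_000, 43)
        eng = ExactEngine(net3rf, data=data)
        rfs = net3rf.graph.risk_factors
        joint = eng.joint_paf(rfs)
        for order in itertools.permutations(rfs):
            assert sum(eng.sequential_path(order)) == pytest.approx(joint, abs=1e-10)


class TestScaleInvariance:
    def test_weights_scaled_by_constant_leave_afs_unchanged(self, net3rf):
        data = simulate_population(net3rf, 10_000, 51)
        scaled = WeightedDataset(data.df, data.weights * 13.7)
        a = sequential_path(net3rf, data, ["A", "B"], rng=11, outcome_mode=OUTCOME_EXPECTED)
        b = sequential_path(net3rf, scaled, ["A", "B"], rng=11, outcome_mode=OUTCOME_EXPECTED)
        for ra, rb in zip(a, b):
            assert ra.estimate == pytest.approx(rb.estimate, abs=1e-12)


def test_results_frame_layout(net3rf):
    data = simulate_population(net3rf, 2_000, 61)
    results = sequential_path(net3rf, data, ["A", "B"], rng=12)
    frame = results_to_frame(results)
    assert list(frame["kind"]) == ["PAF", "SAF"]
    assert list(frame["position"]) == [1, 2]
    assert frame.loc[1, "prior_set"] == "A"
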
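"""Shared toy networks with known parameters.

All fixtures return *generating* networks (declared coefficients, not
fits), so exact oracle values exist for every attributable fraction.
"""

from __future__ import annotations

import numpy as np
import pytest

from seqpaf import (
    CausalGraph,
    FittedNetwork,
    NodeModel,
    NodeSpec,
    WeightedDataset,
    simulate_population,
)

B = ("0", "1")


def _logistic(name, parents, parent_levels, intercept, coefs, levels=B):
    return NodeModel.logistic(name, levels, parents, parent_levels, intercept, coefs)


@pytest.fixture
def chain_net() -> FittedNetwork:
    """C -> A -> Y with C -> Y; one confounder, one risk factor."""
    g = CausalGraph(
        nodes=[
            NodeSpec("C", "confounder", "binary", B),
            NodeSpec("A", "risk_factor", "binary", B, "0"),
            NodeSpec("Y", "outcome", "binary", B),
        ],
        parents={"A": ("C",), "Y": ("C", "A")},
    )
    pl = {"C": B, "A": B}
    return FittedNetwork(
        graph=g,
        node_models={
            "A": _logistic("A", ("C",), pl, -1.0, {("C", "1"): 1.2}),
            "Y": _logistic("Y", ("C", "A"), pl, -2.2, {("C", "1"): 0.5, ("A", "1"): 1.1}),
        },
        root_marginals={"C": NodeModel.marginal("C", B, (0.6, 0.4))},
    )


@pytest.fixture
def net5() -> FittedNetwork:
    """Five nodes, three risk factors, mixed binary/ordinal; 36 pre-outcome configs."""
    lv3 = ("low", "mid", "high")
    g = CausalGraph(
        nodes=[
            NodeSpec("C", "confounder", "ordinal", lv3),
            NodeSpec("A1", "risk_factor", "binary", B, "0"),
            NodeSpec("A2", "risk_factor", "ordinal", lv3, "low"),
            NodeSpec("M", "risk_factor", "binary", B, "0"),
            NodeSpec("Y", "outcome", "binary", B),
        ],
        parents={
            "A1": ("C",),
            "A2": ("C", "A1"),
            "M": ("C", "A1", "A2"),
            "Y": ("C", "A1", "A2", "M"),
        },
    )
    pl = {"C": lv3, "A1": B, "A2": lv3, "M": B}
    return FittedNetwork(
        graph=g,
        node_models={
            "A1": _logistic("A1", ("C",), pl, -0.8, {("C", "mid"): 0.5, ("C", "high"): 0.9}),
            "A2": NodeModel.proportional_odds(
                "A2", lv3, ("C", "A1"), pl, (-0.4, 1.0),
                {("C", "mid"): 0.3, ("C", "high"): 0.6, ("A1", "1"): 0.8},
            ),
            "M": _logistic(
                "M", ("C", "A1", "A2"), pl, -1.5,
                {("C", "high"): 0.3, ("A1", "1"): 0.4, ("A2", "mid"): 0.5, ("A2", "high"): 0.9},
            ),
            "Y": _logistic(
                "Y", ("C", "A1", "A2", "M"), pl, -2.5,
                {
                    ("C", "mid"): 0.2, ("C", "high"): 0.4,
                    ("A1", "1"): 0.7, ("A2", "mid"): 0.4, ("A2", "high"): 0.9,
                    ("M", "1"): 0.8,
                },
            ),
        },
        root_marginals={"C": NodeModel.marginal("C", lv3, (0.5, 0.3, 0.2))},
    )


@pytest.fixture
def net3rf() -> FittedNetwork:
    """Three risk factors with the mediation chain A -> B -> D, all affecting Y."""
    g = CausalGraph(
        nodes=[
            NodeSpec("C", "confounder", "binary", B),
            NodeSpec("A", "risk_factor", "binary", B, "0"),
            NodeSpec("B", "risk_factor", "binary", B, "0"),
            NodeSpec("D", "risk_factor", "binary", B, "0"),
            NodeSpec("Y", "outcome", "binary", B),
        ],
        parents={
            "A": ("C",),
            "B": ("C", "A"),
            "D": ("C", "B"),
            "Y": ("C", "A", "B", "D"),
        },
    )
    pl = {"C": B, "A": B, "B": B, "D": B}
    return FittedNetwork(
        graph=g,
        node_models={
            "A": _logistic("A", ("C",), pl, -0.9, {("C", "1"): 0.6}),
            "B": _logistic("B", ("C", "A"), pl, -1.1, {("C", "1"): 0.4, ("A", "1"): 0.9}),
            "D": _logistic("D", ("C", "B"), pl, -1.4, {("C", "1"): 0.3, ("B", "1"): 0.7}),
            "Y": _logistic(
                "Y", ("C", "A", "B", "D"), pl, -2.3,
                {("C", "1"): 0.4, ("A", "1"): 0.6, ("B", "1"): 0.8, ("D", "1"): 0.5},
            ),
        },
        root_marginals={"C": NodeModel.marginal("C", B, (0.55, 0.45))},
    )


def mediation_net(delta: float) -> FittedNetwork:
    """C; A -> B with strength ``delta``; both raise Y.  delta=0 removes mediation."""
    g = CausalGraph(
        nodes=[
            NodeSpec("C", "confounder", "binary", B),
            NodeSpec("A", "risk_factor", "binary", B, "0"),
            NodeSpec("B", "risk_factor", "binary", B, "0"),
            NodeSpec("Y", "outcome", "binary", B),
        ],
        parents={"A": ("C",), "B": ("C", "A"), "Y": ("C", "A", "B")},
    )
    pl = {"C": B, "A": B, "B": B}
    return FittedNetwork(
        graph=g,
        node_models={
            "A": _logistic("A", ("C",), pl, -0.7, {("C", "1"): 0.5}),
            "B": _logistic("B", ("C", "A"), pl, -1.0, {("C", "1"): 0.4, ("A", "1"): delta}),
            "Y": _logistic(
                "Y", ("C", "A", "B"), pl, -2.0,
                {("C", "1"): 0.3, ("A", "1"): 0.7, ("B", "1"): 0.9},
            ),
        },
        root_marginals={"C": NodeModel.marginal("C", B, (0.5, 0.5))},
    )


def simulate(net: FittedNetwork, n: int, seed: int) -> WeightedDataset:
    return simulate_population(net, n=n, seed=seed)


@pytest.fixture
def chain_data(chain_net) -> WeightedDataset:
    return simulate(chain_net, 20_000, 11)
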
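"""Sequential attributable fractions depend on the elimination order.

On a network with the mediation chain A -> B -> D (all three risk factors
also act directly on disease Y), eliminating A first removes part of B's
and D's burden too, so their increments shrink when they come later.  The
sum of the increments, however, is the joint PAF of the whole set — the
same for every order.
"""

import itertools

from seqpaf import (
    OUTCOME_EXPECTED,
    CausalGraph,
    ExactEngine,
    FittedNetwork,
    NodeModel,
    NodeSpec,
    sequential_path,
    simulate_population,
)

B = ("0", "1")
g = CausalGraph(
    nodes=[
        NodeSpec("C", "confounder", "binary", B),
        NodeSpec("A", "risk_factor", "binary", B, "0"),
        NodeSpec("B", "risk_factor", "binary", B, "0"),
        NodeSpec("D", "risk_factor", "binary", B, "0"),
        NodeSpec("Y", "outcome", "binary", B),
    ],
    parents={"A": ("C",), "B": ("C", "A"), "D": ("C", "B"), "Y": ("C", "A", "B", "D")},
)
pl = {k: B for k in ("C", "A", "B", "D")}
net = FittedNetwork(
    graph=g,
    node_models={
        "A": NodeModel.logistic("A", B, ("C",), pl, -0.9, {("C", "1"): 0.6}),
        "B": NodeModel.logistic("B", B, ("C", "A"), pl, -1.1, {("C", "1"): 0.4, ("A", "1"): 0.9}),
        "D": NodeModel.logistic("D", B, ("C", "B"), pl, -1.4, {("C", "1"): 0.3, ("B", "1"): 0.7}),
        "Y": NodeModel.logistic("Y", B, ("C", "A", "B", "D"), pl, -2.3,
                                {("C", "1"): 0.4, ("A", "1"): 0.6, ("B", "1"): 0.8, ("D", "1"): 0.5}),
    },
    root_marginals={"C": NodeModel.marginal("C", B, (0.55, 0.45))},
)

data = simulate_population(net, n=40_000, seed=3)

for order in (["A", "B", "D"], ["D", "B", "A"]):
    results = sequential_path(net, data, order, rng=4, outcome_mode=OUTCOME_EXPECTED)
    parts = ", ".join(f"SAF[{r.risk_factor}|{sorted(r.prior_set)}]={r.estimate:.4f}"
                      for r in results)
    print(f"order {order}: {parts}")
    print(f"  sum of increments = {sum(r.estimate for r in results):.4f}")

eng = ExactEngine(net, data=data)
joint = eng.joint_paf(["A", "B", "D"])
print(f"\nexact joint PAF of {{A, B, D}} = {joint:.4f}")
devs = [abs(sum(eng.sequential_path(o)) - joint)
        for o in itertools.permutations(["A", "B", "D"])]
print(f"max |SAF-sum - joint PAF| over all 6 orders (oracle): {max(devs):.2e}")
print("\nIndividual increments move with the order; their sum is invariant.")
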
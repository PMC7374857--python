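"""Why ignoring risk-factor interrelationships biases sequential AFs.

Single-regression approaches implicitly use a graph in which risk factors
have no causal effects on each other ("direct effects only").  When risk
factor A raises a downstream risk factor M that itself raises disease,
eliminating A also lowers M — an indirect benefit the direct-effects-only
model misses.  This example quantifies the gap and shows it vanishes when
the A -> M link is cut.
"""

from seqpaf import (
    OUTCOME_EXPECTED,
    CausalGraph,
    ExactEngine,
    FittedNetwork,
    NodeModel,
    NodeSpec,
    estimate_paf,
    project_direct_effects,
    root_table_from_data,
    simulate_population,
)

B = ("0", "1")


def build(delta: float) -> FittedNetwork:
    g = CausalGraph(
        nodes=[
            NodeSpec("C", "confounder", "binary", B),
            NodeSpec("A", "risk_factor", "binary", B, "0"),
            NodeSpec("M", "risk_factor", "binary", B, "0"),
            NodeSpec("Y", "outcome", "binary", B),
        ],
        parents={"A": ("C",), "M": ("C", "A"), "Y": ("C", "A", "M")},
    )
    pl = {"C": B, "A": B, "M": B}
    return FittedNetwork(
        graph=g,
        node_models={
            "A": NodeModel.logistic("A", B, ("C",), pl, -0.7, {("C", "1"): 0.5}),
            "M": NodeModel.logistic("M", B, ("C", "A"), pl, -1.0,
                                    {("C", "1"): 0.4, ("A", "1"): delta}),
            "Y": NodeModel.logistic("Y", B, ("C", "A", "M"), pl, -2.0,
                                    {("C", "1"): 0.3, ("A", "1"): 0.7, ("M", "1"): 0.9}),
        },
        root_marginals={"C": NodeModel.marginal("C", B, (0.5, 0.5))},
    )


for delta in (0.9, 0.0):
    net = build(delta)
    data = simulate_population(net, n=50_000, seed=8)
    proj = project_direct_effects(net, root_table_from_data(data, net.graph))
    full = estimate_paf(net, data, "A", rng=9, outcome_mode=OUTCOME_EXPECTED, n_batches=20)
    direct = estimate_paf(proj, data, "A", rng=10, outcome_mode=OUTCOME_EXPECTED, n_batches=20)
    ex = ExactEngine(net, data=data).paf("A") - ExactEngine(proj, data=data).paf("A")
    print(f"A -> M strength delta = {delta}")
    print(f"  PAF[A], full network      : {full.estimate:.4f}")
    print(f"  PAF[A], direct-only graph : {direct.estimate:.4f}")
    print(f"  gap (estimate / oracle)   : {full.estimate - direct.estimate:.4f} / {ex:.4f}\n")

print("With mediation (delta = 0.9) the full network credits A with the")
print("burden it removes through M; with delta = 0 the two graphs agree.")
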
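"""Exact computation on small discrete networks by brute-force enumeration.

This module is the ground truth against which every stochastic estimator in
the package is checked.  It evaluates the truncated factorization of a
causal Bayesian network directly: the joint distribution is built by
expanding node levels in topological order and multiplying conditional
probabilities; an intervention ``do(A_S = ref_S)`` replaces the factors of
S by point masses at the reference levels.

Two engines are provided.

* **population** — roots follow a supplied root-configuration table (the
  weighted empirical root distribution, or the product of a network's
  declared root marginals).  This gives the population-level truth of a
  known generating network.
* **empirical** — exact *conditional* expectations given an observed
  dataset: for each row, only the descendants of the intervened set are
  integrated out, with every non-descendant column held at its observed
  value and the do(∅) prevalence defined as the observed weighted
  prevalence.  This is precisely the conditional expectation of the
  simulation estimator in expected-outcome mode, so "estimate within k
  Monte-Carlo standard errors of the oracle" is a calibrated check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import CausalGraph
from .intervene import CounterfactualDataset
from .models import FittedNetwork, NodeModel, WeightedDataset, outcome_values

DEFAULT_CONFIG_CAP = 10**7


class StateSpaceError(RuntimeError):
    """The enumeration would exceed the configured configuration cap."""


@dataclass
class JointTable:
    """All configurations of a set of nodes with their probabilities."""

    df: pd.DataFrame  # node columns (str) + "prob"

    def __post_init__(self) -> None:
        total = float(self.df["prob"].sum())
        if not np.isclose(total, 1.0, atol=1e-10):
            raise ValueError(f"joint table probabilities sum to {total}, not 1")
        if (self.df["prob"] < -1e-15).any():
            raise ValueError("negative probability in joint table")

    @property
    def nodes(self) -> list[str]:
        return [c for c in self.df.columns if c != "prob"]

    def marginal(self, nodes: Sequence[str]) -> pd.DataFrame:
        out = (
            self.df.groupby(list(nodes), observed=True, sort=False)["prob"]
            .sum()
            .reset_index()
        )
        return out

    def prob_of(self, **assignment: str) -> float:
        mask = np.ones(len(self.df), bool)
        for k, v in assignment.items():
            mask &= self.df[k].astype(str).to_numpy() == str(v)
        return float(self.df.loc[mask, "prob"].sum())


# ---------------------------------------------------------------------------
# root tables
# ---------------------------------------------------------------------------


def root_table_from_data(data: WeightedDataset | CounterfactualDataset, graph: CausalGraph) -> pd.DataFrame:
    """Weighted empirical distribution of the root-node configurations."""
    roots = graph.root_nodes
    if not roots:
        return pd.DataFrame({"prob": [1.0]})
    df = pd.DataFrame({r: data.df[r].astype(str) for r in roots})
    df["prob"] = data.weights
    out = df.groupby(roots, observed=True, sort=True)["prob"].sum().reset_index()
    out["prob"] = out["prob"] / out["prob"].sum()
    return out


def root_table_from_network(network: FittedNetwork) -> pd.DataFrame:
    """Product of the network's declared root marginal tables (independent roots)."""
    table = pd.DataFrame({"prob": [1.0]})
    for r in network.graph.root_nodes:
        m = network.root_marginals[r]
        probs = m.table["prob"].to_numpy()
        levels = [str(x) for x in m.table["level"]]
        k = len(levels)
        table = table.loc[table.index.repeat(k)].reset_index(drop=True)
        reps = len(table) // k
        table[r] = np.tile(levels, reps)
        table["prob"] = table["prob"].to_numpy() * np.tile(probs, reps)
    return table


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _expand_node(
    table: pd.DataFrame, node: str, model: NodeModel, cap: int
) -> pd.DataFrame:
    levels = list(model.levels)
    k = len(levels)
    n = len(table)
    if n * k > cap:
        raise StateSpaceError(
            f"enumeration exceeds the configuration cap ({n * k} > {cap})"
        )
    probs = model.predict_probs(table)
    out = table.loc[table.index.repeat(k)].reset_index(drop=True)
    out[node] = np.tile(levels, n)
    out["prob"] = np.repeat(table["prob"].to_numpy(), k) * probs.ravel()
    return out


def _enumerate(
    network: FittedNetwork,
    root_table: pd.DataFrame,
    S: frozenset[str],
    include_outcome: bool,
    cap: int,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Expand the truncated factorization; S fixed at reference.

    Returns the table of pre-outcome configurations and, when
    ``include_outcome`` is false, the outcome probabilities per row.
    """
    graph = network.graph
    outcome = graph.outcome
    bad = S - set(graph.risk_factors)
    if bad:
        raise ValueError(f"intervention set contains non-risk-factors {sorted(bad)}")
    table = root_table.copy()
    for r in graph.root_nodes:
        if r in S:
            table[r] = graph.node(r).reference
    for v in graph.topological_order():
        if v in graph.root_nodes or v == outcome:
            continue
        if v in S:
            table[v] = graph.node(v).reference
        else:
            table = _expand_node(table, v, network.node_models[v], cap)
    if include_outcome:
        table = _expand_node(table, outcome, network.node_models[outcome], cap)
        return table, None
    py = network.node_models[outcome].predict_probs(table)[:, 1]
    return table, py


def joint_distribution(
    network: FittedNetwork,
    root_table: pd.DataFrame | None = None,
    cap: int = DEFAULT_CONFIG_CAP,
) -> JointTable:
    """Exact observational joint distribution over all nodes."""
    if root_table is None:
        root_table = root_table_from_network(network)
    table, _ = _enumerate(network, root_table, frozenset(), True, cap)
    return JointTable(table.reset_index(drop=True))


def do_distribution(
    network: FittedNetwork,
    S: Iterable[str],
    root_table: pd.DataFrame | None = None,
    cap: int = DEFAULT_CONFIG_CAP,
) -> JointTable:
    """Exact joint distribution under do(A_S = ref_S)."""
    if root_table is None:
        root_table = root_table_from_network(network)
    table, _ = _enumerate(network, root_table, frozenset(S), True, cap)
    return JointTable(table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------


class ExactEngine:
    """Cached exact counterfactual prevalences and attributable fractions.

    Construct with either a ``root_table`` (or nothing, to use the
    network's declared root marginals) for the population engine, or with
    ``data`` for the empirical conditional engine.
    """

    def __init__(
        self,
        network: FittedNetwork,
        root_table: pd.DataFrame | None = None,
        data: WeightedDataset | CounterfactualDataset | None = None,
        cap: int = DEFAULT_CONFIG_CAP,
    ) -> None:
        if data is not None and root_table is not None:
            raise ValueError("give either data (empirical) or root_table (population)")
        self.network = network
        self.data = data
        self.cap = cap
        if data is None and root_table is None:
            root_table = root_table_from_network(network)
        self.root_table = root_table
        self._prev_cache: dict[frozenset[str], float] = {}

    # -- prevalences -------------------------------------------------------

    def prevalence(self, S: Iterable[str] = ()) -> float:
        key = frozenset(S)
        if key not in self._prev_cache:
            if self.data is not None:
                self._prev_cache[key] = self._prevalence_empirical(key)
            else:
                self._prev_cache[key] = self._prevalence_population(key)
        return self._prev_cache[key]

    def _prevalence_population(self, S: frozenset[str]) -> float:
        table, py = _enumerate(self.network, self.root_table, S, False, self.cap)
        p = table["prob"].to_numpy()
        return float(np.sum(p * py) / np.sum(p))

    def _prevalence_empirical(self, S: frozenset[str]) -> float:
        graph = self.network.graph
        outcome = graph.outcome
        y_levels = graph.node(outcome).levels
        w = self.data.weights
        y_obs = outcome_values(self.data.df[outcome], y_levels)
        if not S:
            return float(np.sum(w * y_obs) / np.sum(w))
        desc = graph.descendants(S) - S
        mediators = [
            v for v in graph.topological_order() if v in desc and v != outcome
        ]
        level_lists = [list(graph.node(v).levels) for v in mediators]
        n_cfg = int(np.prod([len(l) for l in level_lists])) if level_lists else 1
        if n_cfg * self.data.n > self.cap:
            raise StateSpaceError("empirical enumeration exceeds the configuration cap")
        base = self.data.df.copy(deep=False)
        for s in S:
            base[s] = graph.node(s).reference
        n = len(base)
        acc = np.zeros(n)
        for config in itertools.product(*level_lists) if level_lists else [()]:
            dfc = base.copy(deep=False)
            factor = np.ones(n)
            for v, lvl in zip(mediators, config):
                probs = self.network.node_models[v].predict_probs(dfc)
                factor = factor * probs[:, list(graph.node(v).levels).index(lvl)]
                dfc[v] = lvl
            if outcome in desc:
                py = self.network.node_models[outcome].predict_probs(dfc)[:, 1]
            else:
                py = y_obs
            acc += factor * py
        return float(np.sum(w * acc) / np.sum(w))

    # -- attributable fractions --------------------------------------------

    def paf(self, j: str) -> float:
        return self.saf(j, ())

    def saf(self, j: str, S: Iterable[str]) -> float:
        S = frozenset(S)
        if j in S:
            raise ValueError(f"risk factor {j!r} already in the prior set")
        p0 = self.prevalence(())
        return (self.prevalence(S) - self.prevalence(S | {j})) / p0

    def joint_paf(self, S: Iterable[str]) -> float:
        S = frozenset(S)
        if not S:
            raise ValueError("joint PAF needs a nonempty set")
        p0 = self.prevalence(())
        return (p0 - self.prevalence(S)) / p0

    def sequential_path(self, order: Sequence[str]) -> list[float]:
        out = []
        done: frozenset[str] = frozenset()
        for j in order:
            out.append(self.saf(j, done))
            done = done | {j}
        return out

    def average_af(self, risk_factors: Sequence[str] | None = None) -> dict[str, float]:
        """Exact average attributable fractions over all K! elimination orders.

        Computed from the 2^K cached subset prevalences with the standard
        permutation (Shapley) weights |S|!(K-1-|S|)!/K!, which is exact and
        far cheaper than looping over K! orders.
        """
        import math

        rfs = list(risk_factors or self.network.graph.risk_factors)
        K = len(rfs)
        p0 = self.prevalence(())
        out = {}
        for j in rfs:
            others = [r for r in rfs if r != j]
            total = 0.0
            for size in range(K):
                wgt = math.factorial(size) * math.factorial(K - 1 - size) / math.factorial(K)
                for S in itertools.combinations(others, size):
                    S = frozenset(S)
                    total += wgt * (self.prevalence(S) - self.prevalence(S | {j})) / p0
            out[j] = total
        return out


def exact_af(
    network: FittedNetwork,
    kind: str,
    root_table: pd.DataFrame | None = None,
    data: WeightedDataset | CounterfactualDataset | None = None,
    j: str | None = None,
    S: Iterable[str] = (),
    cap: int = DEFAULT_CONFIG_CAP,
) -> float:
    """One-shot exact attributable fraction; see :class:`ExactEngine`."""
    eng = ExactEngine(network, root_table=root_table, data=data, cap=cap)
    if kind == "PAF":
        return eng.paf(j)
    if kind == "SAF":
        return eng.saf(j, S)
    if kind == "joint_PAF":
        return eng.joint_paf(S)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# exact direct-effects projection
# ---------------------------------------------------------------------------


def project_direct_effects(
    network: FittedNetwork,
    root_table: pd.DataFrame | None = None,
    cap: int = DEFAULT_CONFIG_CAP,
) -> FittedNetwork:
    """The probability-limit of refitting on the direct-effects-only graph.

    Risk factors lose their risk-factor parents; each affected node's new
    conditional is the exact marginalisation of the original network's
    joint distribution over the removed parents (what a correctly
    specified saturated refit would converge to).  Nodes whose parent sets
    are unchanged keep their original models.
    """
    if root_table is None:
        root_table = root_table_from_network(network)
    graph = network.graph
    direct = graph.direct_effects_graph()
    outcome = graph.outcome
    pre_outcome, _ = _enumerate(network, root_table, frozenset(), False, cap)

    node_models: dict[str, NodeModel] = {}
    root_marginals = dict(network.root_marginals)
    for v in direct.node_names:
        old_parents = graph.parents[v]
        new_parents = direct.parents[v]
        if not old_parents:
            continue
        if new_parents == old_parents:
            node_models[v] = network.node_models[v]
            continue
        spec = graph.node(v)
        if not new_parents:
            marg = (
                pre_outcome.groupby(v, observed=True, sort=False)["prob"].sum()
            )
            probs = np.array([marg.get(l, 0.0) for l in spec.levels], float)
            root_marginals[v] = NodeModel.marginal(v, spec.levels, probs)
            continue
        joint = (
            pre_outcome.groupby(list(new_parents) + [v], observed=True, sort=False)[
                "prob"
            ]
            .sum()
            .reset_index()
        )
        wide = joint.pivot_table(
            index=list(new_parents), columns=v, values="prob", aggfunc="sum", fill_value=0.0
        ).reset_index()
        for l in spec.levels:
            if l not in wide.columns:
                wide[l] = 0.0
        denom = wide[list(spec.levels)].sum(axis=1).to_numpy()
        tab = wide[list(new_parents)].copy()
        for l in spec.levels:
            with np.errstate(invalid="ignore"):
                tab[f"p[{l}]"] = np.where(
                    denom > 0, wide[l].to_numpy() / denom, 1.0 / len(spec.levels)
                )
        node_models[v] = NodeModel.cpt(
            v,
            spec.levels,
            new_parents,
            {p: graph.node(p).levels for p in new_parents},
            tab,
        )
    return FittedNetwork(graph=direct, node_models=node_models, root_marginals=root_marginals)
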
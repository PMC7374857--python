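"""Causal DAG over typed categorical nodes.

A :class:`CausalGraph` declares the nodes of a causal Bayesian network —
confounders, risk factors and a single binary disease outcome — together
with each node's parent set.  The graph is the a-priori causal model: no
structure learning happens here, and estimation elsewhere in the package
assumes the declared DAG is correct and contains no unmeasured confounders.

Nodes are categorical.  Risk factors carry a *reference level*, the
lowest-risk category; "eliminating" a risk factor means setting every
subject's value to that level counterfactually.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

ROLE_CONFOUNDER = "confounder"
ROLE_RISK_FACTOR = "risk_factor"
ROLE_OUTCOME = "outcome"
_ROLES = (ROLE_CONFOUNDER, ROLE_RISK_FACTOR, ROLE_OUTCOME)
_VAR_TYPES = ("binary", "ordinal")


@dataclass(frozen=True)
class NodeSpec:
    """One node of the causal graph.

    Parameters
    ----------
    name:
        Column name in datasets.
    role:
        ``"confounder"``, ``"risk_factor"`` or ``"outcome"``.
    var_type:
        ``"binary"`` (exactly two levels) or ``"ordinal"`` (ordered levels).
    levels:
        Ordered category labels, length >= 2.  For ordinal nodes the order
        is the substantive ordering used by the proportional-odds model.
    reference:
        The reference (lowest-risk) level.  Defaults to the first level.
        Required meaningfully for risk factors: interventions set the node
        to this level.
    """

    name: str
    role: str
    var_type: str
    levels: tuple[str, ...]
    reference: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(x) for x in self.levels))
        if not self.reference:
            object.__setattr__(self, "reference", self.levels[0])
        else:
            object.__setattr__(self, "reference", str(self.reference))

    def violations(self) -> list[str]:
        out = []
        if self.role not in _ROLES:
            out.append(f"node {self.name!r}: unknown role {self.role!r}")
        if self.var_type not in _VAR_TYPES:
            out.append(f"node {self.name!r}: unknown var_type {self.var_type!r}")
        if len(self.levels) < 2:
            out.append(f"node {self.name!r}: needs at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            out.append(f"node {self.name!r}: duplicate levels")
        if self.var_type == "binary" and len(self.levels) != 2:
            out.append(f"node {self.name!r}: binary node must have exactly 2 levels")
        if self.reference not in self.levels:
            out.append(
                f"node {self.name!r}: reference {self.reference!r} not among levels"
            )
        return out


@dataclass
class CausalGraph:
    """A DAG over :class:`NodeSpec` nodes with explicit parent sets.

    ``parents[v]`` lists the direct causes of ``v`` in declaration order
    (the order matters only for deterministic design-matrix layout).
    """

    nodes: list[NodeSpec]
    parents: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parents = {
            name: tuple(self.parents.get(name, ())) for name in self.node_names
        }

    # -- basic accessors ---------------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(f"unknown node {name!r}")

    @property
    def risk_factors(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == ROLE_RISK_FACTOR]

    @property
    def confounders(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == ROLE_CONFOUNDER]

    @property
    def outcome(self) -> str:
        names = [n.name for n in self.nodes if n.role == ROLE_OUTCOME]
        if len(names) != 1:
            raise ValueError("graph must declare exactly one outcome node")
        return names[0]

    @property
    def root_nodes(self) -> list[str]:
        return [v for v in self.node_names if not self.parents.get(v)]

    def edges(self) -> list[tuple[str, str]]:
        return [(p, v) for v in self.node_names for p in self.parents[v]]

    def _nx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        g.add_edges_from(self.edges())
        return g

    # -- validation --------------------------------------------------------

    def validate(self) -> list[str]:
        """Return human-readable descriptions of every violated invariant.

        An empty list means the graph is a usable DAG: unique node names,
        well-formed node specs, all parents declared, acyclic, and exactly
        one binary outcome with no children.
        """
        out: list[str] = []
        names = self.node_names
        if len(set(names)) != len(names):
            out.append("duplicate node names")
        for n in self.nodes:
            out.extend(n.violations())
        declared = set(names)
        for v, ps in self.parents.items():
            for p in ps:
                if p not in declared:
                    out.append(f"node {v!r}: undeclared parent {p!r}")
            if len(set(ps)) != len(ps):
                out.append(f"node {v!r}: duplicate parent")
            if v in ps:
                out.append(f"node {v!r}: self-loop")
        outcomes = [n for n in self.nodes if n.role == ROLE_OUTCOME]
        if len(outcomes) != 1:
            out.append(f"graph must have exactly one outcome node, found {len(outcomes)}")
        else:
            y = outcomes[0]
            if y.var_type != "binary":
                out.append("outcome must be binary")
            children = {p for v in names for p in self.parents[v] if p == y.name}
            if children:
                out.append("outcome has a child")
        try:
            g = self._nx()
            if not nx.is_directed_acyclic_graph(g):
                out.append("cycle detected")
        except Exception as exc:  # pragma: no cover - defensive
            out.append(f"graph construction failed: {exc}")
        return out

    # -- graph algorithms --------------------------------------------------

    def topological_order(self) -> list[str]:
        """Topological order with ties broken by node declaration order."""
        idx = {name: i for i, name in enumerate(self.node_names)}
        try:
            return list(
                nx.lexicographical_topological_sort(self._nx(), key=lambda v: idx[v])
            )
        except nx.NetworkXUnfeasible as exc:
            raise ValueError("graph has a cycle; no topological order exists") from exc

    def descendants(self, nodes: Iterable[str]) -> set[str]:
        """Union of strict descendants of ``nodes`` (the nodes themselves excluded)."""
        nodes = list(nodes)
        declared = set(self.node_names)
        for v in nodes:
            if v not in declared:
                raise KeyError(f"unknown node {v!r}")
        g = self._nx()
        out: set[str] = set()
        for v in nodes:
            out |= nx.descendants(g, v)
        return out - set(nodes)

    def direct_effects_graph(self) -> "CausalGraph":
        """The comparison graph with all risk-factor → risk-factor edges removed.

        This encodes the implicit assumption of single-regression attributable
        fraction methods: risk factors act on disease only directly, never by
        shifting the distribution of downstream risk factors.  Edges from
        confounders and edges into the outcome are retained; node specs are
        unchanged.
        """
        rf = set(self.risk_factors)
        new_parents = {
            v: tuple(p for p in ps if not (p in rf and v in rf))
            for v, ps in self.parents.items()
        }
        return CausalGraph(nodes=list(self.nodes), parents=new_parents)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "name": n.name,
                    "role": n.role,
                    "type": n.var_type,
                    "levels": list(n.levels),
                    "reference": n.reference,
                }
                for n in self.nodes
            ],
            "edges": [[p, v] for (p, v) in self.edges()],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CausalGraph":
        nodes = [
            NodeSpec(
                name=str(nd["name"]),
                role=str(nd["role"]),
                var_type=str(nd.get("type", nd.get("var_type", "binary"))),
                levels=tuple(nd["levels"]),
                reference=str(nd.get("reference", "")),
            )
            for nd in d["nodes"]
        ]
        parents: dict[str, list[str]] = {n.name: [] for n in nodes}
        for p, v in d.get("edges", []):
            parents.setdefault(str(v), []).append(str(p))
        return cls(nodes=nodes, parents={k: tuple(v) for k, v in parents.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "CausalGraph":
        """Load a graph config from JSON or YAML (by extension; YAML parses both)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_dot(self) -> str:
        """GraphViz DOT text for visual checking of the assumed structure."""
        shape = {ROLE_CONFOUNDER: "box", ROLE_RISK_FACTOR: "ellipse", ROLE_OUTCOME: "doublecircle"}
        lines = ["digraph causal {"]
        for n in self.nodes:
            lines.append(f'  "{n.name}" [shape={shape.get(n.role, "ellipse")}];')
        for p, v in self.edges():
            lines.append(f'  "{p}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


def chain_graph() -> CausalGraph:
    """Minimal confounder → risk factor → outcome chain (C → A → Y), C → Y included."""
    nodes = [
        NodeSpec("C", ROLE_CONFOUNDER, "binary", ("0", "1")),
        NodeSpec("A", ROLE_RISK_FACTOR, "binary", ("0", "1"), reference="0"),
        NodeSpec("Y", ROLE_OUTCOME, "binary", ("0", "1")),
    ]
    return CausalGraph(nodes=nodes, parents={"A": ("C",), "Y": ("C", "A")})
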
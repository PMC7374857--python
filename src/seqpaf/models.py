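"""Conditional probability models for the nodes of a causal Bayesian network.

Each non-root node gets one model of its distribution given its parents:

* binary nodes — weighted logistic regression (statsmodels GLM, binomial
  family with ``var_weights``, i.e. weighted maximum likelihood);
* ordinal nodes with three or more levels — a weighted proportional-odds
  (cumulative logit) model fitted in-package, since the surrounding
  ecosystem's ordinal regression does not accept observation weights.

Parents enter as indicator (dummy) coded main effects with the first
declared level as baseline.  Root nodes are never simulated — their
observed values are carried through every counterfactual dataset — but
their weighted marginal tables are recorded for the synthetic generator
and the enumeration oracle.

The proportional-odds convention used throughout: with ordered levels
``l_0 < ... < l_{K-1}``, cutpoints ``c_1 < ... < c_{K-1}`` and linear
predictor ``eta = x' beta``,

    P(X <= l_{k-1} | x) = expit(c_k - eta),

so positive coefficients push probability mass toward *higher* (riskier)
levels.  Attributable-fraction estimates are invariant to this internal
convention as long as fitting and simulation share it, which they do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm
from scipy.special import expit

from .graph import CausalGraph

PROB_FLOOR = 1e-12

KIND_LOGISTIC = "logistic"
KIND_PROPORTIONAL_ODDS = "proportional_odds"
KIND_MARGINAL = "marginal_table"
KIND_CPT = "cpt"


class FitError(RuntimeError):
    """A node model failed to fit (non-convergence, separation, empty cells)."""


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class WeightedDataset:
    """Subject-level table of node values with per-row positive weights.

    Columns are pandas Categoricals whose categories follow the graph's
    declared level order.  ``weights`` typically come from
    :func:`make_case_control_weights`; unit weights mean a cohort sample.
    """

    df: pd.DataFrame
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.df):
            raise ValueError("weights length must match number of rows")
        if np.any(self.weights <= 0):
            raise ValueError("all weights must be > 0")

    @property
    def n(self) -> int:
        return len(self.df)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        graph: CausalGraph,
        weights: np.ndarray | None = None,
    ) -> "WeightedDataset":
        """Coerce a raw table to the graph's declared levels and validate it."""
        out = {}
        for spec in graph.nodes:
            if spec.name not in df.columns:
                raise KeyError(f"data is missing declared column {spec.name!r}")
            col = df[spec.name].astype(str)
            cat = pd.Categorical(col, categories=list(spec.levels))
            if cat.isna().any():
                bad = sorted(set(col[pd.isna(cat)]))
                raise ValueError(
                    f"column {spec.name!r} contains undeclared levels {bad}"
                )
            out[spec.name] = cat
        if weights is None:
            weights = np.ones(len(df))
        return cls(pd.DataFrame(out, index=range(len(df))), np.asarray(weights, float))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        graph: CausalGraph,
        weights: np.ndarray | None = None,
        weight_column: str | None = None,
        sep: str = ",",
    ) -> "WeightedDataset":
        raw = pd.read_csv(path, sep=sep, dtype=str)
        if weight_column is not None:
            if weight_column not in raw.columns:
                raise KeyError(f"weight column {weight_column!r} not in data")
            weights = raw[weight_column].astype(float).to_numpy()
        return cls.from_dataframe(raw, graph, weights)

    def outcome_indicator(self, graph: CausalGraph) -> np.ndarray:
        """Outcome column as a float 0/1 (or probability) vector."""
        return outcome_values(self.df[graph.outcome], graph.node(graph.outcome).levels)


def outcome_values(col, levels: Sequence[str]) -> np.ndarray:
    """Map an outcome column to floats: labels -> {0,1}; floats pass through.

    Float columns arise in expected-outcome mode, where the column stores
    P(Y = 1 | parents) per row instead of a Bernoulli draw.
    """
    if isinstance(col, pd.Series):
        col = col.array if isinstance(col.dtype, pd.CategoricalDtype) else col.to_numpy()
    if isinstance(col, pd.Categorical):
        return (np.asarray(col) == levels[1]).astype(float)
    arr = np.asarray(col)
    if arr.dtype.kind in "fi":
        return arr.astype(float)
    return (arr == levels[1]).astype(float)


def make_case_control_weights(
    disease: np.ndarray, case_weight: float, control_weight: float
) -> np.ndarray:
    """Per-row weights for a case-control sample.

    Cases (disease = 1) receive ``case_weight`` and controls ``control_weight``
    so that weighted maximum likelihood imitates estimation from a population
    random sample; taking ``case_weight = incidence`` and
    ``control_weight = 1 - incidence`` makes the weighted sample prevalence
    equal the incidence.
    """
    if case_weight <= 0 or control_weight <= 0:
        raise ValueError("weights must be positive")
    d = np.asarray(disease, dtype=float)
    if not np.all(np.isin(d, (0.0, 1.0))):
        raise ValueError("disease vector must contain only 0/1")
    return np.where(d == 1.0, float(case_weight), float(control_weight))


# ---------------------------------------------------------------------------
# node models
# ---------------------------------------------------------------------------


@dataclass
class NodeModel:
    """Conditional distribution of one node given its parents.

    ``params`` layout by kind:

    * ``logistic`` — ``[intercept, coef...]``, coefs on indicator-coded
      parents (baseline = first declared level of each parent);
    * ``proportional_odds`` — ``[c_1..c_{K-1}, coef...]`` with strictly
      increasing cutpoints;
    * ``marginal_table`` — no params; ``table`` holds level probabilities;
    * ``cpt`` — no params; ``table`` maps each parent configuration to a
      probability vector (used for exact projections and hand-built toys).
    """

    node: str
    kind: str
    levels: tuple[str, ...]
    predictors: tuple[str, ...] = ()
    predictor_levels: dict[str, tuple[str, ...]] = field(default_factory=dict)
    params: np.ndarray = field(default_factory=lambda: np.zeros(0))
    coef_names: tuple[str, ...] = ()
    bse: np.ndarray | None = None
    table: pd.DataFrame | None = None
    converged: bool = True
    loglik: float | None = None

    def __post_init__(self) -> None:
        self.levels = tuple(str(x) for x in self.levels)
        self.params = np.asarray(self.params, dtype=float)
        if self.kind == KIND_PROPORTIONAL_ODDS:
            k = len(self.levels) - 1
            cuts = self.params[:k]
            if np.any(np.diff(cuts) <= 0):
                raise ValueError(f"node {self.node!r}: cutpoints must be increasing")

    # -- constructors ------------------------------------------------------

    @classmethod
    def logistic(
        cls,
        node: str,
        levels: Sequence[str],
        predictors: Sequence[str],
        predictor_levels: Mapping[str, Sequence[str]],
        intercept: float,
        coefs: Mapping[tuple[str, str], float] | None = None,
    ) -> "NodeModel":
        """Build a logistic model from named coefficients.

        ``coefs`` maps (parent, level) to the log-odds shift of that level
        relative to the parent's first level; unspecified cells are 0.
        """
        pl = {p: tuple(map(str, predictor_levels[p])) for p in predictors}
        names = _coef_names(predictors, pl)
        beta = np.zeros(1 + len(names))
        beta[0] = intercept
        for i, (p, lvl) in enumerate(_coef_cells(predictors, pl)):
            beta[1 + i] = (coefs or {}).get((p, lvl), 0.0)
        return cls(
            node=node,
            kind=KIND_LOGISTIC,
            levels=tuple(levels),
            predictors=tuple(predictors),
            predictor_levels=pl,
            params=beta,
            coef_names=("(intercept)",) + names,
        )

    @classmethod
    def proportional_odds(
        cls,
        node: str,
        levels: Sequence[str],
        predictors: Sequence[str],
        predictor_levels: Mapping[str, Sequence[str]],
        cutpoints: Sequence[float],
        coefs: Mapping[tuple[str, str], float] | None = None,
    ) -> "NodeModel":
        pl = {p: tuple(map(str, predictor_levels[p])) for p in predictors}
        names = _coef_names(predictors, pl)
        k = len(levels) - 1
        if len(cutpoints) != k:
            raise ValueError("need K-1 cutpoints for K levels")
        beta = np.zeros(k + len(names))
        beta[:k] = np.asarray(cutpoints, float)
        for i, (p, lvl) in enumerate(_coef_cells(predictors, pl)):
            beta[k + i] = (coefs or {}).get((p, lvl), 0.0)
        return cls(
            node=node,
            kind=KIND_PROPORTIONAL_ODDS,
            levels=tuple(levels),
            predictors=tuple(predictors),
            predictor_levels=pl,
            params=beta,
            coef_names=tuple(f"cut[{i + 1}]" for i in range(k)) + names,
        )

    @classmethod
    def marginal(cls, node: str, levels: Sequence[str], probs: Sequence[float]) -> "NodeModel":
        probs = np.asarray(probs, float)
        if probs.shape != (len(levels),) or np.any(probs < 0):
            raise ValueError("need one nonnegative probability per level")
        probs = probs / probs.sum()
        table = pd.DataFrame({"level": list(levels), "prob": probs})
        return cls(node=node, kind=KIND_MARGINAL, levels=tuple(levels), table=table)

    @classmethod
    def cpt(
        cls,
        node: str,
        levels: Sequence[str],
        predictors: Sequence[str],
        predictor_levels: Mapping[str, Sequence[str]],
        table: pd.DataFrame,
    ) -> "NodeModel":
        """Full conditional probability table.

        ``table`` has one row per parent configuration: the parent columns
        plus ``p[<level>]`` probability columns.
        """
        need = [f"p[{l}]" for l in levels]
        for c in list(predictors) + need:
            if c not in table.columns:
                raise ValueError(f"cpt table missing column {c!r}")
        return cls(
            node=node,
            kind=KIND_CPT,
            levels=tuple(levels),
            predictors=tuple(predictors),
            predictor_levels={p: tuple(map(str, predictor_levels[p])) for p in predictors},
            table=table.reset_index(drop=True),
        )

    # -- prediction --------------------------------------------------------

    def predict_probs(self, df: pd.DataFrame) -> np.ndarray:
        """Category-probability matrix (n rows × K levels) given parent columns."""
        n = len(df)
        k = len(self.levels)
        if self.kind == KIND_MARGINAL:
            probs = np.tile(self.table["prob"].to_numpy(), (n, 1))
        elif self.kind == KIND_CPT:
            key = pd.DataFrame(
                {p: df[p].astype(str).to_numpy() for p in self.predictors}
            )
            tab = self.table.copy()
            for p in self.predictors:
                tab[p] = tab[p].astype(str)
            merged = key.merge(tab, on=list(self.predictors), how="left", sort=False)
            probs = merged[[f"p[{l}]" for l in self.levels]].to_numpy(float)
            if np.isnan(probs).any():
                raise ValueError(
                    f"node {self.node!r}: parent configuration absent from CPT"
                )
        elif self.kind == KIND_LOGISTIC:
            x = _design_matrix(df, self.predictors, self.predictor_levels, intercept=True)
            p1 = expit(x @ self.params)
            probs = np.column_stack([1.0 - p1, p1])
        elif self.kind == KIND_PROPORTIONAL_ODDS:
            x = _design_matrix(df, self.predictors, self.predictor_levels, intercept=False)
            ncut = k - 1
            eta = x @ self.params[ncut:]
            cum = expit(self.params[:ncut][None, :] - eta[:, None])
            probs = np.diff(np.hstack([np.zeros((n, 1)), cum, np.ones((n, 1))]), axis=1)
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        probs = np.clip(probs, PROB_FLOOR, 1.0 - PROB_FLOOR)
        return probs / probs.sum(axis=1, keepdims=True)

    def predict_row(self, parent_values: Mapping[str, str]) -> np.ndarray:
        """Probability vector over the node's levels for one parent configuration."""
        for p in self.predictors:
            if p not in parent_values:
                raise KeyError(f"missing parent {p!r}")
            if str(parent_values[p]) not in self.predictor_levels[p]:
                raise ValueError(
                    f"unknown level {parent_values[p]!r} for parent {p!r}"
                )
        df = pd.DataFrame({p: [str(parent_values[p])] for p in self.predictors})
        if not self.predictors:
            df = pd.DataFrame(index=[0])
        return self.predict_probs(df)[0]

    def sample(self, df: pd.DataFrame, rng: np.random.Generator) -> pd.Categorical:
        """One categorical draw per row, reproducible given ``rng``."""
        probs = self.predict_probs(df)
        codes = sample_categorical(probs, rng)
        return pd.Categorical.from_codes(codes, categories=list(self.levels))

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "node": self.node,
            "kind": self.kind,
            "levels": list(self.levels),
            "predictors": list(self.predictors),
            "predictor_levels": {p: list(v) for p, v in self.predictor_levels.items()},
            "params": self.params.tolist(),
            "coef_names": list(self.coef_names),
            "converged": bool(self.converged),
            "loglik": self.loglik,
        }
        if self.bse is not None:
            d["bse"] = np.asarray(self.bse).tolist()
        if self.table is not None:
            d["table"] = self.table.to_dict(orient="list")
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "NodeModel":
        return cls(
            node=d["node"],
            kind=d["kind"],
            levels=tuple(d["levels"]),
            predictors=tuple(d.get("predictors", ())),
            predictor_levels={p: tuple(v) for p, v in d.get("predictor_levels", {}).items()},
            params=np.asarray(d.get("params", []), float),
            coef_names=tuple(d.get("coef_names", ())),
            bse=None if d.get("bse") is None else np.asarray(d["bse"], float),
            table=None if d.get("table") is None else pd.DataFrame(d["table"]),
            converged=bool(d.get("converged", True)),
            loglik=d.get("loglik"),
        )


def sample_categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised inverse-CDF draw: one category code per row of ``probs``."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


def _coef_cells(predictors, predictor_levels):
    for p in predictors:
        for lvl in predictor_levels[p][1:]:
            yield p, lvl


def _coef_names(predictors, predictor_levels) -> tuple[str, ...]:
    return tuple(f"{p}[{lvl}]" for p, lvl in _coef_cells(predictors, predictor_levels))


def _design_matrix(df, predictors, predictor_levels, intercept: bool) -> np.ndarray:
    n = len(df)
    cols = [np.ones(n)] if intercept else []
    for p in predictors:
        vals = df[p]
        vals = vals.astype(str).to_numpy() if isinstance(vals, pd.Series) else np.asarray(vals, str)
        for lvl in predictor_levels[p][1:]:
            cols.append((vals == lvl).astype(float))
    if not cols:
        return np.ones((n, 0))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# fitted network
# ---------------------------------------------------------------------------


@dataclass
class FittedNetwork:
    """A causal graph plus one conditional model per node with parents.

    ``node_models`` covers exactly the non-root nodes.  ``root_marginals``
    holds weighted marginal tables for root nodes; simulation of observed
    data carries root values from the data, so these are used only by the
    synthetic generator and the oracle's population mode.
    """

    graph: CausalGraph
    node_models: dict[str, NodeModel]
    root_marginals: dict[str, NodeModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        non_root = {v for v in self.graph.node_names if self.graph.parents[v]}
        have = set(self.node_models)
        if have != non_root:
            missing, extra = non_root - have, have - non_root
            raise ValueError(
                f"node_models must cover exactly the non-root nodes; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    @property
    def root_nodes(self) -> list[str]:
        return self.graph.root_nodes

    def model_for(self, node: str) -> NodeModel:
        if node in self.node_models:
            return self.node_models[node]
        return self.root_marginals[node]

    def to_dict(self) -> dict:
        return {
            "graph": self.graph.to_dict(),
            "node_models": {k: m.to_dict() for k, m in self.node_models.items()},
            "root_marginals": {k: m.to_dict() for k, m in self.root_marginals.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedNetwork":
        return cls(
            graph=CausalGraph.from_dict(d["graph"]),
            node_models={k: NodeModel.from_dict(v) for k, v in d["node_models"].items()},
            root_marginals={
                k: NodeModel.from_dict(v) for k, v in d.get("root_marginals", {}).items()
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "FittedNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_MAX_ABS_COEF = 30.0  # |log-odds| beyond this flags separation / a degenerate cell


def fit_node_models(data: WeightedDataset, graph: CausalGraph) -> FittedNetwork:
    """Weighted maximum-likelihood fit of every non-root node's model.

    Binary nodes get logistic regressions, ordinal nodes (>= 3 levels)
    proportional-odds models, both on indicator-coded parent main effects.
    Root nodes get weighted empirical marginal tables.  Non-convergence or
    apparent separation raises :class:`FitError` naming the node — a bad
    component model would silently corrupt every downstream counterfactual.
    """
    problems = graph.validate()
    if problems:
        raise ValueError("invalid graph: " + "; ".join(problems))
    node_models: dict[str, NodeModel] = {}
    root_marginals: dict[str, NodeModel] = {}
    w = data.weights
    for name in graph.topological_order():
        spec = graph.node(name)
        parents = graph.parents[name]
        if not parents:
            probs = np.array(
                [w[(np.asarray(data.df[name]) == lvl)].sum() for lvl in spec.levels]
            )
            root_marginals[name] = NodeModel.marginal(name, spec.levels, probs / probs.sum())
            continue
        pl = {p: graph.node(p).levels for p in parents}
        for p in parents:
            present = set(pd.unique(data.df[p].astype(str)))
            empty = [lvl for lvl in pl[p] if lvl not in present]
            if empty:
                raise FitError(
                    f"node {name!r}: parent {p!r} has empty category cells {empty}"
                )
        if len(spec.levels) == 2:
            node_models[name] = _fit_logistic(data, name, spec.levels, parents, pl)
        else:
            node_models[name] = _fit_proportional_odds(data, name, spec.levels, parents, pl)
    return FittedNetwork(graph=graph, node_models=node_models, root_marginals=root_marginals)


def _fit_logistic(data, name, levels, parents, predictor_levels) -> NodeModel:
    y = (np.asarray(data.df[name]) == levels[1]).astype(float)
    x = _design_matrix(data.df, parents, predictor_levels, intercept=True)
    try:
        res = sm.GLM(y, x, family=sm.families.Binomial(), var_weights=data.weights).fit(
            maxiter=200
        )
    except Exception as exc:
        raise FitError(f"node {name!r}: logistic fit failed ({exc})") from exc
    beta = np.asarray(res.params, float)
    if not np.all(np.isfinite(beta)) or np.any(np.abs(beta) > _MAX_ABS_COEF):
        raise FitError(f"node {name!r}: logistic fit did not converge (separation?)")
    return NodeModel(
        node=name,
        kind=KIND_LOGISTIC,
        levels=tuple(levels),
        predictors=tuple(parents),
        predictor_levels=predictor_levels,
        params=beta,
        coef_names=("(intercept)",) + _coef_names(parents, predictor_levels),
        bse=np.asarray(res.bse, float),
        converged=bool(res.converged),
        loglik=float(res.llf),
    )


def _po_negll_grad(theta, x, ycode, w, k):
    """Weighted cumulative-logit negative log-likelihood and gradient.

    theta = (c_1, log(c_2 - c_1), ..., log(c_{K-1} - c_{K-2}), beta); the
    log-difference reparameterisation keeps cutpoints strictly increasing
    for any unconstrained theta.
    """
    ncut = k - 1
    raw = theta[:ncut]
    cuts = np.empty(ncut)
    cuts[0] = raw[0]
    if ncut > 1:
        cuts[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
    beta = theta[ncut:]
    eta = x @ beta
    lo = np.where(ycode > 0, cuts[np.maximum(ycode - 1, 0)] - eta, -np.inf)
    hi = np.where(ycode < ncut, cuts[np.minimum(ycode, ncut - 1)] - eta, np.inf)
    f_hi = expit(hi)
    f_lo = expit(lo)
    p = np.clip(f_hi - f_lo, PROB_FLOOR, 1.0)
    nll = -np.sum(w * np.log(p))

    d_hi = np.where(np.isfinite(hi), f_hi * (1 - f_hi), 0.0)  # dF/d(hi)
    d_lo = np.where(np.isfinite(lo), f_lo * (1 - f_lo), 0.0)
    inv_p = w / p
    # gradient wrt the cutpoints c_k
    g_cuts = np.zeros(ncut)
    for kk in range(ncut):
        contrib = np.where(ycode == kk, d_hi, 0.0) - np.where(ycode == kk + 1, d_lo, 0.0)
        g_cuts[kk] = -np.sum(inv_p * contrib)
    # gradient wrt beta: d p / d eta = -d_hi + d_lo
    g_eta = inv_p * (d_hi - d_lo)  # = -w/p * dp/deta
    g_beta = x.T @ g_eta
    # chain rule to the reparameterised theta
    g_raw = np.zeros(ncut)
    g_raw[0] = g_cuts.sum()
    for j in range(1, ncut):
        g_raw[j] = np.sum(g_cuts[j:]) * np.exp(theta[j])
    return nll, np.concatenate([g_raw, g_beta])


def _fit_proportional_odds(data, name, levels, parents, predictor_levels) -> NodeModel:
    k = len(levels)
    ncut = k - 1
    codes = pd.Categorical(data.df[name], categories=list(levels)).codes.astype(np.int64)
    x = _design_matrix(data.df, parents, predictor_levels, intercept=False)
    w = data.weights
    # start from weighted marginal cumulative logits, beta = 0
    freq = np.array([w[codes == j].sum() for j in range(k)], float)
    cum = np.cumsum(freq / freq.sum())[:-1]
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    c0 = np.log(cum / (1 - cum))
    c0 = np.maximum.accumulate(c0 + 1e-9 * np.arange(ncut))
    theta0 = np.zeros(ncut + x.shape[1])
    theta0[0] = c0[0]
    if ncut > 1:
        theta0[1:ncut] = np.log(np.maximum(np.diff(c0), 1e-3))
    res = scipy.optimize.minimize(
        _po_negll_grad,
        theta0,
        args=(x, codes, w, k),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * max(1.0, w.sum()):
        raise FitError(f"node {name!r}: proportional-odds fit did not converge")
    raw = res.x[:ncut]
    cuts = np.empty(ncut)
    cuts[0] = raw[0]
    if ncut > 1:
        cuts[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
    beta = res.x[ncut:]
    params = np.concatenate([cuts, beta])
    if np.any(np.abs(params) > _MAX_ABS_COEF):
        raise FitError(f"node {name!r}: proportional-odds fit diverged (separation?)")
    bse = _po_bse(params, x, codes, w, k)
    return NodeModel(
        node=name,
        kind=KIND_PROPORTIONAL_ODDS,
        levels=tuple(levels),
        predictors=tuple(parents),
        predictor_levels=predictor_levels,
        params=params,
        coef_names=tuple(f"cut[{i + 1}]" for i in range(ncut))
        + _coef_names(parents, predictor_levels),
        bse=bse,
        converged=True,
        loglik=-float(res.fun),
    )


def _po_bse(params, x, ycode, w, k) -> np.ndarray | None:
    """Asymptotic SEs from a central-difference Hessian in (cuts, beta) space."""
    ncut = k - 1

    def negll(p):
        cuts, beta = p[:ncut], p[ncut:]
        eta = x @ beta
        lo = np.where(ycode > 0, cuts[np.maximum(ycode - 1, 0)] - eta, -np.inf)
        hi = np.where(ycode < ncut, cuts[np.minimum(ycode, ncut - 1)] - eta, np.inf)
        pr = np.clip(expit(hi) - expit(lo), PROB_FLOOR, 1.0)
        return -np.sum(w * np.log(pr))

    m = len(params)
    h = 1e-4 * np.maximum(1.0, np.abs(params))
    hess = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            pp = params.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = params.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = params.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = params.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            hess[i, j] = hess[j, i] = (negll(pp) - negll(pm) - negll(mp) + negll(mm)) / (
                4 * h[i] * h[j]
            )
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        if np.any(d <= 0):
            return None
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# functional conveniences
# ---------------------------------------------------------------------------


def predict_category_probs(model: NodeModel, parent_values: Mapping[str, str]) -> np.ndarray:
    """Probability vector over ``model``'s levels for one parent configuration."""
    return model.predict_row(parent_values)


def sample_node(
    model: NodeModel, parent_values: Mapping[str, str], rng: np.random.Generator
) -> str:
    """One category draw for a single parent configuration."""
    probs = model.predict_row(parent_values)
    code = sample_categorical(probs[None, :], rng)[0]
    return model.levels[code]
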
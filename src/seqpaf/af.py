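"""Attributable-fraction estimators.

All estimators share one algebraic core.  With per-row weights ``w_i``,
observed disease ``Y_i`` and counterfactual disease columns ``D_S(Y_i)``
(draws or expected values under ``do(A_S = ref_S)``), the sequential
attributable fraction of risk factor j given an already-eliminated set S is

    SAF_{j|S} = ( sum_i w_i D_S(Y_i) - sum_i w_i D_{S∪j}(Y_i) ) / sum_i w_i Y_i .

The ordinary PAF is the S = ∅ special case, and the joint PAF of a set is
one simultaneous intervention.  The observed-data denominator is shared by
every estimate in a run, so SAFs along an elimination order telescope
exactly to the joint PAF of the full set.

Negative SAFs are reported as-is: mediated pathways can attenuate or even
reverse an increment, and clipping would hide exactly the phenomenon the
causal network is there to capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervene import (
    OUTCOME_SAMPLE,
    CounterfactualDataset,
    do_intervene,
)
from .models import FittedNetwork, WeightedDataset, outcome_values

KIND_PAF = "PAF"
KIND_SAF = "SAF"
KIND_JOINT = "joint_PAF"
KIND_AAF = "AAF"


@dataclass
class AFResult:
    """A point estimate with optional Monte-Carlo standard error."""

    kind: str
    risk_factor: str | frozenset[str]
    estimate: float
    prior_set: frozenset[str] = frozenset()
    mc_se: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimate > 1.0 + 1e-12:
            raise ValueError("attributable fraction cannot exceed 1")


def as_rng(rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.Generator(np.random.PCG64(rng))


def _outcome_vec(net: FittedNetwork, ds) -> np.ndarray:
    y_levels = net.graph.node(net.graph.outcome).levels
    return outcome_values(ds.df[net.graph.outcome], y_levels)


def _batch_slices(n: int, n_batches: int) -> list[np.ndarray]:
    return np.array_split(np.arange(n), n_batches)


def _ratio_with_batches(num: np.ndarray, den: np.ndarray, n_batches: int | None):
    """Estimate sum(num)/sum(den) with a batch-means standard error.

    Rows are i.i.d. subjects, so splitting them into B blocks and taking
    the SD of the block-level ratios over sqrt(B) estimates the Monte-Carlo
    + sampling error of the full ratio.
    """
    est = float(num.sum() / den.sum())
    if not n_batches:
        return est, None, None
    batches = []
    for idx in _batch_slices(len(num), n_batches):
        d = den[idx].sum()
        batches.append(num[idx].sum() / d if d != 0 else np.nan)
    batches = np.asarray(batches, float)
    ok = batches[np.isfinite(batches)]
    se = float(ok.std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else None
    return est, se, batches


def estimate_saf(
    network: FittedNetwork,
    prev_dataset: CounterfactualDataset,
    next_dataset: CounterfactualDataset,
    observed: WeightedDataset | CounterfactualDataset,
    n_batches: int | None = None,
) -> AFResult:
    """SAF for the single risk factor separating two nested interventions."""
    extra = next_dataset.intervened - prev_dataset.intervened
    if len(extra) != 1 or not prev_dataset.intervened <= next_dataset.intervened:
        raise ValueError(
            "next_dataset must extend prev_dataset's intervention by exactly one risk factor"
        )
    (j,) = extra
    w = np.asarray(observed.weights, float)
    if len(w) != next_dataset.n or len(w) != prev_dataset.n:
        raise ValueError("datasets must share subjects and weights")
    y_obs = _outcome_vec(network, observed)
    denom = w * y_obs
    if denom.sum() == 0:
        raise ZeroDivisionError("observed weighted disease prevalence is zero")
    num = w * (_outcome_vec(network, prev_dataset) - _outcome_vec(network, next_dataset))
    est, se, batches = _ratio_with_batches(num, denom, n_batches)
    return AFResult(
        kind=KIND_SAF if prev_dataset.intervened else KIND_PAF,
        risk_factor=j,
        prior_set=frozenset(prev_dataset.intervened),
        estimate=est,
        mc_se=se,
        meta={} if batches is None else {"batch_estimates": batches},
    )


def sequential_path(
    network: FittedNetwork,
    observed: WeightedDataset,
    order: Sequence[str],
    rng: int | np.random.Generator,
    outcome_mode: str = OUTCOME_SAMPLE,
    n_batches: int | None = None,
    keep_datasets: bool = False,
) -> list[AFResult]:
    """SAF at every position of one elimination order.

    One pass produces the nested datasets D_∅ ⊂ D_{S1} ⊂ ... by reusing
    each step's dataset as the next step's starting point; the observed
    denominator is shared across the whole path.
    """
    if len(set(order)) != len(order):
        raise ValueError("elimination order contains duplicates")
    gen = as_rng(rng)
    current = CounterfactualDataset.from_observed(observed)
    results: list[AFResult] = []
    for pos, j in enumerate(order):
        nxt = do_intervene(network, current, {j}, gen, outcome_mode=outcome_mode)
        res = estimate_saf(network, current, nxt, observed, n_batches=n_batches)
        res.meta.update(position=pos + 1, outcome_mode=outcome_mode)
        if keep_datasets:
            res.meta["dataset"] = nxt
        results.append(res)
        current = nxt
    return results


def estimate_paf(
    network: FittedNetwork,
    observed: WeightedDataset,
    j: str,
    rng: int | np.random.Generator,
    outcome_mode: str = OUTCOME_SAMPLE,
    n_batches: int | None = None,
) -> AFResult:
    """Population attributable fraction of one risk factor.

    Exactly the length-1 sequential path (same rng-substream contract, so
    a shared seed reproduces the identical number).
    """
    res = sequential_path(
        network, observed, [j], rng, outcome_mode=outcome_mode, n_batches=n_batches
    )[0]
    res.kind = KIND_PAF
    return res


def estimate_joint_paf(
    network: FittedNetwork,
    observed: WeightedDataset,
    S: Iterable[str],
    rng: int | np.random.Generator,
    outcome_mode: str = OUTCOME_SAMPLE,
    n_batches: int | None = None,
) -> AFResult:
    """Joint PAF of a set: one simultaneous intervention on all of S.

    Cheaper than summing a sequential path and unbiased for the same
    quantity; the telescoping identity (sum of SAFs along any order through
    S equals this) is a tested property, not the implementation.
    """
    S = list(S)
    if not S:
        raise ValueError("joint PAF needs a nonempty risk-factor set")
    gen = as_rng(rng)
    base = CounterfactualDataset.from_observed(observed)
    d_s = do_intervene(network, base, S, gen, outcome_mode=outcome_mode)
    w = observed.weights
    y_obs = _outcome_vec(network, base)
    denom = w * y_obs
    if denom.sum() == 0:
        raise ZeroDivisionError("observed weighted disease prevalence is zero")
    num = w * (y_obs - _outcome_vec(network, d_s))
    est, se, batches = _ratio_with_batches(num, denom, n_batches)
    return AFResult(
        kind=KIND_JOINT,
        risk_factor=frozenset(S),
        estimate=est,
        mc_se=se,
        meta={"outcome_mode": outcome_mode}
        | ({} if batches is None else {"batch_estimates": batches}),
    )


def results_to_frame(results: Iterable[AFResult]) -> pd.DataFrame:
    """Tidy table of AF results (one row per estimate)."""
    rows = []
    for r in results:
        rf = r.risk_factor
        rows.append(
            {
                "kind": r.kind,
                "risk_factor": "+".join(sorted(rf)) if isinstance(rf, frozenset) else rf,
                "prior_set": "+".join(sorted(r.prior_set)),
                "position": r.meta.get("position", ""),
                "estimate": r.estimate,
                "mc_se": r.mc_se,
            }
        )
    return pd.DataFrame(rows)
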
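"""Average attributable fractions by random sampling of elimination orders.

The average attributable fraction (AAF) of a risk factor is its sequential
attributable fraction averaged over all K! elimination orders — a
Shapley-value-style allocation of the joint PAF across risk factors.  K!
grows too fast to enumerate beyond small K, so :func:`average_af` samples
m i.i.d. uniform permutations, runs one sequential elimination path per
sampled order, and averages; the Monte-Carlo standard error of each AAF is
the across-order standard deviation over sqrt(m).  For small K,
:func:`exact_average_af` computes the exact average from the 2^K subset
prevalences of the enumeration oracle.

Orders are independent work units seeded from deterministic substreams of
the master seed, so results do not depend on execution order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .af import KIND_AAF, AFResult, sequential_path
from .intervene import OUTCOME_SAMPLE
from .models import FittedNetwork, WeightedDataset
from .oracle import ExactEngine


def order_rng(seed: int, order_index: int) -> np.random.Generator:
    """The deterministic rng substream used to simulate one sampled order."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(1, order_index)))
    )


@dataclass
class OrderSample:
    """Sampled elimination orders, optionally with their per-order SAFs."""

    orders: list[tuple[str, ...]]
    seed: int
    per_order_safs: pd.DataFrame | None = None  # rows = orders, cols = risk factors

    @property
    def m(self) -> int:
        return len(self.orders)


@dataclass
class AAFTable:
    """Average attributable fractions with Monte-Carlo uncertainty.

    ``table`` has one row per risk factor (point estimate = mean over
    sampled orders, mc_se = sd / sqrt(m)); ``position_profile`` gives the
    mean SAF by position in the elimination order with a 95% normal
    Monte-Carlo interval.
    """

    table: pd.DataFrame
    position_profile: pd.DataFrame
    order_sample: OrderSample
    joint_paf: float
    joint_paf_mc_se: float | None
    meta: dict = field(default_factory=dict)

    def results(self) -> list[AFResult]:
        out = []
        for _, row in self.table.iterrows():
            out.append(
                AFResult(
                    kind=KIND_AAF,
                    risk_factor=row["risk_factor"],
                    estimate=float(row["aaf"]),
                    mc_se=None if pd.isna(row["mc_se"]) else float(row["mc_se"]),
                    meta=dict(self.meta),
                )
            )
        return out

    def save_csv(self, table_path, positions_path=None) -> None:
        self.table.to_csv(table_path, index=False)
        if positions_path is not None:
            self.position_profile.to_csv(positions_path, index=False)

    def plot_position_profile(self, path) -> None:
        """Mean SAF by elimination position with 95% Monte-Carlo bands."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        prof = self.position_profile
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for rf, sub in prof.groupby("risk_factor", sort=False):
            ax.errorbar(
                sub["position"],
                sub["mean_saf"],
                yerr=1.96 * sub["mc_se"].fillna(0.0),
                marker="o",
                capsize=2,
                label=rf,
            )
        ax.set_xlabel("position in elimination order")
        ax.set_ylabel("mean sequential attributable fraction")
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def sample_orders(
    risk_factors: Sequence[str], m: int, seed: int
) -> OrderSample:
    """m i.i.d. uniformly-random elimination orders, reproducible given seed."""
    if m < 1:
        raise ValueError("need at least one sampled order")
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    )
    rfs = list(risk_factors)
    orders = [tuple(rng.permutation(rfs)) for _ in range(m)]
    return OrderSample(orders=orders, seed=seed)


def average_af(
    network: FittedNetwork,
    observed: WeightedDataset,
    m: int = 1000,
    seed: int = 0,
    outcome_mode: str = OUTCOME_SAMPLE,
    risk_factors: Sequence[str] | None = None,
) -> AAFTable:
    """Monte-Carlo average attributable fractions over m sampled orders.

    Each sampled order contributes one full sequential elimination path
    (fresh counterfactual simulations, its own rng substream); AAF_j is the
    mean of risk factor j's SAFs across orders.  The default m = 1000 is
    the smallest order sample recommended for stable estimates; larger m
    shrinks the Monte-Carlo SE as 1/sqrt(m).
    """
    rfs = list(risk_factors or network.graph.risk_factors)
    sample = sample_orders(rfs, m, seed)
    saf_mat = np.empty((m, len(rfs)))
    pos_mat = np.empty((m, len(rfs)))  # SAF by position within each order
    col = {rf: i for i, rf in enumerate(rfs)}
    for i, order in enumerate(sample.orders):
        results = sequential_path(
            network, observed, order, order_rng(seed, i), outcome_mode=outcome_mode
        )
        for pos, res in enumerate(results):
            saf_mat[i, col[res.risk_factor]] = res.estimate
            pos_mat[i, pos] = res.estimate
    sample.per_order_safs = pd.DataFrame(saf_mat, columns=rfs)

    mc_se = (
        saf_mat.std(axis=0, ddof=1) / math.sqrt(m) if m > 1 else np.full(len(rfs), np.nan)
    )
    table = pd.DataFrame(
        {"risk_factor": rfs, "aaf": saf_mat.mean(axis=0), "mc_se": mc_se}
    )

    # position-stratified profile: mean SAF of each risk factor at each position
    rows = []
    order_arr = np.array([list(o) for o in sample.orders])
    for pos in range(len(rfs)):
        at_pos = order_arr[:, pos]
        for rf in rfs:
            mask = at_pos == rf
            k = int(mask.sum())
            if k == 0:
                continue
            vals = pos_mat[mask, pos]
            rows.append(
                {
                    "position": pos + 1,
                    "risk_factor": rf,
                    "mean_saf": vals.mean(),
                    "mc_se": vals.std(ddof=1) / math.sqrt(k) if k > 1 else np.nan,
                    "n_orders": k,
                }
            )
    profile = pd.DataFrame(rows)

    sums = saf_mat.sum(axis=1)
    return AAFTable(
        table=table,
        position_profile=profile,
        order_sample=sample,
        joint_paf=float(sums.mean()),
        joint_paf_mc_se=float(sums.std(ddof=1) / math.sqrt(m)) if m > 1 else None,
        meta={"m": m, "seed": seed, "outcome_mode": outcome_mode, "engine": "simulation"},
    )


def exact_average_af(
    network: FittedNetwork,
    observed: WeightedDataset | None = None,
    risk_factors: Sequence[str] | None = None,
    max_K: int = 5,
    root_table: pd.DataFrame | None = None,
) -> AAFTable:
    """Exact average attributable fractions via the enumeration oracle.

    With ``observed`` given, uses the empirical conditional engine (exact
    expectation of the simulation estimator on that dataset); otherwise the
    population engine on ``root_table`` / the network's root marginals.
    Every Monte-Carlo SE is exactly zero.  Guarded by ``max_K`` because the
    number of elimination orders grows as K!.
    """
    rfs = list(risk_factors or network.graph.risk_factors)
    K = len(rfs)
    if K > max_K:
        raise ValueError(f"exact average over {K}! orders refused (max_K={max_K})")
    eng = ExactEngine(network, data=observed, root_table=root_table)
    aafs = eng.average_af(rfs)
    table = pd.DataFrame(
        {"risk_factor": rfs, "aaf": [aafs[r] for r in rfs], "mc_se": 0.0}
    )
    rows = []
    for pos in range(K):
        for rf in rfs:
            vals = [
                eng.saf(rf, order[:pos])
                for order in itertools.permutations(rfs)
                if order[pos] == rf
            ]
            rows.append(
                {
                    "position": pos + 1,
                    "risk_factor": rf,
                    "mean_saf": float(np.mean(vals)),
                    "mc_se": 0.0,
                    "n_orders": len(vals),
                }
            )
    profile = pd.DataFrame(rows)
    return AAFTable(
        table=table,
        position_profile=profile,
        order_sample=OrderSample(orders=list(itertools.permutations(rfs)), seed=-1),
        joint_paf=eng.joint_paf(rfs),
        joint_paf_mc_se=0.0,
        meta={"engine": "oracle", "mode": "empirical" if observed is not None else "population"},
    )
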
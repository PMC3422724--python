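"""Comparative cost-effectiveness: ICER tables, dominance, NMB, CEACs.

Strategies are rank-ordered by increasing cost; strategies that are
more costly yet no more effective than a cheaper alternative are
*dominated*; strategies removed because the ICER sequence along the
remaining frontier is non-monotone are *weakly dominated* (extended
dominance); survivors receive an ICER versus the previous frontier
member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import StrategyResult

__all__ = [
    "CEATableRow",
    "CEACPoint",
    "icer_table",
    "nmb",
    "ceac",
    "pairwise_ce_probability",
    "table_to_frame",
]

REFERENCE = "reference"
DOMINATED = "dominated"
WEAKLY_DOMINATED = "weakly_dominated"


@dataclass(frozen=True)
class CEATableRow:
    """One line of a cost-effectiveness table."""

    strategy: str
    cost: float
    qaly: float
    inc_cost: float | None      # vs previous frontier member (None for reference)
    inc_qaly: float | None
    status: str                 # REFERENCE, DOMINATED, WEAKLY_DOMINATED or ICER
    icer: float | None = None

    @property
    def on_frontier(self) -> bool:
        return self.status not in (DOMINATED, WEAKLY_DOMINATED)


@dataclass(frozen=True)
class CEACPoint:
    """Acceptability at one willingness-to-pay threshold."""

    wtp: float
    probabilities: dict[str, float]   # sums to 1 over strategies


def nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit: QALYs valued at ``wtp`` minus cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return result.qaly * wtp - result.cost


def icer_table(results: list[StrategyResult]) -> list[CEATableRow]:
    """Rank-ordered CEA table with dominance classification.

    The least costly strategy is the reference. A strategy is dominated
    if some cheaper (or equally costly) strategy yields at least as many
    QALYs; equal-QALY-higher-cost counts as dominated by convention.
    Extended dominance then removes strategies whose ICER exceeds that
    of the next frontier member.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies to compare")
    names = [r.name for r in results]
    if len(set(names)) != len(names):
        raise ValueError("strategy names must be unique")

    order = sorted(results, key=lambda r: (r.cost, -r.qaly))
    status: dict[str, str] = {}

    # strict dominance
    for i, r in enumerate(order):
        for s in order[:i]:
            cheaper = s.cost < r.cost or (s.cost == r.cost and s.qaly > r.qaly)
            if cheaper and s.qaly >= r.qaly:
                status[r.name] = DOMINATED
                break

    # extended dominance among the remainder: drop members until the
    # ICER sequence along the frontier is increasing
    frontier = [r for r in order if r.name not in status]
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        icers = [
            (frontier[i].cost - frontier[i - 1].cost)
            / (frontier[i].qaly - frontier[i - 1].qaly)
            for i in range(1, len(frontier))
        ]
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:
                status[frontier[i + 1].name] = WEAKLY_DOMINATED
                frontier.pop(i + 1)
                changed = True
                break

    rows: list[CEATableRow] = []
    prev: StrategyResult | None = None
    for r in order:
        if r.name in status:
            comparator = prev if prev is not None else order[0]
            rows.append(CEATableRow(
                strategy=r.name, cost=r.cost, qaly=r.qaly,
                inc_cost=r.cost - comparator.cost,
                inc_qaly=r.qaly - comparator.qaly,
                status=status[r.name]))
            continue
        if prev is None:
            rows.append(CEATableRow(strategy=r.name, cost=r.cost, qaly=r.qaly,
                                    inc_cost=None, inc_qaly=None,
                                    status=REFERENCE))
        else:
            d_cost = r.cost - prev.cost
            d_qaly = r.qaly - prev.qaly
            icer = d_cost / d_qaly
            rows.append(CEATableRow(strategy=r.name, cost=r.cost, qaly=r.qaly,
                                    inc_cost=d_cost, inc_qaly=d_qaly,
                                    status=f"{icer:.0f}", icer=icer))
        prev = r
    return rows


def table_to_frame(rows: list[CEATableRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "Strategy": r.strategy,
                "Cost": r.cost,
                "QALY": r.qaly,
                "IncCost": r.inc_cost,
                "IncQALY": r.inc_qaly,
                "Status": r.status,
            }
            for r in rows
        ]
    )


def _nmb_matrix(costs: np.ndarray, qalys: np.ndarray, wtp: float) -> np.ndarray:
    return qalys * wtp - costs


def ceac(costs: np.ndarray, qalys: np.ndarray, names: list[str],
         wtp_grid: list[float]) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve from PSA samples.

    ``costs`` and ``qalys`` are (iterations x strategies) arrays. At
    each threshold a strategy's probability is the fraction of
    iterations in which its net monetary benefit is maximal; exact ties
    split the iteration's probability equally.
    """
    costs = np.atleast_2d(np.asarray(costs, dtype=float))
    qalys = np.atleast_2d(np.asarray(qalys, dtype=float))
    if costs.size == 0 or costs.shape != qalys.shape:
        raise ValueError("costs and qalys must be equal-shape, non-empty")
    if costs.shape[1] != len(names):
        raise ValueError("one column per strategy required")
    points = []
    for wtp in wtp_grid:
        nmb_mat = _nmb_matrix(costs, qalys, wtp)
        best = nmb_mat.max(axis=1, keepdims=True)
        winners = nmb_mat == best
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        points.append(CEACPoint(wtp=float(wtp),
                                probabilities=dict(zip(names, probs.tolist()))))
    return points


def pairwise_ce_probability(costs: np.ndarray, qalys: np.ndarray,
                            names: list[str], strategy: str, comparator: str,
                            wtp: float) -> float:
    """P(``strategy`` beats ``comparator``) in NMB at one threshold.

    The head-to-head variant of the acceptability curve; ties count 1/2.
    """
    costs = np.atleast_2d(np.asarray(costs, dtype=float))
    qalys = np.atleast_2d(np.asarray(qalys, dtype=float))
    i, j = names.index(strategy), names.index(comparator)
    nmb_i = qalys[:, i] * wtp - costs[:, i]
    nmb_j = qalys[:, j] * wtp - costs[:, j]
    return float(np.mean((nmb_i > nmb_j) + 0.5 * (nmb_i == nmb_j)))


def ceac_to_frame(points: list[CEACPoint]) -> pd.DataFrame:
    names = list(points[0].probabilities)
    return pd.DataFrame(
        [{"wtp": p.wtp, **{n: p.probabilities[n] for n in names}}
         for p in points]
    )
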
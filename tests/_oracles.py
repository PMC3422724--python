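"""Independent reference computations used to validate the package.

Everything here is deliberately written from first principles — closed
forms, enumeration, or per-patient simulation — and shares no code with
the implementation under test.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def expected_state_utility(gu: float, gi: float, sd: float,
                           utilities: dict[str, float]) -> float:
    """Enumerate all eight toxicity combinations and average utilities."""
    total = 0.0
    for has_gu, has_gi, has_sd in product([0, 1], repeat=3):
        p = ((gu if has_gu else 1 - gu)
             * (gi if has_gi else 1 - gi)
             * (sd if has_sd else 1 - sd))
        channels = [ch for ch, flag in zip(("GU", "GI", "SD"),
                                           (has_gu, has_gi, has_sd)) if flag]
        state = "+".join(channels) if channels else "none"
        total += p * utilities[state]
    return total


def dersimonian_laird(thetas: np.ndarray, variances: np.ndarray,
                      ) -> tuple[float, float, float]:
    """Hand-coded DerSimonian-Laird pooling of (estimate, variance) pairs.

    Returns (pooled estimate, pooled variance, tau^2).
    """
    w = 1.0 / variances
    theta_fe = np.sum(w * thetas) / np.sum(w)
    q = np.sum(w * (thetas - theta_fe) ** 2)
    k = len(thetas)
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_re = 1.0 / (variances + tau2)
    theta_re = np.sum(w_re * thetas) / np.sum(w_re)
    return float(theta_re), float(1.0 / np.sum(w_re)), float(tau2)


def annualized_logodds(n: int, events: int, followup_months: float,
                       ) -> tuple[float, float]:
    """Study-level annualized log-odds and delta-method variance."""
    e, m = float(events), float(n)
    if events in (0, n):
        e, m = e + 0.5, m + 1.0
    p = e / m
    var_p = p * (1 - p) / m
    power = 12.0 / followup_months
    p_ann = 1.0 - (1.0 - p) ** power
    grad = power * (1.0 - p) ** (power - 1.0)
    var_ann = grad ** 2 * var_p
    theta = np.log(p_ann / (1.0 - p_ann))
    return float(theta), float(var_ann / (p_ann * (1.0 - p_ann)) ** 2)


def microsimulate(init_probs: np.ndarray, state_utils: np.ndarray,
                  cycle0_costs: np.ndarray, recurring_costs: np.ndarray,
                  qx: np.ndarray, bg: np.ndarray, discount_rate: float,
                  n_paths: int, rng: np.random.Generator,
                  ) -> tuple[float, float, float, float]:
    """Per-patient simulation of the absorbing-toxicity chain.

    Each simulated patient draws an entry state, then survives each
    annual cycle with probability ``1 - qx[c]`` (qx indexed by the age
    attained at the start of the year lived), accruing discounted
    utility and cost while alive. Returns (mean cost, mean QALY,
    SE cost, SE QALY) across paths.

    ``cycle0_costs`` / ``recurring_costs`` are per-state totals
    including monitoring; dead patients accrue nothing.
    """
    n_cycles = len(qx)
    n_states = len(init_probs)
    states = rng.choice(n_states, size=n_paths, p=init_probs)
    alive = states < n_states - 1  # death is the final state
    disc = (1.0 + discount_rate) ** -np.arange(n_cycles)

    qalys = np.zeros(n_paths)
    costs = np.zeros(n_paths)
    for c in range(n_cycles):
        if c > 0:
            survive = rng.random(n_paths) < 1.0 - qx[c - 1]
            alive &= survive
        qalys += alive * disc[c] * bg[c] * state_utils[states]
        per_state = cycle0_costs if c == 0 else recurring_costs
        costs += alive * disc[c] * per_state[states]
    return (float(costs.mean()), float(qalys.mean()),
            float(costs.std(ddof=1) / np.sqrt(n_paths)),
            float(qalys.std(ddof=1) / np.sqrt(n_paths)))


def frontier_by_enumeration(costs: np.ndarray, qalys: np.ndarray,
                            ) -> tuple[set[int], set[int]]:
    """Brute-force dominance classification for small strategy sets.

    Returns (strictly dominated indices, weakly dominated indices).
    A strategy is strictly dominated when some alternative is no more
    costly and at least as effective (strict in one coordinate). The
    frontier is the set of NMB-maximizers over all willingness-to-pay
    values: candidate thresholds are every pairwise ICER plus the
    endpoints; remaining non-frontier, non-dominated strategies are
    weakly dominated.
    """
    n = len(costs)
    strict: set[int] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            better = ((costs[j] < costs[i] and qalys[j] >= qalys[i])
                      or (costs[j] <= costs[i] and qalys[j] > qalys[i]))
            if better:
                strict.add(i)
                break

    candidates = [0.0, 1e12]
    for i in range(n):
        for j in range(i + 1, n):
            if qalys[i] != qalys[j]:
                w = (costs[i] - costs[j]) / (qalys[i] - qalys[j])
                if w > 0:
                    candidates.append(w)
    winners: set[int] = set()
    for w in candidates:
        nmb = qalys * w - costs
        best = np.max(nmb)
        tied = np.flatnonzero(nmb == best)
        # among NMB ties prefer the cheaper strategy
        winners.add(int(min(tied, key=lambda t: costs[t])))
    weak = set(range(n)) - winners - strict
    return strict, weak
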
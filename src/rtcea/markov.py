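"""Lifetime cohort Markov engine.

The cohort enters at ``start_age``, is distributed once across the eight
toxicity-combination states (joint probabilities are products of the
three marginal toxicity probabilities, i.e. channels are independent),
and thereafter each annual cycle either stays in its state or dies:
toxicity states are absorbing apart from the transition to death, which
applies the life-table probability uniformly to every alive state.

Rewards per cycle:

* QALYs: state utility x age-specific background utility x occupancy,
  discounted at ``(1 + r)^-c``; cycle 0 accrues a full year (no
  half-cycle correction — the convention that reproduces the published
  incremental QALYs).
* Costs: cycle 0 carries the one-time treatment cost, the societal
  work-time cost, first-year monitoring, the one-time GI package and a
  full year of recurring toxicity costs; later cycles carry monitoring
  and recurring toxicity costs for the alive states.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    COMBO_STATES,
    STATE_NAMES,
    Arm,
    BackgroundUtility,
    CostModel,
    LifeTable,
    ModelConfig,
    ParameterBundle,
    Treatment,
    ToxicityProfile,
    UtilitySet,
)

__all__ = [
    "HealthState",
    "N_STATES",
    "DEATH",
    "CohortTrace",
    "StrategyResult",
    "initial_distribution",
    "toxicity_utility_expectation",
    "cycle_utility",
    "cycle_cost",
    "run_cohort",
    "run_all",
]


class HealthState(Enum):
    """The nine model states: eight toxicity combinations plus death."""

    NONE = "none"
    GU = "GU"
    GI = "GI"
    SD = "SD"
    GU_GI = "GU+GI"
    GU_SD = "GU+SD"
    GI_SD = "GI+SD"
    GU_GI_SD = "GU+GI+SD"
    DEATH = "death"

    @property
    def index(self) -> int:
        return STATE_NAMES.index(self.value)

    @property
    def channels(self) -> frozenset[str]:
        """Toxicity channels present in this state."""
        if self.value in ("none", "death"):
            return frozenset()
        return frozenset(self.value.split("+"))

    @property
    def is_alive(self) -> bool:
        return self is not HealthState.DEATH


N_STATES = len(STATE_NAMES)
DEATH = N_STATES - 1

# (has_gu, has_gi, has_sd) per combination state, in STATE_NAMES order
_COMBO_FLAGS = np.array(
    [[ch in s.split("+") for ch in ("GU", "GI", "SD")] for s in COMBO_STATES],
    dtype=float,
)


@dataclass(frozen=True)
class StrategyResult:
    """Lifetime discounted totals for one strategy."""

    name: str
    cost: float
    qaly: float
    perspective: str


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted accruals."""

    ages: np.ndarray              # (C,)
    occupancy: np.ndarray         # (C, 9), rows sum to 1
    disc_cost: np.ndarray         # (C,)
    disc_qaly: np.ndarray         # (C,)

    @property
    def total_cost(self) -> float:
        return float(self.disc_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.disc_qaly.sum())

    def survival(self) -> np.ndarray:
        """Alive fraction per cycle."""
        return 1.0 - self.occupancy[:, DEATH]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATE_NAMES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(self.ages)))
        df["disc_cost"] = self.disc_cost
        df["disc_qaly"] = self.disc_qaly
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def initial_distribution(tox: ToxicityProfile,
                         treatment_mortality: float = 0.0) -> np.ndarray:
    """Occupancy vector at model entry.

    Joint toxicity-state probabilities multiply the three marginals
    (independent channels) and are scaled by survival of treatment
    itself; treatment mortality goes straight to the death state.
    """
    marg = np.array([tox.gu, tox.gi, tox.sd])
    p_combo = np.prod(np.where(_COMBO_FLAGS, marg, 1.0 - marg), axis=1)
    occ = np.empty(N_STATES)
    occ[:DEATH] = (1.0 - treatment_mortality) * p_combo
    occ[DEATH] = treatment_mortality
    return occ


def toxicity_utility_expectation(tox: ToxicityProfile,
                                 utilities: UtilitySet) -> float:
    """Expected state utility over the entry distribution (alive states)."""
    occ = initial_distribution(tox, 0.0)
    return float(occ @ utilities.as_vector())


def cycle_utility(state: HealthState, age: int, utilities: UtilitySet,
                  bg: BackgroundUtility) -> float:
    """Quality weight for one year in ``state`` at ``age``; death is 0."""
    if state is HealthState.DEATH:
        return 0.0
    return utilities.utility(state.value) * bg(age)


def _recurring_state_costs(costs: CostModel) -> np.ndarray:
    """Annual cost per state for every alive cycle (monitoring excluded)."""
    gu_annual = (costs.gu_visits_per_year * costs.office_visit
                 + costs.oxybutynin_days_per_year * costs.oxybutynin_daily
                 + costs.cystoscopies_per_year * costs.cystoscopy)
    sd_annual = costs.sildenafil_doses_per_year * costs.sildenafil_dose
    gi_package = (costs.gi_visits_onetime * costs.office_visit
                  + costs.gi_weighted_onetime)
    vec = np.zeros(N_STATES)
    vec[:DEATH] = _COMBO_FLAGS @ np.array([
        gu_annual,
        gi_package if costs.gi_cost_mode == "annual" else 0.0,
        sd_annual,
    ])
    return vec


def _onetime_state_costs(costs: CostModel) -> np.ndarray:
    """Cycle-0-only cost per state (the one-time GI package)."""
    vec = np.zeros(N_STATES)
    if costs.gi_cost_mode == "one_time":
        gi_package = (costs.gi_visits_onetime * costs.office_visit
                      + costs.gi_weighted_onetime)
        vec[:DEATH] = _COMBO_FLAGS[:, 1] * gi_package
    return vec


def _monitoring_cost(costs: CostModel, cycle: int) -> float:
    visits = (costs.monitoring_visits_year1 if cycle == 0
              else costs.monitoring_visits_later)
    return (visits * costs.monitoring_visit_cost
            + costs.psa_tests_per_year * costs.psa_test)


def cycle_cost(state: HealthState, cycle: int, treatment: Treatment,
               costs: CostModel, perspective: str = "payer") -> float:
    """Undiscounted cost accrued by one cohort member in ``state`` at ``cycle``.

    Dead members accrue nothing. Alive members accrue monitoring plus
    the recurring costs of their toxicity channels; cycle 0 additionally
    carries the treatment cost, the one-time GI package (in the default
    one-time GI costing) and, from the societal perspective, the value
    of work time lost to the treatment course.
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    if state is HealthState.DEATH:
        return 0.0
    i = state.index
    total = _monitoring_cost(costs, cycle) + _recurring_state_costs(costs)[i]
    if cycle == 0:
        total += treatment.treatment_cost + _onetime_state_costs(costs)[i]
        if perspective == "societal":
            total += treatment.work_hours_lost * costs.wage_per_hour
    return total


def _survival_curve(life_table: LifeTable, config: ModelConfig) -> np.ndarray:
    """S(c): fraction of the entry cohort alive at cycle c (before any
    treatment mortality), with S(0) = 1."""
    ages = np.arange(config.start_age, config.max_age + 1)
    q = np.array([life_table.q(a) for a in ages])
    surv = np.ones(ages.size)
    surv[1:] = np.cumprod(1.0 - q[:-1])
    return surv


def run_cohort(arm: Arm, bundle: ParameterBundle, life_table: LifeTable,
               bg: BackgroundUtility, config: ModelConfig | None = None,
               ) -> tuple[CohortTrace, StrategyResult]:
    """Propagate the cohort from ``start_age`` to ``max_age``.

    Because toxicity states are absorbing and background mortality is
    state-independent, occupancy at cycle c is the entry distribution
    with every alive state scaled by the survival curve S(c); the engine
    exploits this to propagate all cycles with vectorized operations.
    """
    config = config or bundle.config
    if not (life_table.covers(config.start_age, config.max_age)
            and bg.covers(config.start_age, config.max_age)):
        raise ValueError("life table / background utility do not cover "
                         f"ages [{config.start_age}, {config.max_age}]")

    n = config.n_cycles
    ages = np.arange(config.start_age, config.max_age + 1)
    disc = (1.0 + config.discount_rate) ** -np.arange(n)
    surv = _survival_curve(life_table, config)
    bgv = np.array([bg(a) for a in ages])

    occ0 = initial_distribution(arm.toxicity, arm.treatment.treatment_mortality)
    alive0 = occ0[:DEATH]

    occupancy = np.empty((n, N_STATES))
    occupancy[:, :DEATH] = surv[:, None] * alive0[None, :]
    occupancy[:, DEATH] = 1.0 - occupancy[:, :DEATH].sum(axis=1)

    u = bundle.utilities.as_vector()
    disc_qaly = disc * bgv * (occupancy @ u)

    costs = bundle.costs
    recur = _recurring_state_costs(costs)
    per_cycle_cost = occupancy @ recur
    alive_frac = occupancy[:, :DEATH].sum(axis=1)
    per_cycle_cost += alive_frac * _monitoring_cost(costs, 1)
    # cycle-0 extras on top of the recurring pattern
    per_cycle_cost[0] += alive_frac[0] * (_monitoring_cost(costs, 0)
                                          - _monitoring_cost(costs, 1))
    per_cycle_cost[0] += arm.treatment.treatment_cost
    per_cycle_cost[0] += occ0 @ _onetime_state_costs(costs)
    if config.perspective == "societal":
        per_cycle_cost[0] += (arm.treatment.work_hours_lost
                              * costs.wage_per_hour)
    disc_cost = disc * per_cycle_cost

    trace = CohortTrace(ages=ages, occupancy=occupancy,
                        disc_cost=disc_cost, disc_qaly=disc_qaly)
    result = StrategyResult(name=arm.name, cost=trace.total_cost,
                            qaly=trace.total_qaly,
                            perspective=config.perspective)
    return trace, result


def run_all(bundle: ParameterBundle, life_table: LifeTable,
            bg: BackgroundUtility, config: ModelConfig | None = None,
            ) -> list[StrategyResult]:
    """Run every strategy in the bundle; returns results in bundle order."""
    return [run_cohort(arm, bundle, life_table, bg, config)[1]
            for arm in bundle.arms]
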
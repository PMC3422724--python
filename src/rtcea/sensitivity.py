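"""Uncertainty analyses around the base case.

* One-way analysis: probabilities and utilities move to the ends of
  their 95% confidence intervals (clamped to [0, 1]); costs move to
  75% / 125% of the base value.
* Probabilistic sensitivity analysis: probabilities and utilities are
  drawn from method-of-moments beta distributions, costs from gamma
  distributions with SE fixed at 50% of the mean (shape 4); the proton
  arm's sexual-dysfunction draw is tied to the IMRT draw by default,
  mirroring the base-case assumption that the two rates are equal.
* Threshold scans: SBRT toxicity probabilities in chosen channels are
  scaled by a common multiplier until a criterion first holds (QALY
  ordering flips, or the comparator's ICER falls below a threshold).
* Scenarios: annual (rather than one-time) GI costing, and setting the
  proton arm's SD toxicity equal to SBRT's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from . import cea
from .markov import StrategyResult, run_all, run_cohort
from .parameters import (
    STATE_NAMES,
    TOX_CHANNELS,
    Arm,
    BackgroundUtility,
    CostModel,
    LifeTable,
    ModelConfig,
    ParameterBundle,
    UtilitySet,
)

__all__ = [
    "ParamSpec",
    "PSAResult",
    "default_param_specs",
    "one_way",
    "tornado",
    "beta_params",
    "gamma_params",
    "draw_parameters",
    "run_psa",
    "threshold_scan",
    "scenario_run",
]

logger = logging.getLogger(__name__)

#: Unit-cost fields of :class:`CostModel` sampled / varied as costs.
COST_FIELDS = (
    "urologist_visit",
    "office_visit",
    "psa_test",
    "oxybutynin_daily",
    "cystoscopy",
    "gi_weighted_onetime",
    "sildenafil_dose",
    "wage_per_hour",
)


@dataclass(frozen=True)
class ParamSpec:
    """A single parameter to vary: where it lives and how far it moves."""

    path: str            # e.g. "arm:SBRT:toxicity:GU", "utility:GU+GI",
    #                      "cost:treatment:SBRT", "cost:unit:cystoscopy"
    base: float
    low: float
    high: float
    distribution: Literal["beta", "gamma", "fixed"]
    se: float = 0.0

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.path}: require low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})")
        if self.se < 0:
            raise ValueError(f"{self.path}: negative SE")


# ---------------------------------------------------------------------------
# Parameter addressing
# ---------------------------------------------------------------------------


def _set_param(bundle: ParameterBundle, path: str, value: float) -> ParameterBundle:
    """Return a copy of ``bundle`` with one addressed parameter replaced."""
    parts = path.split(":")
    arms = list(bundle.arms)
    utilities = bundle.utilities
    costs = bundle.costs
    try:
        if parts[0] == "arm":
            _, name, section, *rest = parts
            idx = next(i for i, a in enumerate(arms) if a.name == name)
            arm = arms[idx]
            if section == "toxicity":
                (channel,) = rest
                tox = arm.toxicity.model_copy(
                    update={channel.lower(): value})
                arms[idx] = Arm(treatment=arm.treatment, toxicity=tox)
            elif section == "treatment_cost":
                treatment = arm.treatment.model_copy(
                    update={"treatment_cost": value})
                arms[idx] = Arm(treatment=treatment, toxicity=arm.toxicity)
            else:
                raise KeyError(section)
        elif parts[0] == "utility":
            (_, state) = parts
            if state not in STATE_NAMES:
                raise KeyError(state)
            values = dict(utilities.values)
            values[state] = value
            utilities = UtilitySet(values=values, se=dict(utilities.se))
        elif parts[0] == "cost":
            if parts[1] == "treatment":
                return _set_param(bundle, f"arm:{parts[2]}:treatment_cost", value)
            (_, _, fname) = parts
            if fname not in COST_FIELDS:
                raise KeyError(fname)
            costs = costs.model_copy(update={fname: value})
        else:
            raise KeyError(parts[0])
    except (StopIteration, KeyError, ValueError, IndexError) as exc:
        raise KeyError(f"unknown parameter path {path!r}") from exc
    return ParameterBundle(bundle.config, arms, utilities, costs)


def default_param_specs(bundle: ParameterBundle) -> list[ParamSpec]:
    """The standard one-way set: every toxicity, utility and cost input."""
    specs: list[ParamSpec] = []
    for arm in bundle.arms:
        for ch in TOX_CHANNELS:
            base, se = arm.toxicity.prob(ch), arm.toxicity.se(ch)
            specs.append(ParamSpec(
                path=f"arm:{arm.name}:toxicity:{ch}", base=base,
                low=max(0.0, base - 1.96 * se),
                high=min(1.0, base + 1.96 * se),
                distribution="beta", se=se))
        cost = arm.treatment.treatment_cost
        specs.append(ParamSpec(
            path=f"cost:treatment:{arm.name}", base=cost,
            low=0.75 * cost, high=1.25 * cost,
            distribution="gamma", se=0.5 * cost))
    for state in STATE_NAMES:
        if state in ("none", "death"):
            continue
        base, se = bundle.utilities.values[state], bundle.utilities.se[state]
        specs.append(ParamSpec(
            path=f"utility:{state}", base=base,
            low=max(0.0, base - 1.96 * se), high=min(1.0, base + 1.96 * se),
            distribution="beta", se=se))
    for fname in COST_FIELDS:
        base = getattr(bundle.costs, fname)
        specs.append(ParamSpec(
            path=f"cost:unit:{fname}", base=base,
            low=0.75 * base, high=1.25 * base,
            distribution="gamma", se=0.5 * base))
    return specs


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------


def one_way(spec: ParamSpec, bundle: ParameterBundle, life_table: LifeTable,
            bg: BackgroundUtility, config: ModelConfig | None = None,
            ) -> tuple[list[cea.CEATableRow], list[cea.CEATableRow]]:
    """CEA tables with one parameter at its low and at its high value."""
    tables = []
    for value in (spec.low, spec.high):
        varied = _set_param(bundle, spec.path, value)
        tables.append(cea.icer_table(run_all(varied, life_table, bg, config)))
    return tables[0], tables[1]


def tornado(bundle: ParameterBundle, life_table: LifeTable,
            bg: BackgroundUtility, config: ModelConfig | None = None,
            strategy: str = "SBRT", comparator: str = "IMRT",
            wtp: float = 50_000.0,
            specs: Iterable[ParamSpec] | None = None) -> "pd.DataFrame":
    """Incremental NMB of ``strategy`` vs ``comparator`` at each extreme."""
    import pandas as pd

    specs = list(specs) if specs is not None else default_param_specs(bundle)
    rows = []
    for spec in specs:
        extremes = []
        for value in (spec.low, spec.high):
            varied = _set_param(bundle, spec.path, value)
            results = {r.name: r for r in run_all(varied, life_table, bg, config)}
            extremes.append(cea.nmb(results[strategy], wtp)
                            - cea.nmb(results[comparator], wtp))
        rows.append({"parameter": spec.path, "low_value": spec.low,
                     "high_value": spec.high, "inmb_low": extremes[0],
                     "inmb_high": extremes[1]})
    df = pd.DataFrame(rows)
    df["spread"] = (df["inmb_high"] - df["inmb_low"]).abs()
    return df.sort_values("spread", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def beta_params(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shape parameters for a probability/utility.

    alpha = m * nu, beta = (1 - m) * nu with nu = m(1-m)/s^2 - 1.
    Raises when the variance is infeasible (s^2 >= m(1-m)).
    """
    var = se ** 2
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean {mean} outside (0, 1)")
    if var >= mean * (1.0 - mean):
        raise ValueError(f"variance {var} infeasible for mean {mean}")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_params(mean: float, se_fraction: float = 0.5) -> tuple[float, float]:
    """Gamma (shape, scale) with SE a fixed fraction of the mean.

    shape = 1/fraction^2 (= 4 at the default 50%), scale = mean/shape.
    """
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    shape = 1.0 / se_fraction ** 2
    return shape, mean / shape


def _draw_prob(rng: np.random.Generator, mean: float, se: float,
               label: str) -> float:
    """Beta draw, falling back to the fixed mean when SE is zero or the
    method-of-moments parameterization is infeasible."""
    if se == 0.0 or mean in (0.0, 1.0):
        return mean
    try:
        a, b = beta_params(mean, se)
    except ValueError:
        logger.warning("beta method-of-moments infeasible for %s "
                       "(mean=%g, se=%g); holding fixed", label, mean, se)
        return mean
    return float(rng.beta(a, b))


def _draw_cost(rng: np.random.Generator, mean: float,
               se_fraction: float = 0.5) -> float:
    if mean == 0.0 or se_fraction == 0.0:
        return mean
    shape, scale = gamma_params(mean, se_fraction)
    return float(rng.gamma(shape, scale))


def draw_parameters(bundle: ParameterBundle, rng: np.random.Generator,
                    tie_pt_sd_to_imrt: bool = True,
                    cost_se_fraction: float = 0.5) -> ParameterBundle:
    """One PSA draw of the full parameter bundle.

    Toxicity probabilities and state utilities are beta draws; unit and
    treatment costs are gamma draws with SE = 50% of the mean.
    Utilization counts, treatment mortality (0) and zero-SE utilities
    stay fixed. When ``tie_pt_sd_to_imrt`` the PT arm reuses the IMRT
    sexual-dysfunction draw instead of drawing its own.

    Draws are taken in a fixed documented order (arms in bundle order,
    channel order GU/GI/SD, then utilities in state order, then costs),
    so results are bitwise reproducible for a given generator state.
    """
    arms: list[Arm] = []
    sd_draws: dict[str, float] = {}
    for arm in bundle.arms:
        tox = arm.toxicity
        update: dict[str, float] = {}
        for ch in TOX_CHANNELS:
            label = f"{arm.name}.{ch}"
            if (ch == "SD" and tie_pt_sd_to_imrt and arm.name == "PT"
                    and "IMRT" in sd_draws):
                update["sd"] = sd_draws["IMRT"]
                continue
            value = _draw_prob(rng, tox.prob(ch), tox.se(ch), label)
            update[ch.lower()] = value
            if ch == "SD":
                sd_draws[arm.name] = value
        arms.append(Arm(treatment=arm.treatment,
                        toxicity=tox.model_copy(update=update)))

    values = dict(bundle.utilities.values)
    for state in STATE_NAMES:
        se = bundle.utilities.se[state]
        if se > 0.0:
            values[state] = _draw_prob(rng, values[state], se,
                                       f"utility.{state}")
    utilities = UtilitySet(values=values, se=dict(bundle.utilities.se))

    cost_update = {f: _draw_cost(rng, getattr(bundle.costs, f),
                          cost_se_fraction)
                   for f in COST_FIELDS}
    costs = bundle.costs.model_copy(update=cost_update)
    arms = [Arm(treatment=a.treatment.model_copy(
                    update={"treatment_cost":
                            _draw_cost(rng, a.treatment.treatment_cost,
                                       cost_se_fraction)}),
                toxicity=a.toxicity) for a in arms]
    return ParameterBundle(bundle.config, arms, utilities, costs)


@dataclass
class PSAResult:
    """Monte-Carlo samples and derived acceptability summaries."""

    names: list[str]
    costs: np.ndarray            # (n_iter, n_strategies)
    qalys: np.ndarray            # (n_iter, n_strategies)
    seed: int
    perspective: str
    wtp_thresholds: tuple[float, ...]
    ceac_points: list[cea.CEACPoint] = field(default_factory=list)

    @property
    def n_iter(self) -> int:
        return self.costs.shape[0]

    def pairwise_probability(self, strategy: str, comparator: str,
                             wtp: float) -> float:
        return cea.pairwise_ce_probability(self.costs, self.qalys, self.names,
                                           strategy, comparator, wtp)


def run_psa(bundle: ParameterBundle, life_table: LifeTable,
            bg: BackgroundUtility, config: ModelConfig | None = None,
            n_iter: int = 10_000, seed: int = 0,
            tie_pt_sd_to_imrt: bool = True,
            wtp_grid: Iterable[float] | None = None) -> PSAResult:
    """Propagate parameter uncertainty through the full cohort model.

    Every iteration redraws the bundle and reruns each strategy's
    lifetime cohort; deterministic given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    config = config or bundle.config
    rng = np.random.default_rng(seed)
    names = [arm.name for arm in bundle.arms]
    costs = np.empty((n_iter, len(names)))
    qalys = np.empty((n_iter, len(names)))
    for i in range(n_iter):
        sampled = draw_parameters(bundle, rng, tie_pt_sd_to_imrt)
        for j, arm in enumerate(sampled.arms):
            _, res = run_cohort(arm, sampled, life_table, bg, config)
            costs[i, j] = res.cost
            qalys[i, j] = res.qaly
    grid = (list(wtp_grid) if wtp_grid is not None
            else list(np.arange(0.0, 200_001.0, 10_000.0)))
    points = cea.ceac(costs, qalys, names, grid)
    return PSAResult(names=names, costs=costs, qalys=qalys, seed=seed,
                     perspective=config.perspective,
                     wtp_thresholds=tuple(config.wtp_thresholds),
                     ceac_points=points)


# ---------------------------------------------------------------------------
# Threshold scans
# ---------------------------------------------------------------------------


def _scale_toxicity(bundle: ParameterBundle, strategy: str,
                    channels: Iterable[str], multiplier: float,
                    ) -> ParameterBundle:
    scaled = bundle
    arm = bundle.arm(strategy)
    for ch in channels:
        value = min(1.0, arm.toxicity.prob(ch) * multiplier)
        scaled = _set_param(scaled, f"arm:{strategy}:toxicity:{ch}", value)
    return scaled


def threshold_scan(bundle: ParameterBundle, life_table: LifeTable,
                   bg: BackgroundUtility, config: ModelConfig | None = None,
                   strategy: str = "SBRT", comparator: str = "IMRT",
                   channels: Iterable[str] = TOX_CHANNELS,
                   criterion: Literal["qaly_flip", "icer_below"] = "qaly_flip",
                   wtp: float = 100_000.0, max_multiplier: float = 3.0,
                   step: float = 0.01) -> float | None:
    """Smallest toxicity multiplier at which ``criterion`` first holds.

    The named channels of ``strategy`` are scaled by a common multiplier
    on a 1% grid (probabilities clamped at 1). ``qaly_flip``: the scaled
    strategy yields fewer QALYs than ``comparator``. ``icer_below``: the
    comparator gains QALYs over the scaled strategy at an incremental
    cost per QALY at or below ``wtp``. Returns None if never met.
    """
    channels = list(channels)
    config = config or bundle.config
    n_steps = int(round((max_multiplier - 1.0) / step))
    for k in range(n_steps + 1):
        m = 1.0 + k * step
        scaled = _scale_toxicity(bundle, strategy, channels, m)
        results = {r.name: r for r in run_all(scaled, life_table, bg, config)}
        s, c = results[strategy], results[comparator]
        if criterion == "qaly_flip":
            if s.qaly < c.qaly:
                return round(m, 10)
        elif criterion == "icer_below":
            if c.qaly > s.qaly and (c.cost - s.cost) / (c.qaly - s.qaly) <= wtp:
                return round(m, 10)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    return None


# ---------------------------------------------------------------------------
# Alternative scenarios
# ---------------------------------------------------------------------------


def scenario_bundle(name: Literal["gi_annual_cost", "pt_sd_equals_sbrt"],
                    bundle: ParameterBundle) -> ParameterBundle:
    """The parameter bundle under a named alternative scenario."""
    if name == "gi_annual_cost":
        costs = bundle.costs.model_copy(update={"gi_cost_mode": "annual"})
        return ParameterBundle(bundle.config, list(bundle.arms),
                               bundle.utilities, costs)
    if name == "pt_sd_equals_sbrt":
        sbrt = bundle.arm("SBRT").toxicity
        arms = []
        for arm in bundle.arms:
            if arm.name == "PT":
                tox = arm.toxicity.model_copy(
                    update={"sd": sbrt.sd, "sd_se": sbrt.sd_se})
                arm = Arm(treatment=arm.treatment, toxicity=tox)
            arms.append(arm)
        return ParameterBundle(bundle.config, arms, bundle.utilities,
                               bundle.costs)
    raise ValueError(f"unknown scenario {name!r}")


def scenario_run(name: Literal["gi_annual_cost", "pt_sd_equals_sbrt"],
                 bundle: ParameterBundle, life_table: LifeTable,
                 bg: BackgroundUtility,
                 ) -> dict[str, list[cea.CEATableRow]]:
    """Re-run the base case under a scenario, from both perspectives."""
    scen = scenario_bundle(name, bundle)
    tables = {}
    for perspective in ("payer", "societal"):
        config = scen.config.model_copy(update={"perspective": perspective})
        tables[perspective] = cea.icer_table(
            run_all(scen, life_table, bg, config))
    return tables
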
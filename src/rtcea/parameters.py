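"""Validated model inputs and configuration I/O.

All monetary values are 2011 US dollars. The bundled defaults are the
base case of the decision model: three external-beam radiotherapy
strategies (SBRT, IMRT, proton therapy) for a cohort of 65-year-old men
with localized prostate cancer, three long-term toxicity channels
(genitourinary, gastrointestinal, sexual dysfunction), per-state
utilities, and unit costs / utilization counts for treatment,
routine monitoring, and toxicity management.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "TOX_CHANNELS",
    "COMBO_STATES",
    "STATE_NAMES",
    "ConfigError",
    "Treatment",
    "ToxicityProfile",
    "Arm",
    "UtilitySet",
    "CostModel",
    "ModelConfig",
    "LifeTable",
    "BackgroundUtility",
    "ParameterBundle",
    "default_parameters",
    "load_config",
    "save_config",
    "export_parameters_csv",
]

#: The three long-term toxicity channels.
TOX_CHANNELS: tuple[str, ...] = ("GU", "GI", "SD")

#: The eight toxicity-combination health states, in canonical order.
COMBO_STATES: tuple[str, ...] = (
    "none",
    "GU",
    "GI",
    "SD",
    "GU+GI",
    "GU+SD",
    "GI+SD",
    "GU+GI+SD",
)

#: All nine model states (combination states plus death).
STATE_NAMES: tuple[str, ...] = COMBO_STATES + ("death",)


class ConfigError(ValueError):
    """Raised when a configuration file cannot be read or validated."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class Treatment(BaseModel, frozen=True):
    """One radiotherapy strategy: one-time cost, patient time, mortality."""

    name: str
    treatment_cost: float = Field(ge=0)
    work_hours_lost: float = Field(ge=0)
    treatment_mortality: float = Field(ge=0, le=1, default=0.0)


class ToxicityProfile(BaseModel, frozen=True):
    """Annual probability (with SE) of each long-term toxicity channel.

    Probabilities are the chance of developing the toxicity within the
    first year after treatment; SEs parameterize beta distributions in
    the probabilistic sensitivity analysis. ``prob +/- 1.96*se`` may fall
    outside [0, 1]; sampling and one-way analyses clamp downstream.
    """

    gu: float = Field(ge=0, le=1)
    gu_se: float = Field(ge=0)
    gi: float = Field(ge=0, le=1)
    gi_se: float = Field(ge=0)
    sd: float = Field(ge=0, le=1)
    sd_se: float = Field(ge=0)

    def prob(self, channel: str) -> float:
        return getattr(self, channel.lower())

    def se(self, channel: str) -> float:
        return getattr(self, channel.lower() + "_se")


class Arm(BaseModel, frozen=True):
    """A treatment together with its toxicity profile."""

    treatment: Treatment
    toxicity: ToxicityProfile

    @property
    def name(self) -> str:
        return self.treatment.name


class UtilitySet(BaseModel, frozen=True):
    """Preference weights for the nine health states.

    ``values[state]`` is the utility (1 = perfect health, 0 = death) and
    ``se[state]`` its standard error. Keys must cover :data:`STATE_NAMES`.
    """

    values: dict[str, float]
    se: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "UtilitySet":
        for key in STATE_NAMES:
            if key not in self.values or key not in self.se:
                raise ValueError(f"utility set missing state {key!r}")
        for key, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"utility[{key}]={v} outside [0, 1]")
        for key, s in self.se.items():
            if s < 0:
                raise ValueError(f"utility se[{key}]={s} negative")
        return self

    def utility(self, state: str) -> float:
        return self.values[state]

    def as_vector(self) -> np.ndarray:
        """Utilities in :data:`STATE_NAMES` order."""
        return np.array([self.values[s] for s in STATE_NAMES])


class CostModel(BaseModel, frozen=True):
    """Unit costs, utilization counts and costing conventions.

    GI toxicity is costed once at model entry by default
    (``gi_cost_mode='one_time'``) because its symptoms are the least
    likely to be chronic; GU and SD management costs recur annually.
    ``monitoring_visit_rate`` selects which listed visit fee routine
    monitoring uses; the default is the office rate, which is the
    assignment consistent with the base-case totals (see docs/methods.md).
    """

    # unit costs, 2011 USD
    urologist_visit: float = Field(ge=0, default=177.0)
    office_visit: float = Field(ge=0, default=102.0)
    psa_test: float = Field(ge=0, default=103.0)
    oxybutynin_daily: float = Field(ge=0, default=1.0)
    cystoscopy: float = Field(ge=0, default=214.0)
    gi_weighted_onetime: float = Field(ge=0, default=259.0)
    sildenafil_dose: float = Field(ge=0, default=12.0)
    # utilization counts
    monitoring_visits_year1: float = Field(ge=0, default=2.0)
    monitoring_visits_later: float = Field(ge=0, default=1.0)
    psa_tests_per_year: float = Field(ge=0, default=2.0)
    gu_visits_per_year: float = Field(ge=0, default=2.0)
    oxybutynin_days_per_year: float = Field(ge=0, default=365.0)
    cystoscopies_per_year: float = Field(ge=0, default=1.0)
    gi_visits_onetime: float = Field(ge=0, default=2.0)
    sildenafil_doses_per_year: float = Field(ge=0, default=22.0)
    # societal perspective
    wage_per_hour: float = Field(ge=0, default=22.45)
    # conventions
    gi_cost_mode: Literal["one_time", "annual"] = "one_time"
    monitoring_visit_rate: Literal["office", "urologist"] = "office"

    @property
    def monitoring_visit_cost(self) -> float:
        if self.monitoring_visit_rate == "office":
            return self.office_visit
        return self.urologist_visit


class ModelConfig(BaseModel, frozen=True):
    """Cohort and analysis settings."""

    start_age: int = 65
    max_age: int = 100
    cycle_length: Literal[1] = 1  # years; the model is annual
    discount_rate: float = 0.03
    perspective: Literal["payer", "societal"] = "payer"
    wtp_thresholds: tuple[float, ...] = (50_000.0, 100_000.0)

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError(f"discount_rate={self.discount_rate} outside [0, 1)")
        if self.start_age >= self.max_age:
            raise ValueError("start_age must be below max_age")
        if any(w < 0 for w in self.wtp_thresholds):
            raise ValueError("willingness-to-pay thresholds must be >= 0")
        return self

    @property
    def n_cycles(self) -> int:
        """Number of annual cycles, including cycle 0."""
        return self.max_age - self.start_age + 1


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability q(age) for the modeled cohort."""

    ages: np.ndarray
    qx: np.ndarray
    _index: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.shape != qx.shape or ages.ndim != 1:
            raise ValueError("ages and qx must be 1-D arrays of equal length")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be consecutive integers")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        object.__setattr__(self, "_index", {int(a): i for i, a in enumerate(ages)})

    def q(self, age: int) -> float:
        try:
            return float(self.qx[self._index[int(age)]])
        except KeyError:
            raise ValueError(f"age {age} outside life table range "
                             f"[{self.ages[0]}, {self.ages[-1]}]") from None

    def covers(self, start_age: int, max_age: int) -> bool:
        return self.ages[0] <= start_age and self.ages[-1] >= max_age

    def to_csv(self, path: str | Path, header: str | None = None) -> None:
        _frame_to_csv(pd.DataFrame({"age": self.ages, "qx": self.qx}), path, header)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        return cls(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())


@dataclass(frozen=True)
class BackgroundUtility:
    """Age-specific utility norm for general-population males.

    Applied multiplicatively to every toxicity-state utility, so the
    quality weight of an alive cohort member at age ``a`` in state ``s``
    is ``utility(s) * bg(a)``.
    """

    ages: np.ndarray
    values: np.ndarray
    _index: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if ages.shape != values.shape or ages.ndim != 1:
            raise ValueError("ages and values must be 1-D arrays of equal length")
        if np.any((values < 0) | (values > 1)):
            raise ValueError("background utilities must lie in [0, 1]")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be consecutive integers")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "_index", {int(a): i for i, a in enumerate(ages)})

    def __call__(self, age: int) -> float:
        try:
            return float(self.values[self._index[int(age)]])
        except KeyError:
            raise ValueError(f"age {age} outside background-utility range "
                             f"[{self.ages[0]}, {self.ages[-1]}]") from None

    def covers(self, start_age: int, max_age: int) -> bool:
        return self.ages[0] <= start_age and self.ages[-1] >= max_age

    def to_csv(self, path: str | Path, header: str | None = None) -> None:
        _frame_to_csv(pd.DataFrame({"age": self.ages, "utility": self.values}),
                      path, header)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BackgroundUtility":
        df = pd.read_csv(path, comment="#")
        return cls(ages=df["age"].to_numpy(), values=df["utility"].to_numpy())


def _frame_to_csv(df: pd.DataFrame, path: str | Path, header: str | None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.strip().splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


class ParameterBundle(NamedTuple):
    """Everything the cohort engine needs apart from the life tables."""

    config: ModelConfig
    arms: list[Arm]
    utilities: UtilitySet
    costs: CostModel

    def arm(self, name: str) -> Arm:
        for arm in self.arms:
            if arm.name == name:
                return arm
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Bundled base-case values
# ---------------------------------------------------------------------------

_DEFAULT_ARMS = (
    # name, treatment cost, work hours lost, (gu, se), (gi, se), (sd, se)
    ("SBRT", 20_889.0, 10.0, (0.040, 0.023), (0.027, 0.010), (0.159, 0.088)),
    ("IMRT", 28_805.0, 90.0, (0.035, 0.016), (0.013, 0.008), (0.272, 0.232)),
    # PT sexual-dysfunction toxicity is assumed equal to IMRT's (no
    # long-term PT SD data; both deliver small doses over ~40 fractions).
    ("PT", 65_250.0, 100.0, (0.019, 0.004), (0.015, 0.006), (0.272, 0.232)),
)

_DEFAULT_UTILITIES = {
    "none": (1.00, 0.00),
    "GU": (0.83, 0.02),
    "GI": (0.71, 0.02),
    "SD": (0.89, 0.01),
    "GU+GI": (0.70, 0.04),
    "GU+SD": (0.79, 0.03),
    "GI+SD": (0.57, 0.04),
    "GU+GI+SD": (0.45, 0.04),
    "death": (0.00, 0.00),
}


def default_parameters() -> ParameterBundle:
    """The bundled base case: strategies, toxicities, utilities, costs."""
    arms = [
        Arm(
            treatment=Treatment(name=name, treatment_cost=cost,
                                work_hours_lost=hours, treatment_mortality=0.0),
            toxicity=ToxicityProfile(gu=gu[0], gu_se=gu[1], gi=gi[0], gi_se=gi[1],
                                     sd=sd[0], sd_se=sd[1]),
        )
        for name, cost, hours, gu, gi, sd in _DEFAULT_ARMS
    ]
    utilities = UtilitySet(
        values={k: v for k, (v, _) in _DEFAULT_UTILITIES.items()},
        se={k: s for k, (_, s) in _DEFAULT_UTILITIES.items()},
    )
    return ParameterBundle(ModelConfig(), arms, utilities, CostModel())


# ---------------------------------------------------------------------------
# Configuration file I/O
# ---------------------------------------------------------------------------


def bundle_to_dict(bundle: ParameterBundle) -> dict:
    """Plain-dict form of a bundle, suitable for YAML/JSON serialization."""
    return {
        "model": bundle.config.model_dump(mode="json"),
        "arms": [
            {
                **arm.treatment.model_dump(mode="json"),
                "toxicity": arm.toxicity.model_dump(mode="json"),
            }
            for arm in bundle.arms
        ],
        "utilities": {
            state: {"value": bundle.utilities.values[state],
                    "se": bundle.utilities.se[state]}
            for state in STATE_NAMES
        },
        "costs": bundle.costs.model_dump(mode="json"),
    }


def _bundle_from_dict(raw: dict, source: str) -> ParameterBundle:
    defaults = default_parameters()
    try:
        config = ModelConfig(**{**defaults.config.model_dump(), **raw.get("model", {})})
        costs = CostModel(**{**defaults.costs.model_dump(), **raw.get("costs", {})})
        if "arms" in raw:
            arms = []
            for spec in raw["arms"]:
                spec = dict(spec)
                tox = spec.pop("toxicity")
                arms.append(Arm(treatment=Treatment(**spec),
                                toxicity=ToxicityProfile(**tox)))
        else:
            arms = defaults.arms
        if "utilities" in raw:
            utilities = UtilitySet(
                values={k: v["value"] for k, v in raw["utilities"].items()},
                se={k: v["se"] for k, v in raw["utilities"].items()},
            )
        else:
            utilities = defaults.utilities
    except (ValueError, KeyError, TypeError) as exc:
        raise ConfigError(f"invalid configuration in {source}: {exc}") from exc
    return ParameterBundle(config, arms, utilities, costs)


def load_config(path: str | Path) -> ParameterBundle:
    """Load and validate a YAML (or JSON) parameter file.

    Missing sections fall back to the bundled base-case defaults; any
    invariant violation raises :class:`ConfigError` naming the offending
    field.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"configuration file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse configuration file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration file {path} must contain a mapping")
    return _bundle_from_dict(raw, str(path))


def save_config(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a bundle as a YAML file that :func:`load_config` round-trips."""
    Path(path).write_text(yaml.safe_dump(bundle_to_dict(bundle), sort_keys=False))


def export_parameters_csv(bundle: ParameterBundle, path: str | Path) -> pd.DataFrame:
    """One row per model parameter: name, value, SE, PSA distribution."""
    rows: list[tuple[str, float, float, str]] = []
    for arm in bundle.arms:
        t = arm.treatment
        rows.append((f"{t.name}.treatment_cost", t.treatment_cost,
                     0.5 * t.treatment_cost, "gamma"))
        rows.append((f"{t.name}.work_hours_lost", t.work_hours_lost, 0.0, "fixed"))
        rows.append((f"{t.name}.treatment_mortality", t.treatment_mortality,
                     0.0, "fixed"))
        for ch in TOX_CHANNELS:
            rows.append((f"{t.name}.toxicity.{ch}", arm.toxicity.prob(ch),
                         arm.toxicity.se(ch), "beta"))
    for state in STATE_NAMES:
        se = bundle.utilities.se[state]
        rows.append((f"utility.{state}", bundle.utilities.values[state], se,
                     "beta" if se > 0 else "fixed"))
    for name in ("urologist_visit", "office_visit", "psa_test", "oxybutynin_daily",
                 "cystoscopy", "gi_weighted_onetime", "sildenafil_dose",
                 "wage_per_hour"):
        value = getattr(bundle.costs, name)
        rows.append((f"cost.{name}", value, 0.5 * value, "gamma"))
    for name in ("monitoring_visits_year1", "monitoring_visits_later",
                 "psa_tests_per_year", "gu_visits_per_year",
                 "oxybutynin_days_per_year", "cystoscopies_per_year",
                 "gi_visits_onetime", "sildenafil_doses_per_year"):
        rows.append((f"utilization.{name}", getattr(bundle.costs, name),
                     0.0, "fixed"))
    df = pd.DataFrame(rows, columns=["parameter", "value", "se", "distribution"])
    df.to_csv(path, index=False)
    return df
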
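"""Random-effects pooling of study-level toxicity incidence.

Long-term toxicity inputs to the cohort model are annual probabilities
pooled across single-arm studies with differing follow-up. Each study's
cumulative incidence is first converted to an annual probability under a
constant-hazard assumption, then mapped to the log-odds scale with a
delta-method variance, pooled with a DerSimonian-Laird random-effects
model, and transformed back to the probability scale. Studies are
annualized *before* pooling so that every study contributes an estimate
on a common one-year time basis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit
from statsmodels.stats.meta_analysis import combine_effects

__all__ = [
    "StudyRecord",
    "PooledEstimate",
    "annualize",
    "pool_random_effects",
    "read_studies_csv",
]


class StudyRecord(BaseModel, frozen=True):
    """One study's toxicity table: patients, events, follow-up."""

    study_id: str
    n: int = Field(gt=0)
    events: int = Field(ge=0)
    followup_months: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "StudyRecord":
        if self.events > self.n:
            raise ValueError(f"events ({self.events}) exceed n ({self.n})")
        return self


class PooledEstimate(BaseModel, frozen=True):
    """Pooled annual toxicity probability with uncertainty summaries.

    ``se`` is on the probability scale (delta method from the log-odds
    pooled SE); ``tau2`` and ``i2`` describe between-study heterogeneity
    on the log-odds scale.
    """

    annual_prob: float = Field(ge=0, le=1)
    se: float = Field(ge=0)
    tau2: float = Field(ge=0)
    i2: float = Field(ge=0, le=1, default=0.0)
    k: int = Field(ge=1)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval computed on the log-odds scale."""
        from scipy.stats import norm

        if self.annual_prob in (0.0, 1.0) or self.se == 0.0:
            return (self.annual_prob, self.annual_prob)
        theta = logit(self.annual_prob)
        se_theta = self.se / (self.annual_prob * (1.0 - self.annual_prob))
        z = norm.ppf(0.5 + level / 2.0)
        return (float(expit(theta - z * se_theta)),
                float(expit(theta + z * se_theta)))


def annualize(p_cum: float, followup_months: float) -> float:
    """Convert cumulative incidence over a follow-up to an annual probability.

    Assumes a constant hazard: ``1 - (1 - p_cum)**(12 / followup_months)``.
    """
    if not 0.0 <= p_cum < 1.0:
        raise ValueError(f"cumulative probability {p_cum} outside [0, 1)")
    if followup_months <= 0:
        raise ValueError("followup_months must be positive")
    return 1.0 - (1.0 - p_cum) ** (12.0 / followup_months)


def _study_logodds(record: StudyRecord) -> tuple[float, float]:
    """Annualized log-odds and delta-method variance for one study.

    A continuity correction of 0.5 is added to events and non-events
    when the event count sits on the boundary {0, n}.
    """
    e, n = float(record.events), float(record.n)
    if record.events in (0, record.n):
        e += 0.5
        n += 1.0
    p_hat = e / n
    var_p = p_hat * (1.0 - p_hat) / n
    p_ann = annualize(p_hat, record.followup_months)
    grad = (12.0 / record.followup_months) * (1.0 - p_hat) ** (
        12.0 / record.followup_months - 1.0)
    var_ann = grad ** 2 * var_p
    theta = float(logit(p_ann))
    var_theta = var_ann / (p_ann * (1.0 - p_ann)) ** 2
    return theta, var_theta


def pool_random_effects(studies: list[StudyRecord]) -> PooledEstimate:
    """DerSimonian-Laird pooled annual probability across studies.

    Each study is annualized, mapped to log-odds with a delta-method
    variance, and pooled with inverse-variance weights that include the
    DL between-study variance tau^2. A single study passes through with
    tau^2 = 0. Zero-event (or all-event) studies are valid thanks to the
    continuity correction.
    """
    if not studies:
        raise ValueError("cannot pool an empty study list")
    # canonical ordering makes the result invariant to input permutation
    studies = sorted(studies, key=lambda s: (s.study_id, s.n, s.events,
                                             s.followup_months))
    thetas, variances = zip(*(_study_logodds(s) for s in studies))
    thetas = np.array(thetas)
    variances = np.array(variances)
    k = len(studies)
    if k == 1:
        theta, var = float(thetas[0]), float(variances[0])
        tau2, i2 = 0.0, 0.0
    else:
        # errstate: statsmodels' untruncated tau2 / I2 side computations
        with np.errstate(invalid="ignore", divide="ignore"):
            res = combine_effects(thetas, variances, method_re="dl")
        if res.tau2 > 0.0:
            theta = float(res.mean_effect_re)
            var = float(res.sd_eff_w_re) ** 2
            tau2 = float(res.tau2)
        else:
            # truncated DL: tau2 clipped at 0 collapses to the
            # fixed-effect inverse-variance combination
            theta = float(res.mean_effect_fe)
            var = float(res.sd_eff_w_fe) ** 2
            tau2 = 0.0
        i2 = float(np.clip(res.i2, 0.0, 1.0))
    p = float(expit(theta))
    se_p = float(np.sqrt(var)) * p * (1.0 - p)
    return PooledEstimate(annual_prob=p, se=se_p, tau2=max(tau2, 0.0),
                          i2=i2, k=k)


def read_studies_csv(path: str | Path) -> list[StudyRecord]:
    """Read a study table with columns study_id,n,events,followup_months."""
    df = pd.read_csv(path, comment="#")
    required = {"study_id", "n", "events", "followup_months"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"study table {path} missing columns {sorted(missing)}")
    return [
        StudyRecord(study_id=str(row.study_id), n=int(row.n),
                    events=int(row.events),
                    followup_months=float(row.followup_months))
        for row in df.itertuples()
    ]
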
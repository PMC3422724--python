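# rtcea

Cost-effectiveness modeling of modern external-beam radiotherapy for
localized prostate cancer.

For 65-year-old men with localized prostate cancer, stereotactic body
radiation therapy (SBRT), intensity-modulated radiation therapy (IMRT)
and proton beam therapy (PT) achieve comparable disease control but
differ sharply in price, time burden and long-term toxicity. `rtcea`
is a decision-analytic package for quantifying that trade-off: it
computes lifetime discounted costs (2011 USD) and quality-adjusted
life years (QALYs) per strategy, incremental cost-effectiveness ratios
(ICERs) with dominance classification, and the full apparatus of
uncertainty analysis used in health technology assessment. It is aimed
at health economists and methods researchers who want a transparent,
scriptable, fully tested implementation rather than a spreadsheet.

## The model

A lifetime Markov cohort model with nine states: the eight
combinations of three long-term toxicity channels — genitourinary
(GU), gastrointestinal (GI), sexual dysfunction (SD) — plus death.
Toxicity is assigned once at model entry with joint probability
∏ p(channel) (independent channels); afterwards each annual cycle a
member stays put or dies with the life-table probability q(age).
Per-strategy value accrues as

    QALYs = Σ_c (1+r)^−c Σ_s occ_c(s) · u(s) · bg(age_c)
    Cost  = treatment cost + Σ_c (1+r)^−c [monitoring + toxicity costs]_c

with r = 3 %, state utilities u(s) from published preference weights,
and bg(age) an age-specific background-utility norm. GU and SD
toxicity costs recur annually; GI toxicity is a one-time cost. The
societal perspective adds the value of patient time in treatment (10 /
90 / 100 hours at $22.45/h). Annual toxicity probabilities come from a
DerSimonian–Laird random-effects meta-analysis of study-level
incidence on the log-odds scale, annualized under a constant hazard.
Two unpublished inputs (cohort mortality, background-utility norm) are
replaced by calibrated synthetic stand-ins; see `docs/methods.md`.

## Worked example

```bash
rtcea base --out results
```

prints the base-case cost-effectiveness tables and writes them as CSV:

```
payer:
  SBRT  cost=     24895 qaly=8.110 status=reference
  IMRT  cost=     33069 qaly=8.048 status=dominated
  PT    cost=     69387 qaly=8.063 status=dominated
societal:
  SBRT  cost=     25120 qaly=8.110 status=reference
  IMRT  cost=     35090 qaly=8.048 status=dominated
  PT    cost=     71632 qaly=8.063 status=dominated
```

SBRT is the cheapest strategy *and* yields the most QALYs — both
comparators are dominated (costlier, fewer QALYs), so no ICER is
defined for them. The QALY gaps (−0.062 vs IMRT, −0.047 vs PT) come
from SBRT's lower toxicity burden, chiefly sexual dysfunction (0.159
vs 0.272 annually).

The same things are available as a library:

```python
from rtcea import default_parameters, default_tables, run_all, icer_table

bundle = default_parameters()          # strategies, utilities, costs
life, bg = default_tables()            # calibrated synthetic tables
for row in icer_table(run_all(bundle, life, bg)):
    print(row.strategy, round(row.cost), round(row.qaly, 3), row.status)
```

Meta-analysis of study-level toxicity tables:

```python
from rtcea import pool_random_effects, simulate_toxicity_studies

studies = simulate_toxicity_studies(0.04, 4, 150,
                                    [17.0, 24.0, 33.0, 35.5], seed=5)
est = pool_random_effects(studies)
print(round(est.annual_prob, 4), [round(x, 4) for x in est.ci()])
# 0.0435 [0.0337, 0.0559]
```

Other subcommands: `rtcea psa` (probabilistic sensitivity analysis and
acceptability curves), `rtcea oneway` (tornado tables), `rtcea
threshold` (toxicity multiplier scans), `rtcea scenario` (annual GI
costing; PT SD set equal to SBRT), `rtcea pool` (meta-analysis of a
study CSV), `rtcea synth` (regenerate the synthetic tables), and
`rtcea full` for the whole pipeline with a manifest. All accept
`--config` (YAML overrides of any parameter) and the stochastic stages
accept `--seed`.

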
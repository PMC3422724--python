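# Methods

## Model structure

`rtcea` implements a lifetime cohort Markov model comparing three
external-beam radiotherapy strategies for localized prostate cancer in
65-year-old US men: stereotactic body radiation therapy (SBRT, ≤5
fractions), intensity-modulated radiation therapy (IMRT, ~40 fractions)
and proton beam therapy (PT, ~40 fractions). Disease control is assumed
equivalent across strategies, so the model contains no recurrence or
progression states; strategies differ only in their one-time treatment
cost, patient time in treatment, and long-term (≥ grade 2 RTOG, ≥12
months) toxicity profile over three channels: genitourinary (GU),
gastrointestinal (GI) and sexual dysfunction (SD).

The state space is the eight combinations of the three toxicity
channels plus death. Toxicity is assigned once, at model entry: the
joint state probabilities are the products of the three marginal annual
toxicity probabilities (channels independent — only marginals are
reported anywhere, so independence is the natural maximum-entropy
choice). Thereafter each annual cycle a cohort member either stays in
their state or dies; the life-table death probability applies uniformly
to every alive state. Because the toxicity states are absorbing, the
occupancy at cycle *c* is the entry distribution scaled by the survival
curve S(c), and the engine propagates all cycles with vectorized
operations; a per-patient microsimulation oracle in the test suite
confirms the trace (1 000 000 paths, agreement within 3 Monte-Carlo
SEs).

Cycle length is one year, horizon age 100 with forced death at the
terminal age, and no half-cycle correction: cycle 0 carries the
treatment cost, the toxicity assignment, the one-time GI cost and a
full undiscounted year of utility, monitoring and toxicity accruals.
This Excel-style convention is what reproduces the published
incremental QALYs; a half-cycle-corrected variant would scale every
total by a factor the published numbers do not support.

## Rewards

**QALYs.** Each alive cycle contributes
`u(state) × bg(age) × (1+r)^-c`, with state utilities from the
published utility table (no toxicity 1.00, GU 0.83, GI 0.71, SD 0.89,
GU&GI 0.70, GU&SD 0.79, GI&SD 0.57, all three 0.45, death 0) and
`bg(age)` an age-specific background-utility norm for US males. The
discount rate r is 3 % per year for both costs and QALYs.

Because utilities are constant in time and mortality is
state-independent, total QALYs factor exactly as `E[u] × D`, where
`E[u]` is the toxicity-utility expectation under the entry distribution
(0.968338 / 0.960971 / 0.962771 for SBRT / IMRT / PT) and
`D = Σ_c (1+r)^-c S(c) bg(age_c)` is a strategy-independent discounted
quality-weight factor. This factorization is asserted in the tests and
is the key to calibrating the synthetic tables (below).

**Costs** (2011 USD). Every alive cycle accrues routine monitoring
(2 visits + 2 PSA tests in year 1, then 1 visit + 2 PSA tests) and the
recurring costs of the member's toxicity channels: GU = 2 office visits
+ 365 days oxybutynin + 1 cystoscopy per year; SD = 22 sildenafil doses
× $12 per year. GI toxicity is costed once at entry (2 office visits +
a $259 weighted enema/colonoscopy package) because GI symptoms are the
least likely to be chronic; an `annual` GI costing mode is available as
a scenario. Cycle 0 additionally carries the treatment cost ($20,889 /
$28,805 / $65,250) and, from the societal perspective, lost work time
(10 / 90 / 100 hours) valued at a wage rate. Treatment-related
mortality is zero for all three strategies.

Two costing details are under-determined by the published tables and
were resolved by arithmetic consistency with the published totals:

* **Monitoring visit rate.** The cost table lists both a urologist
  visit ($177) and an office visit ($102) without saying which applies
  to routine monitoring. Writing each strategy's lifetime cost as
  `constant + slope × L`, with `L = Σ_c (1+r)^-c S(c)` the discounted
  person-year factor, the three published payer totals imply
  L ≈ 10.15–10.27 under office-rate monitoring (mutually consistent
  across all three strategies and both perspectives) but L ≈ 8.32 under
  urologist-rate monitoring — impossible alongside D ≈ 8.375, since
  D ≤ L × max(bg) and bg ≤ 0.9. Monitoring therefore defaults to the
  office rate; `CostModel.monitoring_visit_rate` switches it.
* **Wage rate.** The cost table prints a rounded $20/hour, but the
  societal-minus-payer gaps ($224 / $2,020 / $2,245 over 10 / 90 / 100
  hours) imply $22.40–$22.45; the default is 22.45, with the printed
  $20 available through configuration.

Even so, the implied discounted-time factor differs slightly between
the IMRT (≈11.0) and PT (≈13.7) incremental-cost comparisons in the
source results, so the original cost composition cannot be recovered
exactly; absolute and incremental costs are reproduced to within about
0.15 %.

## Synthetic stand-in tables

Two inputs of the original analysis were never published: the
SEER-derived all-cause mortality of the cohort and the age-specific
background-utility norm. `synthetic_data` supplies documented
stand-ins:

* **Life table**: Gompertz hazard `a·e^{b(age-65)}` with b = 0.09 and
  a = 0.03476, giving q(65) ≈ 0.034 and an undiscounted life
  expectancy of ≈12.7 years; q(100) is forced to 1.
* **Background utility**: piecewise constant by decade — 0.83 (65–74),
  0.80 (75–84), 0.77 (85–94), 0.75 (95+) — inside the plausible US
  male EQ-5D norm range.

The pair is calibrated jointly so that D = 8.37517, the value the
published results pin down (total SBRT QALYs 8.11 divided by
E[u] = 0.968338). D and L are the only aggregates of these tables the
cohort results depend on, so hitting D (with the bg levels fixed at the
values above, which place L ≈ 10.21) reproduces the published QALY and
cost levels simultaneously. `calibrate_baseline_hazard()` re-derives
the frozen `a` and is checked in the tests. The stand-ins are *not*
SEER data: passing tests show internal consistency with the published
aggregate results, not agreement with any unpublished mortality cell.
The study simulator (`simulate_toxicity_studies`) draws binomial event
counts from a constant-hazard cumulative incidence and emulates the
sample-size/follow-up structure of the source studies; it does not
model between-study heterogeneity unless given heterogeneous inputs.

## Meta-analysis of toxicity

Study-level cumulative incidences are annualized under a constant
hazard (`1 − (1−p)^{12/f}` for follow-up f months), mapped to log-odds
with delta-method variances (continuity correction 0.5 when the event
count is 0 or n), pooled by DerSimonian–Laird random effects
(tau² truncated at zero, where the estimator collapses to the
fixed-effect combination), and back-transformed. Annualization happens
*before* pooling so every study contributes on a common one-year
basis. The DL estimator was chosen as the standard non-iterative
random-effects method; REML/Paule–Mandel are out of scope. The pooling
arithmetic is delegated to `statsmodels.stats.meta_analysis`; an
independently hand-coded DL oracle in the tests cross-checks it. The
bundled default toxicity probabilities are the published pooled values
(the underlying event counts live in the source studies and are not
re-pooled here).

## Uncertainty analyses

* **One-way**: probabilities and utilities move to base ± 1.96 SE
  (clamped to [0,1]); costs to 75 % / 125 % of base. Cost variations
  never change the dominance picture. Toxicity confidence intervals,
  however, are wide enough to flip the QALY ordering — the upper SBRT
  SD bound (+108 %) exceeds the +43 % flip point found by the threshold
  scan, and the comparator SD lower bounds clamp to 0 — so no blanket
  "results unchanged" claim is made for toxicity parameters.
* **PSA**: probabilities and utilities are drawn from method-of-moments
  betas (α = m·ν, β = (1−m)·ν, ν = m(1−m)/s² − 1; infeasible variances
  fall back to the fixed value with a logged warning); every cost is
  drawn from a gamma with SE = 50 % of the mean (shape 4, scale
  mean/4). All draws are independent; PT's SD draw is tied to IMRT's by
  default (they are assumed equal), with an independent-draw switch.
  Zero-SE utilities (none, death), utilization counts and treatment
  mortality stay fixed. Draw order is fixed, so a seed reproduces
  results bitwise. The default iteration count is 10,000.
* **Threshold scans**: SBRT toxicity probabilities in chosen channels
  are scaled by a common multiplier on a 1 % grid (probabilities
  clamped at 1) until the QALY ordering flips against a comparator or
  the comparator's ICER falls below a willingness-to-pay threshold;
  the grid mirrors the integer-percent resolution of the reported
  thresholds. SBRT QALYs are strictly decreasing and costs strictly
  increasing in the multiplier, so the first grid hit is the
  threshold.
* **Scenarios**: `gi_annual_cost` applies the GI package every alive
  year; `pt_sd_equals_sbrt` sets PT's SD probability and SE to SBRT's.

## Decision rules

Strategies are ranked by cost; a strategy is dominated when a cheaper
(or equally costly) one yields at least as many QALYs, and weakly
(extendedly) dominated when removing it restores an increasing ICER
sequence along the frontier; survivors get ICERs versus the previous
frontier member. A brute-force enumeration oracle (NMB argmax over all
pairwise-ICER breakpoints) validates the classification on 1,000 random
instances. Acceptability curves report, at each willingness-to-pay
value, the fraction of PSA iterations in which a strategy's net
monetary benefit is maximal (ties split equally); head-to-head
probabilities use the pairwise variant, matching how the source
reports them. In the `pt_sd_equals_sbrt` scenario the recomputed PT
ICER is ≈ $780,000/QALY; the source prints $13,755,207 against its own
incremental values of $44,221 and 0.057 QALYs (which divide to
≈ $776,000), so the printed ICER is documented as internally
inconsistent and is not a reproduction target. In the same scenario the
classification here is *strict* dominance of IMRT (it costs more and
yields fewer QALYs than SBRT), where the source labels it "weakly
dominated"; the strategy is off the frontier either way.

## Known limitations

* The PSA probability of SBRT being cost-effective versus IMRT at
  $50,000/QALY comes out near 69 % (payer) under the sampling scheme
  above, versus the reported 75.1 %. The variance of the incremental
  NMB is dominated by the IMRT SD toxicity SE (0.232) and the gamma
  treatment-cost draws (SE = 50 % of $28,805 and $20,889); no variant
  consistent with the stated distributions reproduces 75.1 % while
  also keeping the versus-PT probabilities near their reported 94.1 %
  and 95.5 % (holding treatment costs fixed, for example, yields 84 %
  and 100 %). The original iteration count and sampling machinery are
  unreported.
* Toxicity channels are modeled as independent; real GU/GI/SD
  toxicities are likely positively correlated, which would slightly
  lower the no-toxicity occupancy.
* Toxicity never resolves (no data on time to resolution), which is
  conservative against the lower-toxicity strategy.
* The life table and background-utility table are calibrated
  stand-ins; absolute cost and QALY levels inherit their calibration,
  while incremental QALYs, dominance and threshold multipliers follow
  from published inputs alone.

## Problem sizes

Default analyses use the full 36-cycle horizon (ages 65–100). The test
suite validates with a 1,000,000-path microsimulation, 1,000 random
frontier instances, a 2,000-replicate coverage experiment for the
meta-analysis (six studies of 300 patients each), and 10,000-iteration
PSAs; the whole suite runs in well under a minute.
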
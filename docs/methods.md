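# Methods

## Scope and structure

`uroflow` simulates the urgent suspected-urological-cancer referral pathway
from GP presentation to diagnosis (or exit without diagnosis) under three
management arms: standard care, risk-test prioritization, and risk-test
triage-and-prioritization. Two pathway models are kept separate — prostate,
and bladder/kidney — because their diagnostic cascades and volumes differ;
both share the same queueing and economic machinery. The model ends at
diagnosis: staging, treatment and post-diagnosis outcomes are out of scope,
except for the exploratory life-year decrements described below.

## Time and horizon

The clock is integer days. The base horizon is the 365-day calendar year
December 2021 – November 2022 (month lengths 31, 31, 28, 31, 30, 31, 30,
31, 31, 30, 31, 30). Simulation continues past the horizon until the last
referral event plus a 90-day run-out tail, so that late arrivals — and
false negatives re-referred 183 days after presentation — can resolve
rather than being mechanically censored. Queues start empty: no initial
backlog is modelled, a documented simplification.

## Synthetic referral stream

Arrivals are Poisson per calendar month, with monthly means
`annual_referrals × monthly_weights[m]`, uniform within the month. This is
the maximum-entropy reading of data reported as monthly totals. Each
patient then receives:

* `has_cancer ~ Bernoulli(0.169)` — the base-case prevalence of confirmed
  urological cancer among urgent referrals;
* a pathway/subtype: P(prostate pathway) = 0.7591; within the
  bladder/kidney pathway, P(bladder) = 0.5979 (the suspected subtype is
  assigned to all referrals, cancer or not, mirroring how referral volumes
  are reported);
* an age band, from a per-subtype categorical distribution. The default is
  three bands (`<60`, `60-79`, `80+`) with uniform probabilities — an
  explicit placeholder, since registry-derived per-band proportions are
  site data the user should supply;
* a risk category from a conditional table over (high, medium, low) given
  cancer status. The cancer row default is (0.87, 0.10, 0.03): the
  rule-out threshold of the test is tuned for ~97 % sensitivity, so the
  anchored quantity is P(low | cancer) = 0.03. The non-cancer row default
  (0.05, 0.70, 0.25) is synthetic; its load-bearing feature is the ~25 %
  rule-out rate among non-cancers, which sets how much urgent-pathway
  capacity triage releases (≈ 21 % of all referrals at base-case
  prevalence).

Risk category is conditionally independent of age band given cancer
status, and is drawn for every patient in every replication so that all
arms can replay identical randomness; standard care simply ignores it.

## Queueing mechanism

Secondary-care capacity is expressed as appointment slots per period
(daily by default; fractional daily rates are spread exactly by an
accumulator, so `from_rate(r, n)` delivers `floor(r·k)` slots over any
first `k` days). The pending queue is served each day in
(priority-class rank, referral day, patient id) order — high before medium
before low, ties broken first-come-first-served, so the standard-care arm
(a single "unclassified" class) is plain FIFO.

Capacity is interpreted as the providers' throughput of patients seen
*within the 14-day window* ("window" mechanism, the default). An entry
that can no longer be reached within 14 days of referral leaves the
within-window track without consuming a slot: it breaches the target and
is seen at 14 days plus an excess delay drawn from an empirical
distribution supported on 1–16 days (default: geometrically decaying
weights ∝ 0.8^(k−1), a synthetic stand-in for observed additional-wait
distributions; configurable per scenario). Two consequences make this the
right mechanism for the question at hand:

* reordering the queue redistributes the *same* timely slots, so
  prioritization barely changes overall compliance while concentrating
  timely appointments on high-risk patients;
* every referral resolves within 30 days of its referral date, so a
  priority discipline cannot starve low-priority patients indefinitely.

A pure "backlog" mechanism (entries wait for a slot indefinitely;
unbounded waits, censoring at the tail end) is retained as an option for
studying waiting-list dynamics, but it is not the default: under heavy
load it lets the low-risk class starve, which contradicts the bounded
additional-wait behaviour observed in practice.

The TWW boundary is inclusive: a 14-day wait complies, 15 days breaches
(`tww_window_days` is configurable).

### Capacity calibration

Scenarios specify either an explicit capacity rate/schedule or a target
standard-care compliance fraction (e.g. 0.70 or 0.90). In the latter case
the daily slot rate is found by bisection on the simulated FIFO compliance
fraction over three calibration cohorts drawn with a fixed internal seed
(20211201): capacity stands in for observed provider throughput, so it is
a property of the scenario and deliberately does not vary with the
analysis seed, nor across PSA draws.

## Management arms

* **standard** — everyone urgently referred on their arrival day,
  unclassified priority.
* **prioritize** — everyone referred; queue class = risk category.
* **triage_and_prioritize** — low-risk patients are not urgently referred.
  Low-risk non-cancers (true negatives) exit with no further cost, benefit
  or harm — an explicit simplification; if many would in reality be
  referred non-urgently, cost savings are overstated. Low-risk cancers
  (false negatives) remain symptomatic, make two additional GP visits
  (evenly spaced over the delay) and are re-referred 183 days (six months)
  after presentation, re-entering the urgent queue as high priority — a
  clinically conservative choice, configurable.

## Diagnostic cascades and costs

Every prostate-pathway patient accrues a GP consultation and a PSA test;
every bladder/kidney patient a GP consultation; test arms add the
risk-prediction test for every presenting patient. Referred-and-seen
prostate patients accrue the triage appointment and mpMRI; mpMRI-positive
patients a TRUS biopsy; biopsy-positive patients an MDT review. Positivity
is conditional on cancer status with defaults
P(mpMRI+ | cancer) = P(biopsy+ | cancer) = 1 (every confirmed cancer must
traverse the full cascade for an MDT diagnosis to occur),
P(mpMRI+ | no cancer) = 0.35 and P(biopsy+ | no cancer) = 0, all
configurable. Referred-and-seen bladder/kidney patients accrue cystoscopy,
ultrasound, X-ray and MDT review, unconditionally.

Unit costs are carried as integer pennies (exact to £0.01) and multiplied
by a single inflation factor to the 2022 price year. The shipped table
(GP £39, PSA £5, risk test £35.20, triage appointment £170, mpMRI £250,
TRUS biopsy £450, MDT £110, cystoscopy £390, ultrasound £55, X-ray £30) is
synthetic — order-of-magnitude NHS-like placeholders to be replaced by
tariff data via CSV. Costs are not discounted over the one-year horizon.
Integer-penny arithmetic makes the structural identity "prioritization
costs exactly one risk test more per patient than standard care when the
referral sets coincide" exact rather than float-approximate.

## Life years and net monetary benefit

A cancer patient seen more than 28 days after referral incurs the
2-month-delay decrement to 10-year survival for their subtype and age
band; a missed (false-negative) cancer incurs the 6-month decrement.
4-month cells are carried in the table although the base-case model never
triggers them. The shipped decrement table is synthetic: 6-month baselines
of 0.010 / 0.200 / 0.120 life years for prostate / bladder / kidney,
scaled by delay (2 months × 0.25, 4 months × 0.55, 6 months × 1.0) and age
band (younger bands lose more). The ordering — bladder and kidney losses
far exceeding prostate — reflects the faster stage progression of those
cancers; the magnitudes are placeholders for user-supplied estimates, and
downstream life-year results should be treated as exploratory.

Decrements are discounted at 3.5 %/year. How a 10-year survival decrement
distributes over the decade is genuinely open; the default spreads it
uniformly over years 1–10 (discount factor = mean of the ten annual
factors ≈ 0.852), with a lump-sum alternative at a configurable year
(e.g. all-at-year-10 gives 1.035⁻¹⁰ ≈ 0.709). Neither is asserted as the
historically correct choice; both are one switch apart.

With quality of life assumed unaffected by diagnostic delay, QALYs equal
life years and, per replication pair,
`INMB = WTP × (LY_lost(standard) − LY_lost(test)) − (Cost(test) − Cost(standard))`
at WTP = £20,000/QALY. Intervals are 2.5/97.5 percentiles over
replications (or PSA draws).

## Replication design and randomness

Each replication draws its cohort, cascade uniforms and excess delays from
`numpy` Philox/PCG substreams keyed by (master seed, stream id, scenario,
replication). All arms of a replication share those draws (common random
numbers), so within-replication arm differences are pure policy effects —
this is what makes the per-replication orderings (prioritization never
lowers cancer compliance; triage never lowers overall compliance below
prioritization) assertable on every replication rather than only in
expectation. Seeds are derived order-independently, so results do not
depend on which arms or scenarios are evaluated, or in what order.

The deterministic analysis uses 650 replications per scenario; the PSA
uses 1,200 parameter draws with one stochastic replication per draw by
default (first- and second-order uncertainty mixed; `inner_reps` averages
out first-order noise within draws when separation is wanted). PSA
families are beta for single probabilities, Dirichlet for the risk-matrix
rows (moment-matched on the largest component; structural zeros stay
zero), and gamma for costs and decrements, all moment-matched to the
deterministic values with a default coefficient of variation of 0.1.
Decrement cells are perturbed by one gamma multiplier per
(subtype, age band) group so the monotone-in-delay structure of the table
is preserved. PSA replication substreams coincide with the deterministic
ones, so a zero-variance PSA reuses the same stochastic replications and
parameter uncertainty is the only systematic difference between the
analyses.

## Default scenario grid

Four scenarios: each model under (high volume, poor performance) and
(low volume, high performance). Annual volumes are provider-scale —
prostate 7,200/2,400, bladder/kidney 6,000/2,000 — and standard-care
compliance targets are 0.70 (poor) and 0.90 (high, near the 93 %
operational standard). Volumes at the lower end were sized so that
replication-level binomial noise (a handful of breaching patients per
replication, ~3 % of cancers in the low-risk class) cannot mask the
priority-discipline orderings at 650 replications; with compliance
targets much above ~0.95 those orderings hold only in expectation, not
replication-by-replication, because single low-risk cancer patients
dominate the comparison.

## Numerical and degenerate-input choices

* Probability vectors must sum to 1 within 1e-9; negative or non-finite
  parameters raise `ConfigurationError` naming the offending field.
* Empty cohorts yield zero costs and NaN compliance fractions rather than
  errors; a single replication yields degenerate intervals with a warning.
* Ties in the queue are broken by (referral day, patient id) — fully
  deterministic.
* A capacity schedule that does not span the horizon plus tail raises a
  configuration error rather than silently truncating.
* The vectorised replication path is audited against an independent
  patient-level routing path (timelines and penny ledgers) in the test
  suite; the fast heap-based queue is audited against a brute-force
  full-re-sort scheduler and a hand-traced 20-patient fixture.

## What the synthetic generator does and does not emulate

It reproduces the *statistical structure* the models assume: monthly
arrival volumes, prevalence and subtype mix, risk-classification rates,
bounded excess delays, and capacity consistent with a stated compliance
level. It does not emulate: real per-provider waiting-time distributions
or seasonality beyond monthly weights; correlation between risk category
and age or subtype; referral-volume trends across years; non-urgent
pathways for ruled-out patients; or authentic tariffs and survival
decrements. Passing tests therefore demonstrate that the mechanisms are
implemented correctly and that qualitative conclusions (who gains timely
appointments, the sign of cost differences, the source of life-year
losses) follow from the stated assumptions — not that the absolute
figures match any particular provider's experience.

## Problem sizes used in checks

The packaged checks pool ≥ 50,000 synthetic patients (10 independent
streams) for parameter recovery, run the full default grid at 650
replications for the arm-ordering properties, and 1,200 zero-variance PSA
draws for the degeneracy comparison — sizes chosen to give the pooled
estimators standard errors several times smaller than the tolerances they
are checked against.

## Known limitations

* No initial waiting-list backlog; the first weeks of the horizon are
  unrealistically empty under heavy load.
* Single-stage secondary-care capacity per model — no separate queues per
  diagnostic test, no staff rostering.
* True negatives exit at zero downstream cost; any real non-urgent
  referral activity would erode the triage arm's savings.
* Life-year outputs rest on synthetic decrement magnitudes and an assumed
  accrual/discounting pattern; treat them as exploratory.
* Breaching patients' delayed appointments are assumed not to compete
  with within-window capacity; if providers in fact serve them from the
  same clinics, compliance under triage would improve slightly less.
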
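"""One full model replication: cohort -> queue -> costs -> life years.

Randomness is organised for common random numbers (CRN): each replication
draws its cohort, diagnostic-cascade uniforms and excess-delay samples once,
from substreams keyed by (master seed, stream id, scenario, replication),
and every management arm is evaluated on those identical draws.  Arm
differences within a replication are therefore pure policy effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .cohort import Cohort, Patient, generate_cohort
from .economics import CostTable, DecrementTable, EconParams, discount_factor
from .engine import PRIORITY_RANK, sample_excess_delay, simulate_queue
from .pathways import (
    ArmPolicy,
    CascadeProbs,
    route_bladder_kidney,
    route_prostate,
)
from .scenarios import Grid, Scenario, required_schedule_days

__all__ = [
    "SharedDraws",
    "ArmFlow",
    "ReplicationResult",
    "make_shared_draws",
    "arm_flow",
    "simulate_arm",
    "run_replication",
    "replication_patients",
]

# Substream identifiers (stable across releases; part of the seed contract).
_STREAM_COHORT = 1
_STREAM_CASCADE = 2
_STREAM_EXCESS = 3

_DELAY_INDEX = {0: 0, 2: 1, 4: 2, 6: 3}


def _substream(master_seed: int, stream: int, scenario_key: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, stream, scenario_key, rep])
    )


@dataclass
class SharedDraws:
    """Per-replication randomness shared across arms (CRN)."""

    cohort: Cohort
    u_mpmri: np.ndarray
    u_biopsy: np.ndarray
    excess_days: np.ndarray


def make_shared_draws(scenario: Scenario, rep: int, master_seed: int) -> SharedDraws:
    rng = _substream(master_seed, _STREAM_COHORT, scenario.key, rep)
    cohort = generate_cohort(scenario.cohort, scenario.model, scenario.horizon_days, rng)
    n = len(cohort)
    rng_cascade = _substream(master_seed, _STREAM_CASCADE, scenario.key, rep)
    u_mpmri = rng_cascade.random(n)
    u_biopsy = rng_cascade.random(n)
    rng_excess = _substream(master_seed, _STREAM_EXCESS, scenario.key, rep)
    excess = sample_excess_delay(scenario.excess, rng_excess, size=n)
    return SharedDraws(cohort, u_mpmri, u_biopsy, np.asarray(excess, dtype=np.int64))


@dataclass
class ReplicationResult:
    """Aggregates of one replication of one scenario under one arm."""

    scenario: str
    model: str
    arm: str
    rep: int
    n_patients: int
    n_referred: int
    n_ruled_out: int
    n_missed: int
    n_censored: int
    tww_overall: float
    tww_cancer: float
    tww_noncancer: float
    mean_wait: float
    cost_pence: int
    ly_lost: float

    @property
    def cost_gbp(self) -> float:
        return self.cost_pence / 100.0

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["cost_gbp"] = self.cost_gbp
        return d


def _arm_masks(
    cohort: Cohort, policy: ArmPolicy
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised referral decisions: (referred, fn, referral_day, rank)."""
    n = len(cohort)
    arrival = cohort.arrival_day.astype(np.int64)
    if policy.arm == "standard":
        referred = np.ones(n, dtype=bool)
        fn = np.zeros(n, dtype=bool)
        ref_day = arrival.copy()
        rank = np.full(n, PRIORITY_RANK["unclassified"], dtype=np.int64)
        return referred, fn, ref_day, rank
    if (cohort.risk < 0).any():
        raise AssertionError(f"risk category missing in {policy.arm} arm")
    rank = cohort.risk.astype(np.int64)  # risk codes coincide with class ranks
    if policy.arm == "prioritize":
        referred = np.ones(n, dtype=bool)
        fn = np.zeros(n, dtype=bool)
        ref_day = arrival.copy()
        return referred, fn, ref_day, rank
    low = cohort.risk == 2
    fn = low & cohort.has_cancer
    referred = ~low | fn
    ref_day = np.where(fn, arrival + policy.fn_delay_days, arrival)
    rank = np.where(fn, PRIORITY_RANK[policy.fn_re_referral_class], rank)
    return referred, fn, ref_day, rank


@dataclass
class ArmFlow:
    """Per-patient flow of one arm on one replication's shared draws."""

    referred: np.ndarray
    fn: np.ndarray  # missed cancers (false negatives of the triage rule-out)
    ref_day: np.ndarray
    rank: np.ndarray
    service: np.ndarray  # within-window service day, -1 otherwise
    in_window: np.ndarray
    seen: np.ndarray
    final_wait: np.ndarray
    met: np.ndarray


def arm_flow(scenario: Scenario, policy: ArmPolicy, shared: SharedDraws) -> ArmFlow:
    """Run the queue for one arm and derive per-patient waits and outcomes."""
    cohort = shared.cohort
    n = len(cohort)
    schedule = scenario.schedule()
    end_day = required_schedule_days(scenario.horizon_days) - 1
    window = scenario.tww_window_days

    referred, fn, ref_day, rank = _arm_masks(cohort, policy)
    service = np.full(n, -1, dtype=np.int64)
    idx = np.flatnonzero(referred)
    queue_window = window if scenario.mechanism == "window" else None
    if len(idx):
        service[idx] = simulate_queue(
            ref_day[idx], rank[idx], schedule, end_day=end_day, ids=idx, window=queue_window
        )
    in_window = service >= 0
    if scenario.mechanism == "window":
        # breaching patients are still seen, after an empirical excess delay
        seen = referred
        final_wait = np.where(in_window, service - ref_day, window + shared.excess_days)
    else:
        seen = in_window
        final_wait = np.where(seen, service - ref_day, -1)
    met = seen & in_window & (final_wait <= window)
    return ArmFlow(referred, fn, ref_day, rank, service, in_window, seen, final_wait, met)


def simulate_arm(
    scenario: Scenario,
    policy: ArmPolicy,
    shared: SharedDraws,
    costs: CostTable,
    decrements: DecrementTable,
    econ: EconParams,
    rep: int = 0,
) -> ReplicationResult:
    """Evaluate one arm on one replication's shared draws."""
    cohort = shared.cohort
    n = len(cohort)
    window = scenario.tww_window_days
    flow = arm_flow(scenario, policy, shared)
    referred, fn, ref_day = flow.referred, flow.fn, flow.ref_day
    seen, final_wait, met = flow.seen, flow.final_wait, flow.met

    # exits must partition the cohort
    n_ruled_out = int((~referred).sum())
    n_censored = int((referred & ~seen).sum())
    if int(seen.sum()) + n_ruled_out + n_censored != n:
        raise AssertionError("patient exits do not reconcile with cohort size")

    cancer = cohort.has_cancer
    with np.errstate(invalid="ignore"):
        tww_overall = float(met[referred].mean()) if referred.any() else float("nan")
        tww_cancer = (
            float((met & (ref_day == cohort.arrival_day))[cancer].mean())
            if cancer.any()
            else float("nan")
        )
        nc_ref = referred & ~cancer
        tww_noncancer = float(met[nc_ref].mean()) if nc_ref.any() else float("nan")
        mean_wait = float(final_wait[seen].mean()) if seen.any() else float("nan")

    # life years lost: missed or censored cancers carry the 6-month
    # decrement, seen cancers waiting > 28 days the 2-month one
    delay_idx = np.zeros(n, dtype=np.int64)
    delay_idx[seen & cancer & (final_wait > 28)] = _DELAY_INDEX[2]
    delay_idx[cancer & (fn | (referred & ~seen))] = _DELAY_INDEX[6]
    table = decrements.as_array(cohort.age_bands)
    ly = table[cohort.subtype, cohort.age_band, delay_idx]
    ly_lost = float(ly[cancer].sum() * discount_factor(econ))

    cost = _arm_costs(cohort, policy, scenario.cascade, shared, costs, seen, fn)

    return ReplicationResult(
        scenario=scenario.label,
        model=scenario.model,
        arm=policy.arm,
        rep=rep,
        n_patients=n,
        n_referred=int(referred.sum()),
        n_ruled_out=n_ruled_out,
        n_missed=int(fn.sum()),
        n_censored=n_censored,
        tww_overall=tww_overall,
        tww_cancer=tww_cancer,
        tww_noncancer=tww_noncancer,
        mean_wait=mean_wait,
        cost_pence=int(cost.sum()),
        ly_lost=ly_lost,
    )


def _arm_costs(
    cohort: Cohort,
    policy: ArmPolicy,
    cascade: CascadeProbs,
    shared: SharedDraws,
    costs: CostTable,
    served: np.ndarray,
    fn: np.ndarray,
) -> np.ndarray:
    """Per-patient cost in pennies (integer)."""
    c = costs.pence_map()
    n = len(cohort)
    cancer = cohort.has_cancer
    prostate = cohort.subtype == 0
    total = np.zeros(n, dtype=np.int64)
    total += c["gp-consult"]
    total[prostate] += c["psa-test"]
    if policy.uses_risk_test:
        total += c["pinpoint-test"]
    total[fn] += policy.fn_extra_gp_visits * c["gp-consult"]

    sp = served & prostate
    total[sp] += c["triage-appt"] + c["mpmri"]
    p_mri = np.where(cancer, cascade.mpmri_pos_cancer, cascade.mpmri_pos_nocancer)
    mri_pos = sp & (shared.u_mpmri < p_mri)
    total[mri_pos] += c["trus-biopsy"]
    p_bio = np.where(cancer, cascade.biopsy_pos_cancer, cascade.biopsy_pos_nocancer)
    bio_pos = mri_pos & (shared.u_biopsy < p_bio)
    total[bio_pos] += c["mdt"]

    sb = served & ~prostate
    total[sb] += c["cystoscopy"] + c["ultrasound"] + c["x-ray"] + c["mdt"]
    return total


def run_replication(
    scenario: Scenario,
    arm: str,
    rep: int,
    master_seed: int,
    grid: Grid | None = None,
) -> ReplicationResult:
    """Simulate one full-year replication of one arm.

    The same (scenario, rep, master_seed) triple always yields identical
    shared draws regardless of which arms are evaluated, so results across
    arms at a fixed replication are CRN-paired.
    """
    if grid is None:
        grid = Grid(scenarios=[scenario])
    shared = make_shared_draws(scenario, rep, master_seed)
    policy = ArmPolicy.for_arm(arm)
    return simulate_arm(scenario, policy, shared, grid.costs, grid.decrements, grid.econ, rep)


def replication_patients(
    scenario: Scenario,
    arm: str,
    rep: int,
    master_seed: int,
    grid: Grid | None = None,
) -> list[Patient]:
    """Patient-level event log of one replication (slow reference path).

    Rebuilds every patient's timeline and cost ledger through the per-patient
    pathway routines, using the same shared draws and queue outcomes as the
    vectorised path; used for event-log export and for auditing the
    vectorised aggregation.
    """
    if grid is None:
        grid = Grid(scenarios=[scenario])
    shared = make_shared_draws(scenario, rep, master_seed)
    policy = ArmPolicy.for_arm(arm)
    cohort = shared.cohort
    flow = arm_flow(scenario, policy, shared)
    service = np.where(
        flow.seen & ~flow.in_window,
        flow.ref_day + scenario.tww_window_days + shared.excess_days,
        flow.service,
    )
    pence = grid.costs.pence_map()
    patients = cohort.to_patients()
    if policy.arm == "standard":
        for p in patients:
            p.risk_category = None
    for i, p in enumerate(patients):
        day = int(service[i]) if flow.seen[i] else None
        if p.subtype == "prostate":
            route_prostate(
                p,
                policy,
                pence,
                scenario.cascade,
                float(shared.u_mpmri[i]),
                float(shared.u_biopsy[i]),
                day,
            )
        else:
            route_bladder_kidney(p, policy, pence, day)
        # survival decrement trigger: >28-day wait for a diagnosed cancer
        if p.has_cancer and p.referral_delay_months == 0:
            if flow.seen[i] and flow.final_wait[i] > 28:
                p.referral_delay_months = 2
            elif flow.referred[i] and not flow.seen[i]:
                p.referral_delay_months = 6
    return patients


def event_log_frame(patients: Iterable[Patient]):
    """Tidy (patient id, event, day) table for CSV export."""
    import pandas as pd

    rows = [(p.id, name, day) for p in patients for name, day in p.timeline]
    return pd.DataFrame(rows, columns=["id", "event", "day"])
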
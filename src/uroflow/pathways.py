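"""Diagnostic pathways and management arms.

Two pathways are modelled, ending at diagnosis:

* prostate: GP consult + PSA blood test (+ risk test in test arms) ->
  urgent referral -> secondary-care triage appointment -> mpMRI ->
  TRUS biopsy if mpMRI positive -> MDT review if biopsy positive;
* bladder/kidney: GP consult (+ risk test) -> urgent referral ->
  cystoscopy + ultrasound + X-ray (all three for every referred patient)
  -> MDT review.

Three management arms:

* ``standard``: everyone urgently referred, first-come-first-served;
* ``prioritize``: everyone referred, queue ordered high > medium > low risk;
* ``triage_and_prioritize``: low-risk patients are not urgently referred.
  Low-risk non-cancers (true negatives) exit with no further cost, benefit
  or harm.  Low-risk cancers (false negatives, ~3 % of cancers in the base
  case) stay symptomatic, make two further GP visits and are re-referred
  after six months (183 days), re-entering the urgent queue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort import ConfigurationError, Patient

__all__ = [
    "ARMS",
    "ArmPolicy",
    "PathwayStep",
    "CascadeProbs",
    "ReferralDecision",
    "apply_arm_policy",
    "route_prostate",
    "route_bladder_kidney",
    "COSTED_STEPS",
]

ARMS = ("standard", "prioritize", "triage_and_prioritize")

SIX_MONTHS_DAYS = 183

#: Clinical steps that carry a unit cost (the fixed vocabulary joining the
#: pathway definitions to the cost table).
COSTED_STEPS = frozenset(
    {
        "gp-consult",
        "psa-test",
        "pinpoint-test",
        "triage-appt",
        "mpmri",
        "trus-biopsy",
        "mdt",
        "cystoscopy",
        "ultrasound",
        "x-ray",
    }
)


@dataclass(frozen=True)
class PathwayStep:
    """A named, costed step of a diagnostic pathway."""

    name: str
    unit_cost_pence: int

    def __post_init__(self) -> None:
        if self.unit_cost_pence < 0:
            raise ConfigurationError(f"unit cost of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class ArmPolicy:
    """Referral/priority policy of a management arm."""

    arm: str
    low_risk_referred: bool
    fn_extra_gp_visits: int = 2
    fn_delay_days: int = SIX_MONTHS_DAYS
    #: Priority class a re-referred missed cancer enters the queue with.
    fn_re_referral_class: str = "high"

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ConfigurationError(f"unknown arm {self.arm!r}")
        if self.arm in ("standard", "prioritize") and not self.low_risk_referred:
            raise ConfigurationError(f"{self.arm} arm must refer every patient")
        if self.arm == "triage_and_prioritize" and self.low_risk_referred:
            raise ConfigurationError("triage arm must not refer low-risk patients urgently")

    @property
    def uses_risk_test(self) -> bool:
        return self.arm != "standard"

    @classmethod
    def for_arm(cls, arm: str, **kwargs) -> "ArmPolicy":
        return cls(arm=arm, low_risk_referred=(arm != "triage_and_prioritize"), **kwargs)


@dataclass(frozen=True)
class CascadeProbs:
    """Conditional positivity probabilities of the prostate cascade.

    Every confirmed cancer must traverse mpMRI and biopsy for diagnosis to
    be made at MDT, hence both cancer-conditional defaults are 1.
    """

    mpmri_pos_cancer: float = 1.0
    mpmri_pos_nocancer: float = 0.35
    biopsy_pos_cancer: float = 1.0
    biopsy_pos_nocancer: float = 0.0

    def __post_init__(self) -> None:
        for f in ("mpmri_pos_cancer", "mpmri_pos_nocancer", "biopsy_pos_cancer", "biopsy_pos_nocancer"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{f} must be a probability, got {v!r}")


@dataclass(frozen=True)
class ReferralDecision:
    referred: bool
    referral_day: int | None
    priority_class: str | None
    extra_gp_days: tuple[int, ...] = ()


def apply_arm_policy(p: Patient, policy: ArmPolicy) -> ReferralDecision:
    """Decide referral timing and queue class for one patient.

    Standard care refers everyone unclassified; prioritization refers
    everyone under their risk class; triage-and-prioritization withholds
    low-risk patients, re-referring the missed cancers after the policy
    delay with two additional GP consultations in the interim.
    """
    if policy.arm == "standard":
        return ReferralDecision(True, p.arrival_day, "unclassified")
    if p.risk_category is None:
        raise AssertionError(f"patient {p.id}: risk category missing in {policy.arm} arm")
    if policy.arm == "prioritize" or p.risk_category != "low":
        return ReferralDecision(True, p.arrival_day, p.risk_category)
    # triage arm, low risk
    if not p.has_cancer:
        return ReferralDecision(False, None, None)
    # false negative: symptomatic, two extra GP visits, delayed referral
    delay = policy.fn_delay_days
    visits = tuple(
        p.arrival_day + round(delay * (k + 1) / (policy.fn_extra_gp_visits + 1))
        for k in range(policy.fn_extra_gp_visits)
    )
    return ReferralDecision(True, p.arrival_day + delay, policy.fn_re_referral_class, visits)


def _costed(p: Patient, step: str, day: int, cost_pence: Mapping[str, int]) -> None:
    if step not in cost_pence:
        raise ConfigurationError(f"no unit cost configured for step {step!r}")
    p.add_event(step, day)
    p.add_cost(step, cost_pence[step])


def route_prostate(
    p: Patient,
    policy: ArmPolicy,
    cost_pence: Mapping[str, int],
    cascade: CascadeProbs,
    u_mpmri: float,
    u_biopsy: float,
    service_day: int | None,
) -> Patient:
    """Trace one patient through the prostate pathway, filling timeline and
    cost ledger.

    ``service_day`` is the secondary-care appointment day from the queue
    simulation (None if never seen / not referred); ``u_mpmri``/``u_biopsy``
    are the patient's common-random-number draws for test positivity.
    """
    if p.subtype != "prostate":
        raise ConfigurationError(f"patient {p.id} is not on the prostate pathway")
    _costed(p, "gp-consult", p.arrival_day, cost_pence)
    _costed(p, "psa-test", p.arrival_day, cost_pence)
    if policy.uses_risk_test:
        _costed(p, "pinpoint-test", p.arrival_day, cost_pence)
    decision = apply_arm_policy(p, policy)
    for day in decision.extra_gp_days:
        _costed(p, "gp-consult", day, cost_pence)
    if not decision.referred:
        p.add_event("exit", p.arrival_day)
        return p
    p.add_event("re-referral" if decision.referral_day != p.arrival_day else "referral", decision.referral_day)
    if decision.referral_day != p.arrival_day:
        p.referral_delay_months = 6
    if service_day is None:
        p.add_event("censored", decision.referral_day)
        return p
    p.add_event("seen", service_day)
    _costed(p, "triage-appt", service_day, cost_pence)
    _costed(p, "mpmri", service_day, cost_pence)
    pos_mri = u_mpmri < (cascade.mpmri_pos_cancer if p.has_cancer else cascade.mpmri_pos_nocancer)
    if pos_mri:
        _costed(p, "trus-biopsy", service_day, cost_pence)
        pos_biopsy = u_biopsy < (
            cascade.biopsy_pos_cancer if p.has_cancer else cascade.biopsy_pos_nocancer
        )
        if pos_biopsy:
            _costed(p, "mdt", service_day, cost_pence)
            if p.has_cancer:
                p.add_event("diagnosis", service_day)
    p.add_event("exit", service_day)
    return p


def route_bladder_kidney(
    p: Patient,
    policy: ArmPolicy,
    cost_pence: Mapping[str, int],
    service_day: int | None,
) -> Patient:
    """Trace one patient through the bladder/kidney pathway.

    Every referred patient receives cystoscopy, ultrasound and X-ray, and
    all results are reviewed at an MDT meeting.
    """
    if p.subtype not in ("bladder", "kidney"):
        raise ConfigurationError(f"patient {p.id} is not on the bladder/kidney pathway")
    _costed(p, "gp-consult", p.arrival_day, cost_pence)
    if policy.uses_risk_test:
        _costed(p, "pinpoint-test", p.arrival_day, cost_pence)
    decision = apply_arm_policy(p, policy)
    for day in decision.extra_gp_days:
        _costed(p, "gp-consult", day, cost_pence)
    if not decision.referred:
        p.add_event("exit", p.arrival_day)
        return p
    p.add_event("re-referral" if decision.referral_day != p.arrival_day else "referral", decision.referral_day)
    if decision.referral_day != p.arrival_day:
        p.referral_delay_months = 6
    if service_day is None:
        p.add_event("censored", decision.referral_day)
        return p
    p.add_event("seen", service_day)
    for step in ("cystoscopy", "ultrasound", "x-ray", "mdt"):
        _costed(p, step, service_day, cost_pence)
    if p.has_cancer:
        p.add_event("diagnosis", service_day)
    p.add_event("exit", service_day)
    return p
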
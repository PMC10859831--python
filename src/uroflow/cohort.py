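"""Synthetic urgent-referral cohort generation.

Builds the patient stream entering the suspected-urological-cancer urgent
referral ("two-week wait", TWW) pathway: monthly arrival volumes, cancer
status, suspected subtype (prostate vs bladder/kidney, and bladder vs kidney
within the latter), age band, and the three-category risk classification
(high / medium / low) produced by a blood-based risk-prediction test ordered
in primary care.

The classification is represented as a conditional probability table over
risk categories given cancer status -- the accuracy of the underlying
prediction algorithm is an *input* to the model, not something simulated
from blood-test values.

Base-case anchors: cancer prevalence 16.9 % among urgent urological
referrals; 75.91 % of referrals on the prostate pathway; 59.79 % of
bladder/kidney referrals suspected bladder; 3 % of cancers classified low
risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "CohortParams",
    "Patient",
    "Cohort",
    "MONTH_LENGTHS",
    "HORIZON_DAYS",
    "SUBTYPES",
    "RISK_CATEGORIES",
    "generate_arrivals",
    "assign_attributes",
    "assign_risk_category",
    "generate_cohort",
]


class ConfigurationError(ValueError):
    """Raised when model parameters are inconsistent or incomplete."""


#: Calendar month lengths for the simulated year December 2021 -- November 2022.
MONTH_LENGTHS: tuple[int, ...] = (31, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30)
HORIZON_DAYS: int = sum(MONTH_LENGTHS)  # 365

SUBTYPES: tuple[str, ...] = ("prostate", "bladder", "kidney")
PATHWAYS: tuple[str, ...] = ("prostate", "bladder_kidney")
RISK_CATEGORIES: tuple[str, ...] = ("high", "medium", "low")
DEFAULT_AGE_BANDS: tuple[str, ...] = ("<60", "60-79", "80+")

_PROB_TOL = 1e-12


def _as_probvec(name: str, values: Sequence[float], length: int | None = None) -> tuple[float, ...]:
    v = tuple(float(x) for x in values)
    if length is not None and len(v) != length:
        raise ConfigurationError(f"{name} must have length {length}, got {len(v)}")
    if not all(np.isfinite(v)):
        raise ConfigurationError(f"{name} contains non-finite entries: {v}")
    if any(x < 0 or x > 1 for x in v):
        raise ConfigurationError(f"{name} entries must lie in [0, 1]: {v}")
    if abs(sum(v) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1 (got {sum(v)!r})")
    return v


def _check_prob(name: str, p: float) -> float:
    p = float(p)
    if not np.isfinite(p) or not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p!r}")
    return p


def _default_age_band_probs() -> dict[str, tuple[float, ...]]:
    # Placeholder uniform bands; the real Routes-to-Diagnosis per-band
    # proportions are site data and must be supplied via configuration.
    n = len(DEFAULT_AGE_BANDS)
    return {s: (1.0 / n,) * n for s in SUBTYPES}


def _default_risk_matrix() -> dict[bool, tuple[float, float, float]]:
    # Cancer row anchored at P(low | cancer) = 0.03 (rule-out threshold set for
    # ~97 % sensitivity); non-cancer row is a synthetic placeholder giving a
    # ~25 % rule-out rate among non-cancers.
    return {True: (0.87, 0.10, 0.03), False: (0.05, 0.70, 0.25)}


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic referral stream.

    annual_referrals
        Expected number of urgent referrals per year entering the pathway.
    monthly_weights
        Twelve non-negative weights (summing to one) splitting the annual
        volume across calendar months, December first.
    prevalence
        P(confirmed urological cancer) among urgent referrals.
    prostate_share
        P(referral is on the prostate pathway).
    bladder_share_of_bk
        P(suspected bladder | bladder/kidney pathway).
    age_band_probs
        Per-subtype probability vector over ``age_bands``.
    risk_matrix
        Conditional probabilities of (high, medium, low) risk given cancer
        status: ``{True: row, False: row}``.
    """

    annual_referrals: float = 2400.0
    monthly_weights: tuple[float, ...] = (1.0 / 12,) * 12
    prevalence: float = 0.169
    prostate_share: float = 0.7591
    bladder_share_of_bk: float = 0.5979
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS
    age_band_probs: Mapping[str, tuple[float, ...]] = field(default_factory=_default_age_band_probs)
    risk_matrix: Mapping[bool, tuple[float, float, float]] = field(default_factory=_default_risk_matrix)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.annual_referrals) or self.annual_referrals < 0:
            raise ConfigurationError(
                f"annual_referrals must be finite and >= 0, got {self.annual_referrals!r}"
            )
        object.__setattr__(
            self, "monthly_weights", _as_probvec("monthly_weights", self.monthly_weights, 12)
        )
        _check_prob("prevalence", self.prevalence)
        _check_prob("prostate_share", self.prostate_share)
        _check_prob("bladder_share_of_bk", self.bladder_share_of_bk)
        bands = tuple(self.age_bands)
        object.__setattr__(self, "age_bands", bands)
        probs = {}
        for s in SUBTYPES:
            if s not in self.age_band_probs:
                raise ConfigurationError(f"age_band_probs missing subtype {s!r}")
            probs[s] = _as_probvec(f"age_band_probs[{s}]", self.age_band_probs[s], len(bands))
        object.__setattr__(self, "age_band_probs", probs)
        rm = {}
        for status in (True, False):
            if status not in self.risk_matrix:
                raise ConfigurationError(f"risk_matrix missing row for has_cancer={status}")
            rm[status] = _as_probvec(f"risk_matrix[{status}]", self.risk_matrix[status], 3)
        object.__setattr__(self, "risk_matrix", rm)

    def with_(self, **kwargs) -> "CohortParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class Patient:
    """One simulated individual on the urgent referral pathway.

    ``timeline`` is an ordered list of (event-name, day) pairs with
    non-decreasing days; ``cost_ledger`` is a list of (item-name, pence)
    pairs.  ``risk_category`` stays ``None`` until the risk test is applied
    (standard care never assigns one).
    """

    id: int
    arrival_day: int
    has_cancer: bool | None = None
    subtype: str | None = None
    age_band: str | None = None
    risk_category: str | None = None
    referral_delay_months: int = 0
    timeline: list[tuple[str, int]] = field(default_factory=list)
    cost_ledger: list[tuple[str, int]] = field(default_factory=list)

    def add_event(self, name: str, day: int) -> None:
        if self.timeline and day < self.timeline[-1][1]:
            raise AssertionError(
                f"patient {self.id}: event {name!r} at day {day} precedes "
                f"{self.timeline[-1]}"
            )
        self.timeline.append((name, int(day)))

    def add_cost(self, item: str, pence: int) -> None:
        if pence < 0:
            raise ConfigurationError(f"negative cost for {item!r}")
        self.cost_ledger.append((item, int(pence)))

    @property
    def total_cost_pence(self) -> int:
        return sum(p for _, p in self.cost_ledger)


class Cohort:
    """Column-oriented container for one replication's patient stream.

    Attribute arrays are aligned by patient id (0..n-1, in arrival order).
    ``risk`` is -1 before classification, else an index into
    :data:`RISK_CATEGORIES`.
    """

    def __init__(
        self,
        arrival_day: np.ndarray,
        has_cancer: np.ndarray,
        subtype: np.ndarray,
        age_band: np.ndarray,
        risk: np.ndarray,
        age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS,
    ) -> None:
        n = len(arrival_day)
        for name, arr in (
            ("has_cancer", has_cancer),
            ("subtype", subtype),
            ("age_band", age_band),
            ("risk", risk),
        ):
            if len(arr) != n:
                raise ConfigurationError(f"{name} length {len(arr)} != {n}")
        self.arrival_day = np.asarray(arrival_day, dtype=np.int32)
        self.has_cancer = np.asarray(has_cancer, dtype=bool)
        self.subtype = np.asarray(subtype, dtype=np.int8)
        self.age_band = np.asarray(age_band, dtype=np.int8)
        self.risk = np.asarray(risk, dtype=np.int8)
        self.age_bands = age_bands

    def __len__(self) -> int:
        return len(self.arrival_day)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    @property
    def pathway(self) -> np.ndarray:
        """0 for the prostate model, 1 for the bladder/kidney model."""
        return (self.subtype != 0).astype(np.int8)

    def subtype_labels(self) -> np.ndarray:
        return np.array(SUBTYPES, dtype=object)[self.subtype]

    def risk_labels(self) -> np.ndarray:
        out = np.full(len(self), None, dtype=object)
        m = self.risk >= 0
        out[m] = np.array(RISK_CATEGORIES, dtype=object)[self.risk[m]]
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids,
                "arrival_day": self.arrival_day,
                "has_cancer": self.has_cancer,
                "subtype": self.subtype_labels(),
                "age_band": np.array(self.age_bands, dtype=object)[self.age_band],
                "risk_category": self.risk_labels(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_patients(self) -> list[Patient]:
        labels = self.subtype_labels()
        risks = self.risk_labels()
        bands = np.array(self.age_bands, dtype=object)[self.age_band]
        return [
            Patient(
                id=int(i),
                arrival_day=int(self.arrival_day[i]),
                has_cancer=bool(self.has_cancer[i]),
                subtype=labels[i],
                age_band=bands[i],
                risk_category=risks[i],
            )
            for i in range(len(self))
        ]


def _month_starts(horizon_days: int) -> np.ndarray:
    starts = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])
    return starts


def sample_arrival_days(
    params: CohortParams, rng: np.random.Generator, horizon_days: int = HORIZON_DAYS
) -> np.ndarray:
    """Sample sorted arrival days over the horizon.

    Monthly counts are Poisson with mean ``annual_referrals * weight`` and
    arrivals are uniform within each month (a homogeneous Poisson process at
    monthly resolution, the maximum-entropy reading of monthly totals).
    Horizons shorter than a year truncate the calendar; longer horizons
    recycle the 12-month profile.
    """
    starts = _month_starts(horizon_days)
    days: list[np.ndarray] = []
    month = 0
    while True:
        cycle, m = divmod(month, 12)
        start = cycle * HORIZON_DAYS + starts[m]
        if start >= horizon_days:
            break
        length = min(MONTH_LENGTHS[m], horizon_days - start)
        mean = params.annual_referrals * params.monthly_weights[m] * (length / MONTH_LENGTHS[m])
        count = rng.poisson(mean)
        if count:
            days.append(start + rng.integers(0, length, size=count))
        month += 1
    if not days:
        return np.empty(0, dtype=np.int32)
    out = np.concatenate(days).astype(np.int32)
    out.sort(kind="stable")
    return out


def generate_arrivals(
    params: CohortParams,
    horizon_days: int = HORIZON_DAYS,
    rng: np.random.Generator | None = None,
) -> list[Patient]:
    """Generate the bare arrival stream (patients with arrival days only)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    days = sample_arrival_days(params, rng, horizon_days)
    return [Patient(id=i, arrival_day=int(d)) for i, d in enumerate(days)]


def _draw_category(rng: np.random.Generator, probs: Sequence[float]) -> int:
    u = rng.random()
    acc = 0.0
    for i, p in enumerate(probs):
        acc += p
        if u < acc:
            return i
    return len(probs) - 1


def assign_attributes(
    p: Patient,
    params: CohortParams,
    rng: np.random.Generator,
    model: str = "mixed",
) -> Patient:
    """Assign cancer status, subtype and age band to one patient in place.

    ``model`` selects the context: ``"prostate"`` fixes the subtype,
    ``"bladder_kidney"`` splits bladder vs kidney, ``"mixed"`` first routes
    between the two pathways by ``prostate_share``.
    """
    p.has_cancer = bool(rng.random() < params.prevalence)
    if model == "prostate":
        p.subtype = "prostate"
    else:
        if model == "mixed":
            on_prostate = rng.random() < params.prostate_share
        elif model == "bladder_kidney":
            on_prostate = False
        else:
            raise ConfigurationError(f"unknown model {model!r}")
        if on_prostate:
            p.subtype = "prostate"
        else:
            p.subtype = "bladder" if rng.random() < params.bladder_share_of_bk else "kidney"
    band_idx = _draw_category(rng, params.age_band_probs[p.subtype])
    p.age_band = params.age_bands[band_idx]
    return p


def assign_risk_category(
    p: Patient,
    risk_matrix: Mapping[bool, Sequence[float]],
    rng: np.random.Generator,
) -> Patient:
    """Draw the risk-test category for one patient (cancer status required)."""
    if p.has_cancer is None:
        raise ConfigurationError("risk category requested before cancer status assigned")
    row = _as_probvec(f"risk_matrix[{p.has_cancer}]", risk_matrix[bool(p.has_cancer)], 3)
    p.risk_category = RISK_CATEGORIES[_draw_category(rng, row)]
    return p


def generate_cohort(
    params: CohortParams,
    model: str = "mixed",
    horizon_days: int = HORIZON_DAYS,
    rng: np.random.Generator | int | None = None,
) -> Cohort:
    """Generate a full replication cohort (vectorised).

    The same seed and parameters always yield a bit-identical cohort.
    Risk categories are drawn for every patient so that the same cohort can
    be replayed under any management arm with common random numbers;
    standard care simply ignores them.
    """
    if model not in ("mixed", "prostate", "bladder_kidney"):
        raise ConfigurationError(f"unknown model {model!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    arrival = sample_arrival_days(params, rng, horizon_days)
    n = len(arrival)
    has_cancer = rng.random(n) < params.prevalence
    if model == "prostate":
        subtype = np.zeros(n, dtype=np.int8)
    else:
        if model == "mixed":
            on_prostate = rng.random(n) < params.prostate_share
        else:
            on_prostate = np.zeros(n, dtype=bool)
        bladder = rng.random(n) < params.bladder_share_of_bk
        subtype = np.where(on_prostate, 0, np.where(bladder, 1, 2)).astype(np.int8)
    u_band = rng.random(n)
    age_band = np.zeros(n, dtype=np.int8)
    for code, name in enumerate(SUBTYPES):
        mask = subtype == code
        if not mask.any():
            continue
        cum = np.cumsum(params.age_band_probs[name])
        age_band[mask] = np.searchsorted(cum, u_band[mask], side="right").astype(np.int8)
    age_band = np.clip(age_band, 0, len(params.age_bands) - 1)
    u_risk = rng.random(n)
    risk = np.empty(n, dtype=np.int8)
    for status in (True, False):
        mask = has_cancer == status
        if not mask.any():
            continue
        cum = np.cumsum(params.risk_matrix[status])
        risk[mask] = np.clip(np.searchsorted(cum, u_risk[mask], side="right"), 0, 2).astype(np.int8)
    return Cohort(arrival, has_cancer, subtype, age_band, risk, params.age_bands)
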
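"""Capacity-constrained priority-queue simulation core.

Time is integer days from the start of the horizon.  Secondary care offers a
fixed number of appointment slots per period (daily by default); each day the
pending queue is served in (priority-class rank, enqueue day, patient id)
order up to the period's remaining slots, so standard care (a single
"unclassified" class) degenerates to first-come-first-served.

Capacity represents the providers' throughput of patients seen *within* the
14-day two-week-wait (TWW) window.  In the default "window" mechanism an
entry that can no longer be reached within 14 days of referral leaves the
within-window track: it breaches the target and is seen after an additional
empirically distributed delay of 1-16 days, mirroring how observed NHS
waiting statistics record the excess beyond the operational window.  The
slot process decides *who* gets the within-window appointments, so a
priority discipline redistributes timely slots towards high-risk patients
without changing total throughput.  A pure "backlog" mechanism (entries
wait indefinitely for a slot) is available as an alternative.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import Cohort, ConfigurationError, Patient

__all__ = [
    "CapacitySchedule",
    "ExcessDelayDist",
    "QueueEntry",
    "DayQueue",
    "PRIORITY_RANK",
    "enqueue",
    "allocate_slots",
    "simulate_queue",
    "simulate_queue_reference",
    "sample_excess_delay",
    "wait_days",
    "calibrate_capacity_rate",
]

TWW_WINDOW_DAYS = 14
#: Lower rank is served first; standard care uses "unclassified" throughout.
PRIORITY_RANK = {"high": 0, "medium": 1, "low": 2, "unclassified": 3}


@dataclass(frozen=True)
class CapacitySchedule:
    """Appointment slots available per period.

    ``slots_per_period[k]`` slots may be used on any day of period ``k``
    (days ``k*period_length .. (k+1)*period_length - 1``).
    """

    slots_per_period: tuple[int, ...]
    period_length: int = 1

    def __post_init__(self) -> None:
        if self.period_length < 1:
            raise ConfigurationError("period_length must be >= 1")
        slots = tuple(int(s) for s in self.slots_per_period)
        if any(s < 0 for s in slots):
            raise ConfigurationError("slot counts must be >= 0")
        object.__setattr__(self, "slots_per_period", slots)

    @property
    def n_days(self) -> int:
        return len(self.slots_per_period) * self.period_length

    def period_of(self, day: int) -> int:
        if day < 0 or day >= self.n_days:
            raise ConfigurationError(
                f"day {day} outside capacity schedule (covers 0..{self.n_days - 1}); "
                "extend the schedule to span the horizon plus run-out tail"
            )
        return day // self.period_length

    @classmethod
    def from_rate(cls, rate_per_day: float, n_days: int) -> "CapacitySchedule":
        """Daily schedule delivering ``rate_per_day`` slots on average.

        Fractional rates are spread by accumulation, so granularity is much
        finer than one slot per day over any multi-day window.
        """
        if rate_per_day < 0 or not np.isfinite(rate_per_day):
            raise ConfigurationError(f"rate_per_day must be finite and >= 0, got {rate_per_day!r}")
        edges = np.floor(rate_per_day * np.arange(n_days + 1)).astype(np.int64)
        return cls(tuple(np.diff(edges).tolist()), period_length=1)


@dataclass(frozen=True)
class ExcessDelayDist:
    """Distribution of additional waiting days beyond the 14-day window.

    Support is a subset of 1..16 days, per the observed range of additional
    waits for patients not seen within two weeks.
    """

    support: tuple[int, ...] = tuple(range(1, 17))
    probs: tuple[float, ...] = tuple()

    def __post_init__(self) -> None:
        support = tuple(int(d) for d in self.support)
        if any(d < 1 or d > 16 for d in support):
            raise ConfigurationError(f"excess-delay support must lie in [1, 16], got {support}")
        if len(set(support)) != len(support):
            raise ConfigurationError("excess-delay support has duplicates")
        probs = self.probs
        if not probs:
            # Default: geometric-like decay, most excess waits short.
            w = 0.8 ** np.arange(len(support))
            probs = tuple((w / w.sum()).tolist())
        probs = tuple(float(p) for p in probs)
        if len(probs) != len(support):
            raise ConfigurationError("probs and support length mismatch")
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-4:
            raise ConfigurationError("excess-delay probs must be >= 0 and sum to 1")
        # renormalise away rounding slack from hand-edited configs
        total = sum(probs)
        probs = tuple(p / total for p in probs)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def point_mass(cls, days: int) -> "ExcessDelayDist":
        return cls(support=(days,), probs=(1.0,))

    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))


def sample_excess_delay(
    dist: ExcessDelayDist, rng: np.random.Generator, size: int | None = None
) -> int | np.ndarray:
    """Sample additional waiting days (always within [1, 16])."""
    support = np.asarray(dist.support, dtype=np.int64)
    cum = np.cumsum(dist.probs)
    u = rng.random(size)
    idx = np.minimum(np.searchsorted(cum, u, side="right"), len(support) - 1)
    out = support[idx]
    return int(out) if size is None else out


@dataclass(frozen=True, order=True)
class QueueEntry:
    """One referral waiting for a secondary-care appointment.

    Ordering is (class rank, enqueue day, patient id) -- the service
    discipline of the model.
    """

    rank: int
    enqueue_day: int
    patient_id: int

    @property
    def priority_class(self) -> str:
        for name, r in PRIORITY_RANK.items():
            if r == self.rank:
                return name
        return "unclassified"

    @classmethod
    def make(cls, patient_id: int, priority_class: str, enqueue_day: int) -> "QueueEntry":
        if priority_class not in PRIORITY_RANK:
            raise ConfigurationError(f"unknown priority class {priority_class!r}")
        return cls(PRIORITY_RANK[priority_class], int(enqueue_day), int(patient_id))


class DayQueue:
    """Pending-referral queue with class-priority discipline."""

    def __init__(self) -> None:
        self._heap: list[QueueEntry] = []

    def __len__(self) -> int:
        return len(self._heap)

    def enqueue(self, entry: QueueEntry) -> None:
        heapq.heappush(self._heap, entry)

    def pop(self) -> QueueEntry:
        return heapq.heappop(self._heap)

    def drain_order(self) -> list[QueueEntry]:
        """Service order of the current backlog (does not consume it)."""
        return sorted(self._heap)


def enqueue(entry: QueueEntry, queue: DayQueue) -> DayQueue:
    """Functional wrapper over :meth:`DayQueue.enqueue`."""
    queue.enqueue(entry)
    return queue


def allocate_slots(
    queue: DayQueue,
    schedule: CapacitySchedule,
    day: int,
    remaining: dict[int, int] | None = None,
    window: int | None = None,
    breached: list[QueueEntry] | None = None,
) -> list[QueueEntry]:
    """Serve queued entries on ``day`` up to the period's remaining slots.

    With a ``window`` (days), entries that could no longer be seen within
    ``window`` days of their referral leave the within-window service track
    instead of consuming a slot and are appended to ``breached``: they are
    the patients who miss the two-week target and resolve with an
    empirically distributed additional delay.  ``remaining`` tracks slot
    consumption within multi-day periods across calls; omit it for
    single-shot use.
    """
    period = schedule.period_of(day)
    if remaining is None:
        remaining = {}
    if period not in remaining:
        remaining[period] = schedule.slots_per_period[period]
    served: list[QueueEntry] = []
    while remaining[period] > 0 and len(queue) > 0:
        entry = queue.pop()
        if window is not None and day - entry.enqueue_day > window:
            if breached is not None:
                breached.append(entry)
            continue
        served.append(entry)
        remaining[period] -= 1
    return served


def simulate_queue(
    referral_days: np.ndarray,
    ranks: np.ndarray,
    schedule: CapacitySchedule,
    end_day: int | None = None,
    ids: np.ndarray | None = None,
    window: int | None = TWW_WINDOW_DAYS,
) -> np.ndarray:
    """Run the slot-allocation process; return per-entry service days.

    With the default ``window``, an entry not reachable within ``window``
    days of referral leaves the within-window track (service day -1: a
    target breach, resolved downstream with an empirical excess delay)
    without consuming a slot.  With ``window=None`` the queue is a pure
    backlog: entries wait indefinitely and -1 means never served by
    ``end_day`` (censored).  Same-day service is allowed.
    """
    referral_days = np.asarray(referral_days, dtype=np.int64)
    ranks = np.asarray(ranks, dtype=np.int64)
    n = len(referral_days)
    if ids is None:
        ids = np.arange(n, dtype=np.int64)
    else:
        ids = np.asarray(ids, dtype=np.int64)
    if end_day is None:
        end_day = schedule.n_days - 1
    if n and referral_days.max() > end_day:
        raise ConfigurationError("referral beyond simulated window")
    if end_day >= schedule.n_days:
        raise ConfigurationError(
            f"capacity schedule covers {schedule.n_days} days but {end_day + 1} are required"
        )
    service = np.full(n, -1, dtype=np.int64)
    if len(set(ids.tolist())) != n:
        raise ConfigurationError("queue entry ids must be unique")
    order = np.lexsort((ids, referral_days))
    ref_sorted = referral_days[order].tolist()
    rank_sorted = ranks[order].tolist()
    id_sorted = ids[order].tolist()
    idx_sorted = order.tolist()
    heap: list[tuple[int, int, int, int]] = []  # (rank, day, patient id, array index)
    push, pop = heapq.heappush, heapq.heappop
    slots = schedule.slots_per_period
    plen = schedule.period_length
    remaining = 0
    current_period = -1
    ptr = 0
    first_day = int(referral_days.min()) if n else 0
    for day in range(first_day, end_day + 1):
        while ptr < n and ref_sorted[ptr] == day:
            push(heap, (rank_sorted[ptr], day, id_sorted[ptr], idx_sorted[ptr]))
            ptr += 1
        period = day // plen
        if period != current_period:
            current_period = period
            remaining = slots[period]
        while remaining > 0 and heap:
            if window is not None and day - heap[0][1] > window:
                pop(heap)  # expired: breaches the window, frees no slot
                continue
            _, _, _, i = pop(heap)
            service[i] = day
            remaining -= 1
    return service


def simulate_queue_reference(
    referral_days: np.ndarray,
    ranks: np.ndarray,
    schedule: CapacitySchedule,
    end_day: int | None = None,
    ids: np.ndarray | None = None,
    window: int | None = TWW_WINDOW_DAYS,
) -> np.ndarray:
    """Slow reference path built from :class:`DayQueue` and
    :func:`allocate_slots`; used to cross-check :func:`simulate_queue`."""
    referral_days = np.asarray(referral_days, dtype=np.int64)
    ranks = np.asarray(ranks, dtype=np.int64)
    n = len(referral_days)
    if ids is None:
        ids = np.arange(n, dtype=np.int64)
    if end_day is None:
        end_day = schedule.n_days - 1
    service = np.full(n, -1, dtype=np.int64)
    pos = {int(pid): i for i, pid in enumerate(ids)}
    order = np.lexsort((ids, referral_days))
    queue = DayQueue()
    remaining: dict[int, int] = {}
    ptr = 0
    first_day = int(referral_days.min()) if n else 0
    for day in range(first_day, end_day + 1):
        while ptr < n and referral_days[order[ptr]] == day:
            i = order[ptr]
            enqueue(QueueEntry(int(ranks[i]), int(day), int(ids[i])), queue)
            ptr += 1
        for entry in allocate_slots(queue, schedule, day, remaining, window=window):
            service[pos[entry.patient_id]] = day
    return service


def wait_days(p: Patient) -> int:
    """Days from the (latest) referral to first being seen in secondary care.

    Raises if the patient has no referral; returns -1 for a referred patient
    never seen within the simulated window (censored -- excluded from mean
    waits, counted as a TWW breach).
    """
    ref = None
    seen = None
    for name, day in p.timeline:
        if name in ("referral", "re-referral"):
            ref = day
        elif name == "seen" and seen is None and ref is not None:
            seen = day
    if ref is None:
        raise ConfigurationError(f"patient {p.id} has no referral event")
    if seen is None:
        return -1
    return seen - ref


def calibrate_capacity_rate(
    demand_referral_days: Sequence[np.ndarray],
    target_tww: float,
    n_days: int,
    iters: int = 28,
) -> float:
    """Invert the standard-care TWW fraction to a daily slot rate.

    Bisection on the (noisy but effectively monotone) map rate -> simulated
    first-come-first-served TWW fraction, evaluated on the supplied
    calibration cohorts' referral-day arrays.
    """
    if not (0.0 < target_tww <= 1.0):
        raise ConfigurationError(f"target TWW must lie in (0, 1], got {target_tww!r}")
    total = sum(len(d) for d in demand_referral_days)
    if total == 0:
        return 0.0
    mean_daily = total / len(demand_referral_days) / max(1, max(d.max() + 1 for d in demand_referral_days if len(d)))

    def tww_at(rate: float) -> float:
        schedule = CapacitySchedule.from_rate(rate, n_days)
        met = 0
        for days in demand_referral_days:
            ranks = np.full(len(days), PRIORITY_RANK["unclassified"], dtype=np.int64)
            service = simulate_queue(days, ranks, schedule, window=TWW_WINDOW_DAYS)
            met += int((service >= 0).sum())
        return met / total

    lo, hi = 0.0, max(4.0 * mean_daily, 1.0)
    while tww_at(hi) < target_tww and hi < 1e6:
        hi *= 2.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if tww_at(mid) < target_tww:
            lo = mid
        else:
            hi = mid
    return hi
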
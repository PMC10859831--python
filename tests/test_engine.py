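"""Queue discipline, slot allocation, excess delays, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uroflow import CapacitySchedule, ConfigurationError, ExcessDelayDist, QueueEntry
from uroflow.cohort import Patient
from uroflow.engine import (
    PRIORITY_RANK,
    DayQueue,
    allocate_slots,
    calibrate_capacity_rate,
    sample_excess_delay,
    simulate_queue,
    simulate_queue_reference,
    wait_days,
)


def oracle_schedule(entries, slots_by_period, period_length, end_day, window=None):
    """Independent brute-force scheduler: each day, re-sort the *entire*
    pending list by (rank, day, id) and serve from the front."""
    service = {pid: -1 for _, _, pid in entries}
    remaining = {}
    for day in range(end_day + 1):
        pending = [e for e in entries if e[1] <= day and service[e[2]] == -1]
        pending.sort()
        period = day // period_length
        remaining.setdefault(period, slots_by_period[period])
        for rank, enq, pid in pending:
            if remaining[period] == 0:
                break
            if window is not None and day - enq > window:
                service[pid] = -2  # expired: skip, no slot used
                continue
            service[pid] = day
            remaining[period] -= 1
    return np.array([max(service[pid], -1) for _, _, pid in entries])


# hand-traced fixture: 20 patients, 3 weekly periods with (4, 6, 3) slots
HAND_PATIENTS = [
    (0, 0, "low"), (1, 0, "high"), (2, 1, "medium"), (3, 1, "high"), (4, 2, "low"),
    (5, 3, "medium"), (6, 4, "high"), (7, 5, "low"), (8, 6, "medium"), (9, 7, "high"),
    (10, 8, "low"), (11, 9, "medium"), (12, 10, "high"), (13, 11, "low"), (14, 12, "medium"),
    (15, 14, "high"), (16, 15, "medium"), (17, 16, "low"), (18, 18, "high"), (19, 20, "medium"),
]
# worked by hand: 4 slots serve {1,0} day 0 and {3,2} day 1; the 6 slots of
# period 2 clear the backlog {6,9,5,8,4,7} on day 7; period 3's 3 slots go to
# {12,15,11} on day 14; everyone else is still pending at day 20
HAND_EXPECTED = [0, 0, 1, 1, 7, 7, 7, 7, 7, 7, -1, 14, 14, -1, -1, 14, -1, -1, -1, -1]


@pytest.mark.parametrize("impl", [simulate_queue, simulate_queue_reference])
def test_hand_traced_schedule(impl):
    days = np.array([p[1] for p in HAND_PATIENTS])
    ranks = np.array([PRIORITY_RANK[p[2]] for p in HAND_PATIENTS])
    sched = CapacitySchedule((4, 6, 3), period_length=7)
    service = impl(days, ranks, sched, end_day=20, window=14)
    assert service.tolist() == HAND_EXPECTED


def test_single_class_is_fifo():
    rng = np.random.default_rng(3)
    days = np.sort(rng.integers(0, 40, size=60))
    ranks = np.full(60, PRIORITY_RANK["unclassified"])
    sched = CapacitySchedule.from_rate(1.0, 200)
    service = simulate_queue(days, ranks, sched, window=None)
    served = service >= 0
    # FIFO: service order must follow (day, id) order
    order = np.argsort(service[served], kind="stable")
    enq = days[served][order]
    assert (np.diff(enq) >= 0).all()


def test_high_risk_served_before_earlier_low_risk():
    days = np.array([1, 2])
    ranks = np.array([PRIORITY_RANK["low"], PRIORITY_RANK["high"]])
    sched = CapacitySchedule((0, 0, 1, 1, 1, 1), period_length=1)
    service = simulate_queue(days, ranks, sched, window=None)
    assert service[1] < service[0]


@pytest.mark.parametrize("window", [None, 14])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matches_full_sort_oracle(window, seed):
    """200 random interleaved entries: service days equal an independent
    full re-sort scheduler, for both queue mechanisms."""
    rng = np.random.default_rng(seed)
    n = 200
    days = rng.integers(0, 60, size=n)
    ranks = rng.choice([0, 1, 2], size=n)
    slots = tuple(int(s) for s in rng.integers(0, 6, size=15))
    sched = CapacitySchedule(slots, period_length=7)
    entries = [(int(ranks[i]), int(days[i]), i) for i in range(n)]
    expected = oracle_schedule(entries, slots, 7, end_day=104, window=window)
    got = simulate_queue(days, ranks, sched, end_day=104, window=window)
    np.testing.assert_array_equal(got, expected)
    got_ref = simulate_queue_reference(days, ranks, sched, end_day=104, window=window)
    np.testing.assert_array_equal(got_ref, expected)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 20), st.sampled_from([0, 1, 2, 3])),
        min_size=1,
        max_size=40,
    ),
    st.integers(0, 3),
)
def test_queue_discipline_property(entries, slots_per_day):
    """Service never violates (rank, day, id) order among waiting entries."""
    days = np.array([d for d, _ in entries])
    ranks = np.array([r for _, r in entries])
    sched = CapacitySchedule.from_rate(slots_per_day, 60)
    service = simulate_queue(days, ranks, sched, end_day=59, window=None)
    oracle = oracle_schedule(
        [(int(ranks[i]), int(days[i]), i) for i in range(len(entries))],
        sched.slots_per_period,
        1,
        end_day=59,
        window=None,
    )
    np.testing.assert_array_equal(service, oracle)


def test_unconstrained_capacity_everyone_within_window():
    days = np.arange(50) % 30
    ranks = np.full(50, 3)
    sched = CapacitySchedule.from_rate(100, 60)
    service = simulate_queue(days, ranks, sched, window=14)
    assert (service == days).all()  # same-day service


def test_zero_capacity_nobody_served():
    days = np.arange(10)
    sched = CapacitySchedule.from_rate(0, 40)
    service = simulate_queue(days, np.full(10, 3), sched, window=None)
    assert (service == -1).all()


def test_slot_conservation_per_period():
    rng = np.random.default_rng(0)
    days = rng.integers(0, 70, size=400)
    ranks = rng.choice([0, 1, 2], size=400)
    slots = (10, 3, 8, 0, 12, 5, 9, 7, 11, 4, 6, 13)
    sched = CapacitySchedule(slots, period_length=7)
    service = simulate_queue(days, ranks, sched, window=14)
    for k, cap in enumerate(slots):
        used = ((service >= 7 * k) & (service < 7 * (k + 1))).sum()
        assert used <= cap


def test_schedule_too_short_raises():
    sched = CapacitySchedule.from_rate(1, 10)
    with pytest.raises(ConfigurationError):
        simulate_queue(np.array([0]), np.array([3]), sched, end_day=50)
    with pytest.raises(ConfigurationError):
        sched.period_of(10)


def test_from_rate_accumulates_exactly():
    for rate in (0.37, 1.0, 2.719, 15.25):
        sched = CapacitySchedule.from_rate(rate, 123)
        cum = np.cumsum(sched.slots_per_period)
        np.testing.assert_array_equal(cum, np.floor(rate * np.arange(1, 124)))


def test_allocate_slots_single_shot():
    q = DayQueue()
    for e in [QueueEntry.make(0, "low", 0), QueueEntry.make(1, "high", 1)]:
        q.enqueue(e)
    sched = CapacitySchedule((1,), period_length=7)
    served = allocate_slots(q, sched, day=2)
    assert [e.patient_id for e in served] == [1]
    assert len(q) == 1
    with pytest.raises(ConfigurationError):
        QueueEntry.make(0, "urgent", 0)


class TestExcessDelay:
    def test_point_mass(self):
        d = ExcessDelayDist.point_mass(5)
        rng = np.random.default_rng(0)
        assert all(sample_excess_delay(d, rng) == 5 for _ in range(20))

    def test_uniform_mean(self):
        d = ExcessDelayDist(support=tuple(range(1, 17)), probs=(1 / 16,) * 16)
        draws = sample_excess_delay(d, np.random.default_rng(1), size=50_000)
        assert abs(draws.mean() - 8.5) < 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_support_bounds(self, seed):
        d = ExcessDelayDist()  # default decaying distribution
        draws = sample_excess_delay(d, np.random.default_rng(seed), size=2000)
        assert draws.min() >= 1 and draws.max() <= 16

    def test_invalid_support_raises(self):
        with pytest.raises(ConfigurationError):
            ExcessDelayDist(support=(0, 1), probs=(0.5, 0.5))
        with pytest.raises(ConfigurationError):
            ExcessDelayDist(support=(1, 17), probs=(0.5, 0.5))
        with pytest.raises(ConfigurationError):
            ExcessDelayDist(support=(1, 2), probs=(0.6, 0.6))


class TestWaitDays:
    def _patient(self, events):
        p = Patient(id=0, arrival_day=0)
        for name, day in events:
            p.add_event(name, day)
        return p

    def test_same_day_seen(self):
        assert wait_days(self._patient([("referral", 5), ("seen", 5)])) == 0

    def test_boundary_inclusive(self):
        assert wait_days(self._patient([("referral", 10), ("seen", 24)])) == 14

    def test_boundary_breach(self):
        assert wait_days(self._patient([("referral", 10), ("seen", 25)])) == 15

    def test_re_referral_resets_clock(self):
        p = self._patient([("referral", 0), ("re-referral", 183), ("seen", 185)])
        assert wait_days(p) == 2

    def test_censored(self):
        assert wait_days(self._patient([("referral", 3)])) == -1

    def test_no_referral_raises(self):
        with pytest.raises(ConfigurationError):
            wait_days(self._patient([("gp-consult", 0)]))


def test_calibration_recovers_target_tww():
    rng = np.random.default_rng(11)
    demands = [np.sort(rng.integers(0, 365, size=3000)).astype(np.int64) for _ in range(3)]
    rate = calibrate_capacity_rate(demands, 0.8, n_days=500)
    sched = CapacitySchedule.from_rate(rate, 500)
    fresh = np.sort(np.random.default_rng(99).integers(0, 365, size=3000)).astype(np.int64)
    service = simulate_queue(fresh, np.full(3000, 3), sched, window=14)
    assert abs((service >= 0).mean() - 0.8) < 0.05
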
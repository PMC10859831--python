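"""Cost accounting, life-year decrements and net monetary benefit.

Costs are carried internally as integer pennies (exact to 0.01 GBP) and
inflated to the analysis year by a single multiplier; the one-year horizon
means costs themselves are not discounted.

The exploratory health outcome is life years lost through delayed
diagnosis: a cancer patient waiting more than 28 days from referral incurs
the 2-month-delay decrement to 10-year survival for their subtype and age
band, and a missed (false-negative) cancer incurs the 6-month decrement.
Decrements are discounted at the NICE 3.5 %/year rate over the 10-year
accrual window -- by default as a uniform stream over years 1..10, with a
lump-sum alternative.  Quality of life is assumed unaffected, so QALYs
equal life years and the incremental net monetary benefit is
``INMB = WTP * (LY_lost(standard) - LY_lost(test)) - (cost(test) - cost(standard))``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import ConfigurationError, Patient, SUBTYPES, DEFAULT_AGE_BANDS
from .pathways import COSTED_STEPS

__all__ = [
    "CostTable",
    "DecrementTable",
    "EconParams",
    "DELAY_MONTHS",
    "total_cost",
    "discount_factor",
    "life_years_lost",
    "incremental_summary",
]

DELAY_MONTHS = (2, 4, 6)


def _pence(gbp: float) -> int:
    return int(round(float(gbp) * 100))


#: Synthetic default unit costs (2022 GBP).  Orders of magnitude follow
#: published NHS reference costs / PSSRU figures, but these are placeholders
#: for user-supplied tariffs, not the originals.
DEFAULT_UNIT_COSTS_GBP: dict[str, float] = {
    "gp-consult": 39.00,
    "psa-test": 5.00,
    "pinpoint-test": 35.20,
    "triage-appt": 170.00,
    "mpmri": 250.00,
    "trus-biopsy": 450.00,
    "mdt": 110.00,
    "cystoscopy": 390.00,
    "ultrasound": 55.00,
    "x-ray": 30.00,
}


@dataclass(frozen=True)
class CostTable:
    """Unit costs per pathway step, with an inflation multiplier to 2022 GBP."""

    unit_costs_gbp: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNIT_COSTS_GBP)
    )
    inflation_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.inflation_factor <= 0:
            raise ConfigurationError("inflation_factor must be > 0")
        costs = {str(k): float(v) for k, v in self.unit_costs_gbp.items()}
        if any(v < 0 for v in costs.values()):
            raise ConfigurationError("unit costs must be >= 0")
        object.__setattr__(self, "unit_costs_gbp", costs)

    def pence(self, step: str) -> int:
        if step not in self.unit_costs_gbp:
            raise ConfigurationError(f"no unit cost configured for step {step!r}")
        return _pence(self.unit_costs_gbp[step] * self.inflation_factor)

    def pence_map(self) -> dict[str, int]:
        return {step: self.pence(step) for step in self.unit_costs_gbp}

    @classmethod
    def from_csv(cls, path: str | Path, inflation_factor: float = 1.0) -> "CostTable":
        """Load from a CSV with header ``step,unit_cost,ref_year``."""
        costs: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                costs[row["step"]] = float(row["unit_cost"])
        return cls(costs, inflation_factor)


def total_cost(p: Patient, table: CostTable) -> int:
    """Sum of inflated unit costs over the steps the patient traversed, in
    pennies.  The patient's own ledger is ignored so this doubles as an
    audit of it."""
    return sum(table.pence(name) for name, _ in p.timeline if name in COSTED_STEPS)


def _synthetic_decrements() -> dict[tuple[str, str, int], float]:
    # Synthetic placeholder decrements (life years lost per patient,
    # undiscounted).  Shaped to be monotone in delay and larger for the more
    # aggressive bladder/kidney cancers than for prostate; younger bands
    # (more expected life years at stake over 10 years) lose more.
    base6 = {"prostate": 0.010, "bladder": 0.200, "kidney": 0.120}
    delay_scale = {2: 0.25, 4: 0.55, 6: 1.0}
    age_scale = dict(zip(DEFAULT_AGE_BANDS, (1.3, 1.0, 0.6)))
    return {
        (s, band, d): base6[s] * delay_scale[d] * age_scale[band]
        for s in SUBTYPES
        for band in DEFAULT_AGE_BANDS
        for d in DELAY_MONTHS
    }


@dataclass(frozen=True)
class DecrementTable:
    """Life years lost per patient for a 2-, 4- or 6-month referral delay,
    by cancer subtype and age band.

    Ships with clearly synthetic defaults (see :func:`_synthetic_decrements`);
    real tables are loaded with :meth:`from_csv`.
    """

    values: Mapping[tuple[str, str, int], float] = field(default_factory=_synthetic_decrements)
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS

    def __post_init__(self) -> None:
        vals = {(str(s), str(b), int(d)): float(v) for (s, b, d), v in self.values.items()}
        if any(v < 0 for v in vals.values()):
            raise ConfigurationError("decrements must be >= 0")
        for s in {k[0] for k in vals}:
            for b in {k[1] for k in vals if k[0] == s}:
                seq = [vals.get((s, b, d)) for d in DELAY_MONTHS if (s, b, d) in vals]
                if any(x > y for x, y in zip(seq, seq[1:])):
                    raise ConfigurationError(
                        f"decrements must be non-decreasing in delay for ({s}, {b})"
                    )
        object.__setattr__(self, "values", vals)

    def lookup(self, subtype: str, age_band: str, delay_months: int) -> float:
        if delay_months == 0:
            return 0.0
        key = (subtype, age_band, int(delay_months))
        if key not in self.values:
            raise ConfigurationError(f"decrement table has no cell for {key}")
        return self.values[key]

    def as_array(self, age_bands: Sequence[str]) -> np.ndarray:
        """Dense array [subtype, age band, delay index over (0, 2, 4, 6)]."""
        out = np.zeros((len(SUBTYPES), len(age_bands), 4))
        for si, s in enumerate(SUBTYPES):
            for bi, b in enumerate(age_bands):
                for di, d in enumerate(DELAY_MONTHS, start=1):
                    out[si, bi, di] = self.lookup(s, b, d)
        return out

    @classmethod
    def from_csv(cls, path: str | Path, age_bands: Sequence[str] = DEFAULT_AGE_BANDS) -> "DecrementTable":
        """Load from a CSV with header ``subtype,age_band,delay_months,ly_lost``."""
        vals: dict[tuple[str, str, int], float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                vals[(row["subtype"], row["age_band"], int(row["delay_months"]))] = float(
                    row["ly_lost"]
                )
        return cls(vals, tuple(age_bands))


@dataclass(frozen=True)
class EconParams:
    """Economic evaluation settings.

    discount_rate
        Annual discount rate applied to life years (0.035 = NICE base case).
    wtp
        Willingness to pay per QALY gained, GBP (20,000 = NICE threshold).
    accrual
        How the 10-year survival decrement is spread for discounting:
        ``"uniform"`` (equal fractions in years 1..horizon) or ``"lump"``
        (all at ``lump_year``).
    """

    discount_rate: float = 0.035
    wtp: float = 20_000.0
    qaly_equals_ly: bool = True
    accrual: str = "uniform"
    horizon_years: int = 10
    lump_year: float = 5.0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")
        if self.wtp <= 0:
            raise ConfigurationError("wtp must be > 0")
        if self.accrual not in ("uniform", "lump"):
            raise ConfigurationError(f"unknown accrual mode {self.accrual!r}")


def discount_factor(econ: EconParams) -> float:
    """Multiplier turning an undiscounted decrement into its present value."""
    r = econ.discount_rate
    if econ.accrual == "lump":
        return float((1.0 + r) ** (-econ.lump_year))
    years = np.arange(1, econ.horizon_years + 1)
    return float(np.mean((1.0 + r) ** (-years)))


def life_years_lost(p: Patient, table: DecrementTable, econ: EconParams) -> float:
    """Discounted life years lost for one patient.

    Zero for non-cancers and for cancers diagnosed within 28 days of
    referral; otherwise the subtype/age-band decrement for the patient's
    ``referral_delay_months`` (2 for a >28-day wait, 6 for a missed case).
    """
    if not p.has_cancer or p.referral_delay_months == 0:
        return 0.0
    raw = table.lookup(p.subtype, p.age_band, p.referral_delay_months)
    return raw * discount_factor(econ)


def incremental_summary(
    sc_results: Mapping[str, Sequence[float]] | "object",
    test_results: Mapping[str, Sequence[float]] | "object",
    econ: EconParams,
) -> dict[str, float]:
    """Incremental cost, life years and net monetary benefit, test arm vs
    standard care.

    Each argument must expose per-replication ``cost_gbp`` and ``ly_lost``
    sequences of equal length (paired by replication / common random
    numbers).  Returns means and percentile 95 % intervals.
    """
    sc_cost = np.asarray(sc_results["cost_gbp"], dtype=float)
    sc_ly = np.asarray(sc_results["ly_lost"], dtype=float)
    t_cost = np.asarray(test_results["cost_gbp"], dtype=float)
    t_ly = np.asarray(test_results["ly_lost"], dtype=float)
    if not (len(sc_cost) == len(t_cost) == len(sc_ly) == len(t_ly)):
        raise ConfigurationError("paired results must have matching replication counts")
    if len(sc_cost) == 0:
        raise ConfigurationError("empty result set")
    d_cost = t_cost - sc_cost
    d_ly = sc_ly - t_ly  # life years *gained* by the test arm
    inmb = econ.wtp * d_ly - d_cost

    def ci(x: np.ndarray) -> tuple[float, float]:
        return float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5))

    out = {
        "delta_cost": float(d_cost.mean()),
        "delta_ly": float(d_ly.mean()),
        "inmb": float(inmb.mean()),
    }
    out["delta_cost_lo"], out["delta_cost_hi"] = ci(d_cost)
    out["delta_ly_lo"], out["delta_ly_hi"] = ci(d_ly)
    out["inmb_lo"], out["inmb_hi"] = ci(inmb)
    return out
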
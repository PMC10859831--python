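"""Scenario and grid definitions, capacity calibration, configuration IO.

A *scenario* pins one model (prostate or bladder/kidney pathway) under one
volume x provider-performance condition: cohort parameters, the excess-delay
distribution, the diagnostic-cascade probabilities, and either an explicit
capacity rate or a target standard-care TWW fraction from which capacity is
calibrated by bisection.  A *grid* bundles scenarios with the cost table,
decrement table, economic settings and the arms to compare.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from .cohort import CohortParams, ConfigurationError, HORIZON_DAYS, generate_cohort
from .economics import CostTable, DecrementTable, EconParams
from .engine import CapacitySchedule, ExcessDelayDist, calibrate_capacity_rate
from .pathways import ARMS, CascadeProbs

__all__ = [
    "Scenario",
    "Grid",
    "default_grid",
    "load_grid",
    "ensure_calibrated",
    "required_schedule_days",
    "RUNOUT_TAIL_DAYS",
]

#: Days simulated past the last referral event so late referrals can drain.
RUNOUT_TAIL_DAYS = 90
#: Fixed seed of the calibration pre-run: capacity is a property of the
#: scenario (it stands in for observed provider throughput), so it must not
#: change with the analysis seed.
CALIBRATION_SEED = 20211201
CALIBRATION_REPS = 3


def required_schedule_days(horizon_days: int = HORIZON_DAYS, fn_delay_days: int = 183) -> int:
    """Days of capacity needed: horizon + latest possible re-referral + tail."""
    return horizon_days + fn_delay_days + RUNOUT_TAIL_DAYS + 1


@dataclass
class Scenario:
    """One volume x performance condition for one model."""

    label: str
    model: str  # "prostate" | "bladder_kidney" | "mixed"
    cohort: CohortParams
    volume_level: str = ""
    performance_level: str = ""
    target_tww: float | None = None
    capacity_rate: float | None = None
    capacity: CapacitySchedule | None = None
    excess: ExcessDelayDist = field(default_factory=ExcessDelayDist)
    cascade: CascadeProbs = field(default_factory=CascadeProbs)
    #: "window": capacity is within-window throughput, breaches resolve with
    #: an empirical 1-16 day excess delay; "backlog": pure waiting-list queue.
    mechanism: str = "window"
    tww_window_days: int = 14
    horizon_days: int = HORIZON_DAYS

    def __post_init__(self) -> None:
        if self.model not in ("prostate", "bladder_kidney", "mixed"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.mechanism not in ("window", "backlog"):
            raise ConfigurationError(f"unknown queue mechanism {self.mechanism!r}")
        if self.capacity is None and self.capacity_rate is None and self.target_tww is None:
            raise ConfigurationError(
                f"scenario {self.label!r} needs a capacity schedule, a capacity_rate "
                "or a target_tww to calibrate from"
            )

    @property
    def key(self) -> int:
        """Stable integer identifying the scenario in seed derivation."""
        return zlib.crc32(self.label.encode())

    def schedule(self) -> CapacitySchedule:
        if self.capacity is not None:
            return self.capacity
        ensure_calibrated(self)
        n_days = required_schedule_days(self.horizon_days)
        self.capacity = CapacitySchedule.from_rate(self.capacity_rate, n_days)
        return self.capacity


def ensure_calibrated(scenario: Scenario) -> float:
    """Resolve the scenario's capacity rate, calibrating it if necessary.

    Calibration inverts the standard-care TWW fraction: bisection on the
    daily slot rate until the simulated first-come-first-served fraction of
    referrals seen within 14 days matches ``target_tww`` on a small set of
    calibration cohorts drawn with a fixed seed.
    """
    if scenario.capacity_rate is not None:
        return scenario.capacity_rate
    if scenario.target_tww is None:
        raise ConfigurationError(f"scenario {scenario.label!r} has neither capacity nor target")
    demands = []
    for i in range(CALIBRATION_REPS):
        rng = np.random.default_rng(
            np.random.SeedSequence([CALIBRATION_SEED, scenario.key, i])
        )
        cohort = generate_cohort(scenario.cohort, scenario.model, scenario.horizon_days, rng)
        demands.append(cohort.arrival_day.astype(np.int64))
    rate = calibrate_capacity_rate(
        demands, scenario.target_tww, required_schedule_days(scenario.horizon_days)
    )
    scenario.capacity_rate = rate
    return rate


@dataclass
class Grid:
    """A set of scenarios plus shared economic inputs and arms."""

    scenarios: list[Scenario]
    costs: CostTable = field(default_factory=CostTable)
    decrements: DecrementTable = field(default_factory=DecrementTable)
    econ: EconParams = field(default_factory=EconParams)
    arms: tuple[str, ...] = ARMS

    def __post_init__(self) -> None:
        labels = [s.label for s in self.scenarios]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"scenario labels must be unique, got {labels}")
        for arm in self.arms:
            if arm not in ARMS:
                raise ConfigurationError(f"unknown arm {arm!r}")

    def scenario(self, label: str) -> Scenario:
        for s in self.scenarios:
            if s.label == label:
                return s
        raise ConfigurationError(f"no scenario labelled {label!r}")


def default_grid() -> Grid:
    """The default toy grid: both models under (high volume, poor
    performance) and (low volume, high performance) conditions.

    Volumes are provider-scale annual urgent referral counts; performance
    targets are standard-care TWW fractions of 0.70 (poor) and 0.90 (high).
    Volumes are large enough that the arm-ordering properties implied by the
    priority discipline are not masked by replication-level binomial noise.
    """
    base = CohortParams()
    spec = [
        ("prostate-highvol-poor", "prostate", 7200.0, "high", "poor", 0.70),
        ("prostate-lowvol-high", "prostate", 2400.0, "low", "high", 0.90),
        ("bk-highvol-poor", "bladder_kidney", 6000.0, "high", "poor", 0.70),
        ("bk-lowvol-high", "bladder_kidney", 2000.0, "low", "high", 0.90),
    ]
    scenarios = [
        Scenario(
            label=label,
            model=model,
            cohort=base.with_(annual_referrals=volume),
            volume_level=vol_level,
            performance_level=perf_level,
            target_tww=target,
        )
        for label, model, volume, vol_level, perf_level, target in spec
    ]
    return Grid(scenarios=scenarios)


def _cohort_from_dict(d: dict) -> CohortParams:
    kwargs = {}
    for k in (
        "annual_referrals",
        "monthly_weights",
        "prevalence",
        "prostate_share",
        "bladder_share_of_bk",
        "age_bands",
        "seed",
    ):
        if k in d:
            kwargs[k] = d[k]
    if "age_band_probs" in d:
        kwargs["age_band_probs"] = {k: tuple(v) for k, v in d["age_band_probs"].items()}
    if "risk_matrix" in d:
        rm = d["risk_matrix"]
        kwargs["risk_matrix"] = {
            True: tuple(rm.get("cancer", rm.get(True))),
            False: tuple(rm.get("no_cancer", rm.get(False))),
        }
    return CohortParams(**kwargs)


def load_grid(path: str | Path) -> Grid:
    """Load a grid from a YAML configuration file.

    Top-level keys: ``scenarios`` (list), and optional ``costs`` (mapping or
    ``cost_csv`` path), ``inflation_factor``, ``decrement_csv``, ``econ``
    (mapping of :class:`EconParams` fields) and ``arms``.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "scenarios" not in cfg:
        raise ConfigurationError(f"{path} must define a 'scenarios' list")
    inflation = float(cfg.get("inflation_factor", 1.0))
    if "cost_csv" in cfg:
        costs = CostTable.from_csv(path.parent / cfg["cost_csv"], inflation)
    elif "costs" in cfg:
        costs = CostTable(cfg["costs"], inflation)
    else:
        costs = CostTable(inflation_factor=inflation)
    if "decrement_csv" in cfg:
        decrements = DecrementTable.from_csv(path.parent / cfg["decrement_csv"])
    else:
        decrements = DecrementTable()
    econ = EconParams(**cfg.get("econ", {}))
    scenarios = []
    for sd in cfg["scenarios"]:
        cascade = CascadeProbs(**sd.get("cascade", {}))
        excess = (
            ExcessDelayDist(tuple(sd["excess"]["support"]), tuple(sd["excess"]["probs"]))
            if "excess" in sd
            else ExcessDelayDist()
        )
        scenarios.append(
            Scenario(
                label=sd["label"],
                model=sd.get("model", "mixed"),
                cohort=_cohort_from_dict(sd.get("cohort", {})),
                volume_level=sd.get("volume_level", ""),
                performance_level=sd.get("performance_level", ""),
                target_tww=sd.get("target_tww"),
                capacity_rate=sd.get("capacity_rate"),
                excess=excess,
                cascade=cascade,
                mechanism=sd.get("mechanism", "window"),
            )
        )
    return Grid(
        scenarios=scenarios,
        costs=costs,
        decrements=decrements,
        econ=econ,
        arms=tuple(cfg.get("arms", ARMS)),
    )
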
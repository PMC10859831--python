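"""Deterministic replication batches, probabilistic sensitivity analysis
and result summaries.

Deterministic analysis: 650 replications per scenario by default, each with
its own random-number substreams, common random numbers across arms within
a replication.  PSA: 1,200 parameter draws by default -- probabilities from
beta/Dirichlet families and costs/decrements from gamma families, each
moment-matched to the deterministic value with a configurable coefficient
of variation -- one stochastic replication per draw (configurable inner
replications).  Capacity stays at its calibrated value across PSA draws:
it stands in for observed provider throughput rather than an uncertain
parameter.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortParams, ConfigurationError
from .economics import (
    CostTable,
    DecrementTable,
    EconParams,
    incremental_summary,
)
from .pathways import ArmPolicy, CascadeProbs
from .replication import ReplicationResult, make_shared_draws, simulate_arm
from .scenarios import Grid

__all__ = ["run_deterministic", "run_psa", "summarize", "PSADraw", "sample_psa_params"]

_STREAM_PSA = 5


def _results_frame(rows: list[ReplicationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])


def run_deterministic(
    grid: Grid,
    n_reps: int = 650,
    master_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario x arm of the grid for ``n_reps`` replications.

    Returns one row per (scenario, arm, replication); rows with equal
    (scenario, rep) share their random draws across arms.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    for s in grid.scenarios:
        s.schedule()  # calibrate once up front
    policies = [ArmPolicy.for_arm(a) for a in grid.arms]
    rows: list[ReplicationResult] = []
    for scenario in grid.scenarios:
        for rep in range(n_reps):
            shared = make_shared_draws(scenario, rep, master_seed)
            for policy in policies:
                rows.append(
                    simulate_arm(
                        scenario, policy, shared, grid.costs, grid.decrements, grid.econ, rep
                    )
                )
    return _results_frame(rows)


# --------------------------------------------------------------------------
# PSA parameter sampling


@dataclass(frozen=True)
class PSADraw:
    """One sampled parameter set of the probabilistic sensitivity analysis."""

    index: int
    prevalence: float
    prostate_share: float
    bladder_share_of_bk: float
    risk_matrix: dict
    unit_costs_gbp: dict
    decrements: dict
    mpmri_pos_nocancer: float


def _beta_mm(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Beta draw moment-matched to (mean, cv * mean); degenerate at cv=0."""
    if cv == 0 or mean <= 0.0 or mean >= 1.0:
        return float(mean)
    var = (cv * mean) ** 2
    var = min(var, 0.999 * mean * (1 - mean))
    k = mean * (1 - mean) / var - 1.0
    return float(rng.beta(mean * k, (1 - mean) * k))


def _gamma_mm(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0 or mean <= 0:
        return float(mean)
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def _dirichlet_mm(rng: np.random.Generator, row: tuple[float, ...], cv: float) -> tuple[float, ...]:
    """Dirichlet draw with component SDs ~ cv * mean (matched on the largest
    component); zero-probability components stay exactly zero."""
    if cv == 0:
        return tuple(row)
    m = max(row)
    var = (cv * m) ** 2
    conc = max(m * (1 - m) / var - 1.0, 1e-6)
    nz = [i for i, p in enumerate(row) if p > 0]
    draw = rng.dirichlet([conc * row[i] for i in nz])
    out = [0.0] * len(row)
    for j, i in enumerate(nz):
        out[i] = float(draw[j])
    return tuple(out)


def sample_psa_params(
    rng: np.random.Generator,
    index: int,
    grid: Grid,
    base_cohort: CohortParams,
    base_cascade: CascadeProbs,
    cv: float = 0.1,
) -> PSADraw:
    """Sample one PSA parameter set around the deterministic values."""
    if cv < 0:
        raise ConfigurationError("PSA coefficient of variation must be >= 0")
    rm = {
        status: _dirichlet_mm(rng, base_cohort.risk_matrix[status], cv)
        for status in (True, False)
    }
    costs = {k: _gamma_mm(rng, v, cv) for k, v in grid.costs.unit_costs_gbp.items()}
    # one multiplier per (subtype, age band): delays within a group move
    # together, so the monotone-in-delay structure of the table is preserved
    groups = {(s, b) for (s, b, _) in grid.decrements.values}
    mult = {g: _gamma_mm(rng, 1.0, cv) for g in sorted(groups)}
    decs = {k: v * mult[(k[0], k[1])] for k, v in grid.decrements.values.items()}
    return PSADraw(
        index=index,
        prevalence=_beta_mm(rng, base_cohort.prevalence, cv),
        prostate_share=_beta_mm(rng, base_cohort.prostate_share, cv),
        bladder_share_of_bk=_beta_mm(rng, base_cohort.bladder_share_of_bk, cv),
        risk_matrix=rm,
        unit_costs_gbp=costs,
        decrements=decs,
        mpmri_pos_nocancer=_beta_mm(rng, base_cascade.mpmri_pos_nocancer, cv),
    )


def run_psa(
    grid: Grid,
    n_draws: int = 1200,
    master_seed: int = 0,
    cv: float = 0.1,
    inner_reps: int = 1,
) -> pd.DataFrame:
    """Probabilistic sensitivity analysis over the grid.

    One parameter draw per iteration, ``inner_reps`` stochastic replications
    per draw (default 1: first- and second-order uncertainty mixed, matching
    a draws-equal-replications reading; raise it to average out first-order
    noise within each draw).  The returned frame has one row per
    (scenario, arm, draw, inner rep) with the draw index in ``draw``.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    for s in grid.scenarios:
        s.schedule()
    policies = [ArmPolicy.for_arm(a) for a in grid.arms]
    rows: list[dict] = []
    for draw_idx in range(n_draws):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, _STREAM_PSA, draw_idx])
        )
        for scenario in grid.scenarios:
            draw = sample_psa_params(rng, draw_idx, grid, scenario.cohort, scenario.cascade, cv)
            psa_cohort = scenario.cohort.with_(
                prevalence=draw.prevalence,
                prostate_share=draw.prostate_share,
                bladder_share_of_bk=draw.bladder_share_of_bk,
                risk_matrix=draw.risk_matrix,
            )
            psa_scenario = dataclasses.replace(
                scenario,
                cohort=psa_cohort,
                cascade=dataclasses.replace(
                    scenario.cascade, mpmri_pos_nocancer=draw.mpmri_pos_nocancer
                ),
            )
            psa_scenario.capacity = scenario.capacity
            psa_scenario.capacity_rate = scenario.capacity_rate
            psa_costs = CostTable(draw.unit_costs_gbp, grid.costs.inflation_factor)
            psa_decs = DecrementTable(draw.decrements, grid.decrements.age_bands)
            for k in range(inner_reps):
                # replication substreams are shared with the deterministic
                # analysis (CRN): a zero-variance PSA then reuses the same
                # stochastic replications, so parameter uncertainty is the
                # only systematic difference between the two analyses
                rep = draw_idx * inner_reps + k
                shared = make_shared_draws(psa_scenario, rep, master_seed)
                for policy in policies:
                    r = simulate_arm(
                        psa_scenario, policy, shared, psa_costs, psa_decs, grid.econ, rep
                    )
                    row = r.as_dict()
                    row["draw"] = draw_idx
                    rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    results: pd.DataFrame,
    grid: Grid,
    baseline_arm: str = "standard",
) -> pd.DataFrame:
    """Per scenario x arm means with percentile 95 % intervals, plus
    incremental columns (cost, life years gained, INMB) versus the baseline
    arm, paired by replication."""
    if results.empty:
        raise ConfigurationError("empty result set")
    pair_col = "draw" if "draw" in results.columns else "rep"
    out_rows = []
    for scenario, sdf in results.groupby("scenario", sort=False):
        base = sdf[sdf["arm"] == baseline_arm].sort_values(pair_col)
        for arm, adf in sdf.groupby("arm", sort=False):
            adf = adf.sort_values(pair_col)
            if len(adf) == 1:
                warnings.warn(
                    f"single replication for {scenario}/{arm}: intervals are degenerate"
                )

            def mci(col):
                x = adf[col].to_numpy(dtype=float)
                return x.mean(), np.percentile(x, 2.5), np.percentile(x, 97.5)

            row = {"scenario": scenario, "arm": arm, "n_reps": len(adf)}
            for col in ("tww_overall", "tww_cancer", "tww_noncancer", "mean_wait",
                        "cost_gbp", "ly_lost"):
                m, lo, hi = mci(col)
                row[col] = m
                row[f"{col}_lo"], row[f"{col}_hi"] = lo, hi
            if arm != baseline_arm and len(base) == len(adf):
                inc = incremental_summary(
                    {"cost_gbp": base["cost_gbp"], "ly_lost": base["ly_lost"]},
                    {"cost_gbp": adf["cost_gbp"], "ly_lost": adf["ly_lost"]},
                    grid.econ,
                )
                row.update(inc)
                row["delta_cost_per_patient"] = inc["delta_cost"] / adf["n_patients"].mean()
            out_rows.append(row)
    return pd.DataFrame(out_rows)


def ce_plane(results: pd.DataFrame, baseline_arm: str = "standard") -> pd.DataFrame:
    """Per-draw (incremental cost, incremental life years) pairs for
    cost-effectiveness-plane scatter plots."""
    pair_col = "draw" if "draw" in results.columns else "rep"
    rows = []
    for (scenario, arm), adf in results.groupby(["scenario", "arm"], sort=False):
        if arm == baseline_arm:
            continue
        base = results[(results["scenario"] == scenario) & (results["arm"] == baseline_arm)]
        merged = adf.merge(base, on=["scenario", pair_col], suffixes=("", "_base"))
        rows.append(
            pd.DataFrame(
                {
                    "scenario": scenario,
                    "arm": arm,
                    pair_col: merged[pair_col],
                    "delta_cost": merged["cost_gbp"] - merged["cost_gbp_base"],
                    "delta_ly": merged["ly_lost_base"] - merged["ly_lost"],
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
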
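"""Seeded simulation runs and the factorial HCF x SD experiment.

Run length is measured in animal-unit-months (AUMs): one AUM is one
animal-unit grazing for one month (30.44 days by default).  A run stops
once ``grazing_days * n_cows * au_per_cow / days_per_month`` reaches the
configured target, or when the pasture can no longer support the herd's
daily demand (status ``forage_exhausted``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .errors import ConfigurationError
from .engine import Simulation
from .herd import ROLE_FOLLOWER, ROLE_INDEPENDENT, ROLE_LEADER, SimConfig
from .landscape import LandscapeConfig, Pasture

__all__ = [
    "RunSummary",
    "DailyIntakeRecord",
    "RunResult",
    "run_simulation",
    "factorial_experiment",
    "expected_grazing_days",
    "derive_run_seed",
]


@dataclass(frozen=True)
class RunSummary:
    """End-of-run record for one simulation (one CSV row)."""

    run_id: int
    hcf: float
    sd: float
    seed: int
    n_cows: int
    deaths: int
    grazing_days: int
    ticks: int
    aums_consumed: float
    mean_daily_msal_mg: float
    sd_daily_msal_mg: float
    mean_max_daily_msal_mg: float
    sd_max_daily_msal_mg: float
    cv_total_msal: float
    site_changes_per_day: float
    mean_travel_m_per_day: float
    sd_times_grazed: float
    herd_move_fraction: float
    deaths_leader: int
    deaths_follower: int
    deaths_independent: int
    total_consumed_g: float
    status: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class DailyIntakeRecord:
    """One cow-day of intake (one row of the daily CSV)."""

    run_id: int
    grazing_day: int
    cow_id: int
    role: str
    daily_msal_mg: float
    daily_forage_g: float
    died: bool


@dataclass
class RunResult:
    summary: RunSummary
    daily: pd.DataFrame | None
    simulation: Simulation


def expected_grazing_days(
    target_aums: float,
    n_cows: int,
    au_per_cow: float = 1.1,
    days_per_month: float = 30.44,
) -> int:
    """Grazing-days needed to consume *target_aums* (stopping-rule arithmetic)."""
    return math.ceil(target_aums * days_per_month / (n_cows * au_per_cow))


def _fresh_pasture(landscape: Pasture | LandscapeConfig) -> Pasture:
    """A pristine pasture: regenerate from config, or reset a Pasture copy."""
    if isinstance(landscape, LandscapeConfig):
        return Pasture.generate(landscape)
    return Pasture(
        accessible=landscape.accessible,
        forage_g=landscape.initial_forage_g.copy(),
        initial_forage_g=landscape.initial_forage_g,
        n_forage_g=landscape.n_forage_g,
        msal_mg=landscape.initial_msal_mg.copy(),
        initial_msal_mg=landscape.initial_msal_mg,
        times_grazed=np.zeros(landscape.shape, dtype=np.int64),
        water_cells=set(landscape.water_cells),
        index=landscape.index,
        config=landscape.config,
    )


def run_simulation(
    landscape: Pasture | LandscapeConfig,
    config: SimConfig,
    run_id: int = 0,
    collect_daily: bool = True,
    check_invariants_every_tick: bool = False,
    max_ticks: int | None = None,
) -> RunResult:
    """Run one simulation to its AUM target; fully seed-deterministic."""
    pasture = _fresh_pasture(landscape)
    sim = Simulation(
        pasture,
        config,
        collect_daily=collect_daily,
        check_invariants_every_tick=check_invariants_every_tick,
    )
    limit = max_ticks if max_ticks is not None else 10_000_000
    while sim.aums_consumed < config.target_aums and not sim.forage_exhausted:
        if sim.tick_index >= limit:
            break
        sim.tick()
    status = "forage_exhausted" if sim.forage_exhausted else "completed"
    if sim.tick_index >= limit and sim.aums_consumed < config.target_aums:
        status = "tick_limit"

    daily = None
    if collect_daily:
        daily = pd.DataFrame(
            sim.daily_records,
            columns=[
                "grazing_day",
                "cow_id",
                "role",
                "daily_msal_mg",
                "daily_forage_g",
                "died",
            ],
        )
        daily.insert(0, "run_id", run_id)
    if daily is not None and len(daily):
        stats = metrics.intake_statistics(daily)
    else:
        stats = metrics.IntakeStats(*(float("nan"),) * 5)
    days = max(sim.grazing_day, 1)
    moves = sim.herd_moves + sim.env_moves
    role_deaths = {ROLE_LEADER: 0, ROLE_FOLLOWER: 0, ROLE_INDEPENDENT: 0}
    for ev in sim.death_events:
        role_deaths[ev.role] += 1
    summary = RunSummary(
        run_id=run_id,
        hcf=config.hcf,
        sd=config.sd,
        seed=config.seed,
        n_cows=sim.n,
        deaths=len(sim.death_events),
        grazing_days=sim.grazing_day,
        ticks=sim.tick_index,
        aums_consumed=sim.aums_consumed,
        mean_daily_msal_mg=stats.mean_daily,
        sd_daily_msal_mg=stats.sd_daily,
        mean_max_daily_msal_mg=stats.mean_max,
        sd_max_daily_msal_mg=stats.sd_max,
        cv_total_msal=stats.cv_total,
        site_changes_per_day=sim.site_change_count / days,
        mean_travel_m_per_day=(
            float(np.mean(sim.daily_travel_means_m))
            if sim.daily_travel_means_m
            else float("nan")
        ),
        sd_times_grazed=metrics.grazing_heterogeneity(pasture),
        herd_move_fraction=(sim.herd_moves / moves) if moves else float("nan"),
        deaths_leader=role_deaths[ROLE_LEADER],
        deaths_follower=role_deaths[ROLE_FOLLOWER],
        deaths_independent=role_deaths[ROLE_INDEPENDENT],
        total_consumed_g=sim.total_consumed_g,
        status=status,
    )
    return RunResult(summary=summary, daily=daily, simulation=sim)


def derive_run_seed(base_seed: int, hcf: float, sd: float, rep: int) -> int:
    """Stable per-run seed so any single run reproduces in isolation."""
    ss = np.random.SeedSequence(
        [int(base_seed), int(round(hcf * 1000)), int(round(sd * 1000)), int(rep)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def factorial_experiment(
    landscape: Pasture | LandscapeConfig,
    hcf_levels: list[float],
    sd_levels: list[float],
    reps: int,
    base_seed: int = 0,
    base_config: SimConfig | None = None,
    collect_daily: bool = False,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Full factorial of HCF x SD levels with *reps* replicate seeds each.

    One RunSummary row per (hcf, sd, rep); rows are appended to *out_csv*
    as they complete, so a crashed sweep keeps its finished runs.
    """
    if reps < 1 or not hcf_levels or not sd_levels:
        raise ConfigurationError("need >= 1 level of each factor and reps >= 1")
    if len(set(hcf_levels)) != len(hcf_levels) or len(set(sd_levels)) != len(sd_levels):
        raise ConfigurationError("duplicate factor levels")
    if base_config is None:
        base_config = SimConfig()
    rows = []
    run_id = 0
    wrote_header = False
    for hcf in hcf_levels:
        for sd in sd_levels:
            for rep in range(reps):
                cfg = dataclasses.replace(
                    base_config,
                    hcf=hcf,
                    sd=sd,
                    seed=derive_run_seed(base_seed, hcf, sd, rep),
                )
                result = run_simulation(
                    landscape, cfg, run_id=run_id, collect_daily=collect_daily
                )
                row = result.summary.to_dict()
                rows.append(row)
                if out_csv is not None:
                    pd.DataFrame([row]).to_csv(
                        out_csv,
                        mode="a" if wrote_header else "w",
                        header=not wrote_header,
                        index=False,
                    )
                    wrote_header = True
                run_id += 1
    return pd.DataFrame(rows)
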
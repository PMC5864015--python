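"""Cow population and derivation of behavioral constants.

The two experimental factors are the herd-cohesion-factor (HCF, 1-10) and
the instantaneous stocking density (SD, animal-units per hectare).  HCF
maps geometrically onto two behavioral constants: the desired mean distance
to herdmates (100 m at HCF 1 down to 10 m at HCF 10) and the space
allocated per cow when a new feeding site is chosen (1000 m^2 down to
10 m^2).  SD times the accessible pasture area, divided by 1.1 AU per
500 kg cow, gives the herd size.

Each cow carries an individual lethal tolerance for MSAL alkaloids
(normal, mean 4000 mg, sd 333.33 mg, truncated to +/-25% of the mean) and
a larkspur attraction factor (normal, mean 1.0, sd 0.083, truncated to
[0.75, 1.25]) scaling how much alkaloid it ingests from a cell relative
to its forage intake.  Roles are leader (5%), follower (85%) and
independent (10%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .landscape import Pasture

__all__ = [
    "SimConfig",
    "BehaviorParams",
    "Cow",
    "derive_behavior_params",
    "create_herd",
    "ROLE_LEADER",
    "ROLE_FOLLOWER",
    "ROLE_INDEPENDENT",
    "ROLE_FRACTIONS",
]

ROLE_LEADER = "leader"
ROLE_FOLLOWER = "follower"
ROLE_INDEPENDENT = "independent"
#: role quota order doubles as the largest-remainder tie-break priority
ROLE_FRACTIONS = (
    (ROLE_LEADER, 0.05),
    (ROLE_FOLLOWER, 0.85),
    (ROLE_INDEPENDENT, 0.10),
)

MSAL_TOLERANCE_MEAN_MG = 4000.0
MSAL_TOLERANCE_SD_MG = 333.33
ATTRACTION_MEAN = 1.0
ATTRACTION_SD = 0.083


@dataclass(frozen=True)
class SimConfig:
    """User-facing simulation inputs.

    ``target_aums`` sets run length in animal-unit-months; one AUM is one
    1.0-AU animal grazing for ``days_per_month`` grazing-days.  The daily
    herd-mean consumption that advances the clock by one grazing-day is
    ``daily_intake_g`` (12.5 kg = 2.5% of a 500 kg cow's body weight).
    """

    hcf: float = 4.0
    sd: float = 0.5
    kgs_per_hectare: float = 500.0
    median_plant_mass_g: float = 3.5
    msal_concentration_mg_per_g: float = 3.0
    target_aums: float = 9.3
    seed: int = 0
    au_per_cow: float = 1.1
    days_per_month: float = 30.44
    daily_intake_g: float = 12_500.0
    site_tolerance: int | None = None  # override the herd-size heuristic
    water_threshold_frac: float = 0.2  # "hydration approaching zero"

    def __post_init__(self):
        if not (1.0 <= self.hcf <= 10.0):
            raise ConfigurationError("hcf must lie in [1, 10]")
        if self.sd <= 0:
            raise ConfigurationError("stocking density must be > 0")
        if self.target_aums <= 0:
            raise ConfigurationError("target_aums must be > 0")
        if self.daily_intake_g <= 0 or self.days_per_month <= 0:
            raise ConfigurationError("daily intake and month length must be > 0")


@dataclass(frozen=True)
class BehaviorParams:
    """Constants derived from (HCF, SD, pasture area)."""

    n_cows: int
    herd_distance_m: float
    space_per_cow_m2: float
    site_tolerance: int
    hydration_capacity_g: float
    herdmate_count: int = 20

    def __post_init__(self):
        if self.n_cows < 1:
            raise ConfigurationError("herd must contain at least one cow")
        if not (10.0 - 1e-9 <= self.herd_distance_m <= 100.0 + 1e-9):
            raise ConfigurationError("herd_distance_m out of [10, 100]")
        if not (10.0 - 1e-9 <= self.space_per_cow_m2 <= 1000.0 + 1e-9):
            raise ConfigurationError("space_per_cow_m2 out of [10, 1000]")
        if self.site_tolerance < 2:
            raise ConfigurationError("site_tolerance must be >= 2")


@dataclass
class Cow:
    """One 500 kg (1.1 AU) cow agent."""

    id: int
    role: str
    x: float  # meters; column + 0.5
    y: float  # meters; row + 0.5
    heading_deg: float
    msal_tolerance_mg: float
    larkspur_attraction: float
    msal_level_mg: float = 0.0
    cumulative_consumption_g: float = 0.0
    day_consumption_g: float = 0.0
    day_msal_mg: float = 0.0
    max_day_msal_mg: float = 0.0
    total_msal_mg: float = 0.0
    hydration_g: float = 0.0
    ready_to_go: int = 0
    death_count: int = 0
    travel_m_today: float = 0.0
    total_travel_m: float = 0.0

    @property
    def cell(self) -> tuple[int, int]:
        return int(self.y), int(self.x)


def derive_behavior_params(config: SimConfig, accessible_ha: float) -> BehaviorParams:
    """Translate (HCF, SD, area) into the behavioral constants.

    Herd size is ``round(sd * area / au_per_cow)``.  HCF interpolates
    geometrically between the stated endpoints: herd distance 100 m
    (HCF 1) to 10 m (HCF 10); space per cow 1000 m^2 to 10 m^2.  The
    leaders' site-change patience grows with herd size,
    ``max(2, ceil(n_cows / 10))``, unless overridden in the config; the
    divisor was calibrated once so mean site changes per day stays inside
    the observed 2.3-6.0 band at the desk-scale factorial corners.
    """
    if accessible_ha <= 0:
        raise ConfigurationError("accessible_ha must be > 0")
    n_cows = round(config.sd * accessible_ha / config.au_per_cow)
    if n_cows < 1:
        raise ConfigurationError(
            f"stocking density {config.sd} on {accessible_ha:.2f} ha yields no cows"
        )
    t = (config.hcf - 1.0) / 9.0
    herd_distance = 100.0 * 10.0 ** (-t)
    space_per_cow = 1000.0 * 100.0 ** (-t)
    site_tolerance = (
        config.site_tolerance
        if config.site_tolerance is not None
        else max(2, math.ceil(n_cows / 10))
    )
    return BehaviorParams(
        n_cows=n_cows,
        herd_distance_m=herd_distance,
        space_per_cow_m2=space_per_cow,
        site_tolerance=site_tolerance,
        hydration_capacity_g=config.daily_intake_g / 2.0,
    )


def _role_counts(n_cows: int) -> dict[str, int]:
    """Largest-remainder apportionment of the 5/85/10% role quotas.

    Ties break in the order leader > follower > independent, and at least
    one leader is always present (leaders alone trigger watering and site
    changes, so a leaderless herd would deadlock).
    """
    quotas = {role: n_cows * frac for role, frac in ROLE_FRACTIONS}
    counts = {role: int(math.floor(q)) for role, q in quotas.items()}
    remaining = n_cows - sum(counts.values())
    order = sorted(
        range(len(ROLE_FRACTIONS)),
        key=lambda i: (-(quotas[ROLE_FRACTIONS[i][0]] - counts[ROLE_FRACTIONS[i][0]]), i),
    )
    for i in order[:remaining]:
        counts[ROLE_FRACTIONS[i][0]] += 1
    if counts[ROLE_LEADER] == 0:
        donor = max(
            (r for r in counts if r != ROLE_LEADER and counts[r] > 0),
            key=lambda r: counts[r],
        )
        counts[donor] -= 1
        counts[ROLE_LEADER] += 1
    return counts


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Normal draws truncated to [lo, hi] by rejection (bounds are ~3 sd)."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def create_herd(
    config: SimConfig,
    params: BehaviorParams,
    pasture: Pasture,
    rng: np.random.Generator | None = None,
) -> list[Cow]:
    """Create the cow population, all standing at one random accessible cell.

    Individual draws (tolerance, attraction, headings) and the shuffled
    role assignment are reproducible from the RNG / config seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 21]))
    n = params.n_cows
    if not pasture.accessible.any():
        raise ConfigurationError("pasture has no accessible cells")
    counts = _role_counts(n)
    roles = (
        [ROLE_LEADER] * counts[ROLE_LEADER]
        + [ROLE_FOLLOWER] * counts[ROLE_FOLLOWER]
        + [ROLE_INDEPENDENT] * counts[ROLE_INDEPENDENT]
    )
    roles = [roles[i] for i in rng.permutation(n)]
    tol = _truncated_normal(
        rng, MSAL_TOLERANCE_MEAN_MG, MSAL_TOLERANCE_SD_MG, 3000.0, 5000.0, n
    )
    attr = _truncated_normal(rng, ATTRACTION_MEAN, ATTRACTION_SD, 0.75, 1.25, n)
    headings = rng.uniform(0.0, 360.0, size=n)
    rows, cols = np.where(pasture.accessible)
    k = int(rng.integers(len(rows)))
    y0, x0 = rows[k] + 0.5, cols[k] + 0.5
    return [
        Cow(
            id=i,
            role=roles[i],
            x=float(x0),
            y=float(y0),
            heading_deg=float(headings[i]),
            msal_tolerance_mg=float(tol[i]),
            larkspur_attraction=float(attr[i]),
            hydration_g=params.hydration_capacity_g,
        )
        for i in range(n)
    ]
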
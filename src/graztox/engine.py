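"""Per-tick behavioral engine.

A tick is one feeding-station interaction, not a unit of clock time.  On a
normal tick every cow (visited in a freshly shuffled order) either moves
toward its herdmates (``assess_herd``) or makes a local forage-seeking
move (``environmental_movement``), then eats the cell it lands on.  Two
whole-herd events preempt grazing and consume the entire tick: a watering
trip (triggered by any leader whose hydration has run out) and a site
change (triggered by a leader whose patience with the locally overgrazed
site is exhausted).

Time advances by consumption: when herd-mean intake for the day reaches
12.5 kg per cow, one grazing-day has passed; each cow's toxicosis status
is then assessed (body burden above its individual tolerance is recorded
as a death and reset), and all body burdens are halved (one-grazing-day
elimination half-life).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import InvariantViolation
from .herd import (
    ROLE_FOLLOWER,
    ROLE_INDEPENDENT,
    ROLE_LEADER,
    BehaviorParams,
    Cow,
    SimConfig,
    create_herd,
    derive_behavior_params,
)
from .landscape import Pasture, disc_offsets

__all__ = ["Simulation", "TickContext", "DeathEvent", "eat_fraction"]

COS_45 = math.cos(math.radians(45.0))

#: forage fraction removed on the 1st / 2nd / 3rd-and-later visit to a cell
EAT_FRACTIONS = (0.40, 0.50, 0.60)


def eat_fraction(times_grazed: int) -> float:
    """Fraction of a cell's current forage removed on this visit."""
    return EAT_FRACTIONS[min(times_grazed, 2)]


@dataclass
class TickContext:
    """What happened on one tick."""

    tick_index: int
    watering_tick: bool = False
    site_change_tick: bool = False
    grazing_day_index: int = 0
    mean_times_grazed_global: float = 0.0
    day_completed: bool = False


@dataclass(frozen=True)
class DeathEvent:
    """A lethal-acute-toxicosis event (the cow is not removed)."""

    cow_id: int
    grazing_day: int
    msal_level_at_event_mg: float
    tolerance_mg: float
    attraction: float
    role: str


@dataclass
class _Offsets:
    """Precomputed integer offsets plus norms, unit vectors, flat indices."""

    offs: np.ndarray
    norms: np.ndarray
    units: np.ndarray
    flat: np.ndarray  # offs[:,0] * W + offs[:,1], for interior fast paths
    radius: float

    @classmethod
    def build(cls, offs: np.ndarray, width: int, radius: float) -> "_Offsets":
        norms = np.sqrt((offs * offs).sum(axis=1)).astype(float)
        units = offs / norms[:, None]
        return cls(
            offs=offs,
            norms=norms,
            units=units,
            flat=offs[:, 0] * width + offs[:, 1],
            radius=radius,
        )


def _ring_offsets(r_in: float, r_out: float) -> np.ndarray:
    r = int(np.floor(r_out))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = dy * dy + dx * dx
    keep = (d2 >= r_in * r_in) & (d2 <= r_out * r_out)
    return np.column_stack([dy[keep], dx[keep]])


class Simulation:
    """State and scheduling for one simulation run.

    Fully deterministic given the pasture and ``config.seed``; the herd,
    the per-tick shuffles, and every tie-break share one seeded generator
    chain.
    """

    def __init__(
        self,
        pasture: Pasture,
        config: SimConfig,
        params: BehaviorParams | None = None,
        cows: list[Cow] | None = None,
        collect_daily: bool = True,
        check_invariants_every_tick: bool = False,
    ):
        self.pasture = pasture
        self.config = config
        self.params = params or derive_behavior_params(config, pasture.accessible_ha)
        self.rng = np.random.default_rng(np.random.SeedSequence([config.seed, 22]))
        self.cows = cows if cows is not None else create_herd(
            config, self.params, pasture
        )
        self.n = len(self.cows)
        self.collect_daily = collect_daily
        self.check_every_tick = check_invariants_every_tick

        self.H, self.W = pasture.shape
        self.xs = np.array([c.x for c in self.cows])
        self.ys = np.array([c.y for c in self.cows])
        self._is_leader = np.array([c.role == ROLE_LEADER for c in self.cows])

        self._n_accessible = int(pasture.accessible.sum())
        self._tg_sum = int(pasture.times_grazed[pasture.accessible].sum())
        self._initial_forage_total = pasture.initial_total_forage_g()
        self._initial_msal_total = pasture.initial_total_msal_mg()

        wc = sorted(pasture.water_cells)
        self._water_rc = np.array(wc, dtype=int).reshape(-1, 2)
        self._water_xy = self._water_rc[:, ::-1] + 0.5  # (x, y) centers

        # offset tables
        self._disc10 = disc_offsets(10.0)
        self._disc10_flat = self._disc10[:, 0] * self.W + self._disc10[:, 1]
        self._env = {
            2.0: _Offsets.build(_ring_offsets(1.0, 2.0), self.W, 2.0),
            10.0: _Offsets.build(_ring_offsets(1.0, 10.0), self.W, 10.0),
        }
        self._annulus = _Offsets.build(_ring_offsets(10.0, 25.0), self.W, 25.0)
        # cells whose whole disc of the given radius is in-bounds and
        # accessible: lets the hot loops skip bounds/accessibility masking
        self._safe = {
            10.0: self._erode(10.0),
            25.0: self._erode(25.0),
        }
        self._safe[2.0] = self._safe[10.0]
        self._tg_flat = pasture.times_grazed.ravel()
        self._forage_flat = pasture.forage_g.ravel()
        self._site_radius_m = math.sqrt(
            self.n * self.params.space_per_cow_m2 / math.pi
        )
        self._site_eval_offs = self._subsampled_disc(self._site_radius_m)
        self._site_offs = disc_offsets(self._site_radius_m)
        self._lattice = self._candidate_lattice()

        # counters / logs
        self.tick_index = 0
        self.grazing_day = 0
        self.total_consumed_g = 0.0
        self.total_msal_consumed_mg = 0.0
        self.eat_events = 0
        self.herd_moves = 0
        self.env_moves = 0
        self.site_change_count = 0
        self.watering_count = 0
        self._day_sum_g = 0.0
        self._zero_intake_ticks = 0
        self.forage_exhausted = False
        self.death_events: list[DeathEvent] = []
        self.daily_records: list[tuple] = []  # (day, cow, role, msal, forage, died)
        self.daily_travel_means_m: list[float] = []

    # -- helpers ---------------------------------------------------------

    def _erode(self, radius: float) -> np.ndarray:
        """True where every cell within *radius* is in-bounds and accessible.

        Conservative via a Euclidean distance transform (out-of-bounds
        counts as inaccessible); used only to pick fast paths, so a few
        false negatives near the fence are harmless.
        """
        from scipy.ndimage import distance_transform_edt

        padded = np.zeros(
            (self.H + 2, self.W + 2), dtype=bool
        )
        padded[1:-1, 1:-1] = self.pasture.accessible
        dist = distance_transform_edt(padded)[1:-1, 1:-1]
        return dist > radius

    def _subsampled_disc(self, radius: float) -> np.ndarray:
        """Disc offsets thinned to a lattice of <= ~500 sample cells."""
        offs = disc_offsets(radius)
        stride = max(1, int(math.ceil(radius / 12.0)))
        keep = (offs[:, 0] % stride == 0) & (offs[:, 1] % stride == 0)
        return offs[keep]

    def _candidate_lattice(self) -> np.ndarray:
        """Accessible candidate site centers every 25 m."""
        rows = np.arange(12, self.H, 25)
        cols = np.arange(12, self.W, 25)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        cand = np.column_stack([rr.ravel(), cc.ravel()])
        ok = self.pasture.accessible[cand[:, 0], cand[:, 1]]
        cand = cand[ok]
        if len(cand) == 0:  # tiny pastures: fall back to every accessible cell
            r, c = np.where(self.pasture.accessible)
            cand = np.column_stack([r, c])
        return cand

    def _local_grazed_mean(self, row: int, col: int) -> float:
        """Mean times-grazed over accessible in-bounds cells within 10 m."""
        if self._safe[10.0][row, col]:
            vals = self._tg_flat[row * self.W + col + self._disc10_flat]
            return float(vals.sum()) / len(vals)
        rows = row + self._disc10[:, 0]
        cols = col + self._disc10[:, 1]
        ok = (rows >= 0) & (rows < self.H) & (cols >= 0) & (cols < self.W)
        rows, cols = rows[ok], cols[ok]
        acc = self.pasture.accessible[rows, cols]
        if not acc.any():
            return 0.0
        return float(self.pasture.times_grazed[rows[acc], cols[acc]].mean())

    @property
    def global_mean_times_grazed(self) -> float:
        return self._tg_sum / self._n_accessible

    @property
    def aums_consumed(self) -> float:
        return (
            self.grazing_day * self.n * self.config.au_per_cow
            / self.config.days_per_month
        )

    def _move_cow(self, cow: Cow, row: int, col: int) -> None:
        nx, ny = col + 0.5, row + 0.5
        dx, dy = nx - cow.x, ny - cow.y
        dist = math.hypot(dx, dy)
        if dist > 0:
            cow.heading_deg = math.degrees(math.atan2(dy, dx))
            cow.travel_m_today += dist
            cow.total_travel_m += dist
        cow.x, cow.y = nx, ny
        self.xs[cow.id], self.ys[cow.id] = nx, ny

    # -- behavioral procedures -------------------------------------------

    def check_hydration(self, cow: Cow) -> bool:
        """Leaders trigger a whole-herd watering trip when hydration runs out."""
        return cow.role == ROLE_LEADER and cow.hydration_g <= 0.0

    def go_to_water(self) -> None:
        """Send every cow to its nearest water cell holding <= 2 cows.

        Cows relocate in a freshly shuffled order; after watering every
        hydration is reset to capacity and each leader's ready-to-go is
        primed to site_tolerance - 1 (cattle rarely linger at water).  If
        every water cell already holds 3 cows, overflow cows simply take
        the nearest water cell (prevents deadlock at high densities).
        """
        occupancy: dict[int, int] = {}
        cell_index = {tuple(rc): i for i, rc in enumerate(self._water_rc)}
        for cow in self.cows:
            i = cell_index.get(cow.cell)
            if i is not None:
                occupancy[i] = occupancy.get(i, 0) + 1
        wx, wy = self._water_xy[:, 0], self._water_xy[:, 1]
        occ = np.zeros(len(self._water_rc), dtype=int)
        for i, k in occupancy.items():
            occ[i] = k
        for i in self.rng.permutation(self.n):
            cow = self.cows[i]
            d2 = (wx - cow.x) ** 2 + (wy - cow.y) ** 2
            open_mask = occ < 3
            if open_mask.any():
                d2 = np.where(open_mask, d2, np.inf)
            j = int(np.argmin(d2))
            occ[j] += 1
            self._move_cow(cow, int(self._water_rc[j, 0]), int(self._water_rc[j, 1]))
        for cow in self.cows:
            cow.hydration_g = self.params.hydration_capacity_g
            if cow.role == ROLE_LEADER:
                cow.ready_to_go = self.params.site_tolerance - 1
        self.watering_count += 1

    def check_site_change(self, cow: Cow) -> str:
        """Leader patience bookkeeping for relatively overgrazed sites.

        Returns one of ``none`` / ``increment`` / ``site_change`` /
        ``water_first``.  The local 10 m grazing pressure is compared to
        the pasture-wide mean: pressure above ``0.5 * global + 1.2``
        increments ready-to-go; at the site-tolerance threshold the leader
        initiates a site change - unless its hydration is nearly empty
        (< 20% of capacity), in which case watering takes priority.
        """
        row, col = cow.cell
        local = self._local_grazed_mean(row, col)
        action = "none"
        if local > 0.5 * self.global_mean_times_grazed + 1.2:
            cow.ready_to_go += 1
            action = "increment"
        if cow.ready_to_go >= self.params.site_tolerance:
            threshold = (
                self.config.water_threshold_frac * self.params.hydration_capacity_g
            )
            return "water_first" if cow.hydration_g < threshold else "site_change"
        return action

    def select_new_site(self, cow: Cow) -> tuple[tuple[int, int], float]:
        """Pick the new feeding site for the herd.

        Candidate centers on a 25 m lattice are scored by summed ranks of
        low grazing pressure, high current forage and high neighborhood
        (initial) forage within the site radius; among the best five, the
        one nearest the deciding leader wins.  The site radius allocates
        ``space_per_cow_m2`` per cow.
        """
        cand = self._lattice
        offs = self._site_eval_offs
        rows = cand[:, 0][:, None] + offs[:, 0][None, :]
        cols = cand[:, 1][:, None] + offs[:, 1][None, :]
        ok = (rows >= 0) & (rows < self.H) & (cols >= 0) & (cols < self.W)
        rows_c = np.clip(rows, 0, self.H - 1)
        cols_c = np.clip(cols, 0, self.W - 1)
        ok &= self.pasture.accessible[rows_c, cols_c]
        denom = np.maximum(ok.sum(axis=1), 1)

        def masked_mean(grid):
            vals = grid[rows_c, cols_c]
            return np.where(ok, vals, 0.0).sum(axis=1) / denom

        tg_mean = masked_mean(self.pasture.times_grazed)
        forage_mean = masked_mean(self.pasture.forage_g)
        nforage_mean = masked_mean(self.pasture.n_forage_g)
        score = (
            rankdata(-tg_mean) + rankdata(forage_mean) + rankdata(nforage_mean)
        )
        top5 = np.argsort(-score, kind="stable")[:5]
        d2 = (cand[top5, 1] + 0.5 - cow.x) ** 2 + (cand[top5, 0] + 0.5 - cow.y) ** 2
        best = top5[int(np.argmin(d2))]
        return (int(cand[best, 0]), int(cand[best, 1])), self._site_radius_m

    def change_site(self, site: tuple[tuple[int, int], float]) -> None:
        """Relocate the whole herd to the new site, leaders choosing first.

        Within the site disc each cow takes the accessible cell with the
        most forage that has no cow on it or on any of its four direct
        neighbors; ties break nearest-to-center, then by seeded draw.  If
        the disc fills up, the neighbor constraint is relaxed, and as a
        last resort cows take the nearest free accessible cell outside.
        """
        (crow, ccol), _radius = site
        rows = crow + self._site_offs[:, 0]
        cols = ccol + self._site_offs[:, 1]
        ok = (rows >= 0) & (rows < self.H) & (cols >= 0) & (cols < self.W)
        rows, cols = rows[ok], cols[ok]
        acc = self.pasture.accessible[rows, cols]
        rows, cols = rows[acc], cols[acc]
        forage = self.pasture.forage_g[rows, cols]
        d2 = (rows + 0.5 - (crow + 0.5)) ** 2 + (cols + 0.5 - (ccol + 0.5)) ** 2
        jitter = self.rng.random(len(rows))
        order = np.lexsort((jitter, d2, -forage))
        rows, cols = rows[order], cols[order]

        blocked: set[tuple[int, int]] = set()
        occupied: set[tuple[int, int]] = set()
        n_cells = len(rows)
        ptr = 0

        def place(cow: Cow, r: int, c: int) -> None:
            occupied.add((r, c))
            blocked.add((r, c))
            blocked.update(((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)))
            self._move_cow(cow, r, c)

        role_groups = [
            [c for c in self.cows if c.role == ROLE_LEADER],
            [c for c in self.cows if c.role == ROLE_FOLLOWER],
            [c for c in self.cows if c.role == ROLE_INDEPENDENT],
        ]
        for group in role_groups:
            for k in self.rng.permutation(len(group)):
                cow = group[k]
                while ptr < n_cells and (int(rows[ptr]), int(cols[ptr])) in blocked:
                    ptr += 1
                if ptr < n_cells:
                    place(cow, int(rows[ptr]), int(cols[ptr]))
                    ptr += 1
                    continue
                # relax: any site cell with no cow directly on it
                placed = False
                for r, c in zip(rows, cols):
                    if (int(r), int(c)) not in occupied:
                        place(cow, int(r), int(c))
                        placed = True
                        break
                if not placed:
                    self._place_nearest_free(cow, crow, ccol, occupied)
        for c in self.cows:
            if c.role == ROLE_LEADER:
                c.ready_to_go = 0
        self.site_change_count += 1

    def _place_nearest_free(
        self, cow: Cow, crow: int, ccol: int, occupied: set[tuple[int, int]]
    ) -> None:
        """Expanding-ring search for the nearest free accessible cell."""
        for radius in range(1, max(self.H, self.W)):
            r0, r1 = max(0, crow - radius), min(self.H, crow + radius + 1)
            c0, c1 = max(0, ccol - radius), min(self.W, ccol + radius + 1)
            best = None
            best_d2 = np.inf
            for r in range(r0, r1):
                for c in range(c0, c1):
                    if not self.pasture.accessible[r, c] or (r, c) in occupied:
                        continue
                    d2 = (r - crow) ** 2 + (c - ccol) ** 2
                    if d2 < best_d2:
                        best, best_d2 = (r, c), d2
            if best is not None:
                occupied.add(best)
                self._move_cow(cow, best[0], best[1])
                return
        raise InvariantViolation("no free accessible cell for placement")

    def _pick_move_cell(
        self, cow: Cow, table: _Offsets, bearing: tuple[float, float]
    ) -> tuple[int, int] | None:
        """Max-forage cell among offsets within a vision cone of *bearing*.

        Cone widens from +/-45 deg to +/-90 deg to unrestricted if no
        candidate exists; ties break nearest, then by seeded draw.
        """
        row, col = cow.cell
        if self._safe[table.radius][row, col]:
            flat = row * self.W + col + table.flat
            ok = None
        else:
            rows = row + table.offs[:, 0]
            cols = col + table.offs[:, 1]
            ok = (rows >= 0) & (rows < self.H) & (cols >= 0) & (cols < self.W)
            rows_c = np.clip(rows, 0, self.H - 1)
            cols_c = np.clip(cols, 0, self.W - 1)
            ok &= self.pasture.accessible[rows_c, cols_c]
            if not ok.any():
                return None
            flat = rows * self.W + cols
        bnorm = math.hypot(*bearing)
        if bnorm == 0:
            cone = ok
        else:
            # offsets are (drow, dcol) = (dy, dx); bearing is (dx, dy)
            cosang = (
                table.units[:, 1] * (bearing[0] / bnorm)
                + table.units[:, 0] * (bearing[1] / bnorm)
            )
            in_cone = cosang >= COS_45
            cone = in_cone if ok is None else ok & in_cone
            if not cone.any():
                in_cone = cosang >= 0.0
                cone = in_cone if ok is None else ok & in_cone
            if not cone.any():
                cone = ok
        if cone is None:  # unrestricted cone on a fully safe disc
            idx = np.arange(len(table.flat))
        else:
            idx = np.flatnonzero(cone)
        forage = self._forage_flat[flat[idx]]
        best = idx[forage == forage.max()]
        if len(best) > 1:
            d = table.norms[best]
            best = best[d == d.min()]
            if len(best) > 1:
                best = best[[int(self.rng.integers(len(best)))]]
        j = int(best[0])
        return int(flat[j] // self.W), int(flat[j] % self.W)

    def assess_herd(self, cow: Cow) -> bool:
        """Herding movement; returns True if the cow herd-moved this tick.

        Herdmates are the nearest 20 cows.  Leaders/followers herd up when
        their mean herdmate distance exceeds the herd distance; independents
        only when it exceeds 2.5x, and they move *away* when closer than
        0.5x.  A herding move targets the max-forage accessible cell
        10-25 m away within +/-45 deg of the herdmate-centroid bearing.
        """
        if self.n < 2:
            return False
        dx = self.xs - cow.x
        dy = self.ys - cow.y
        d = np.hypot(dx, dy)
        d[cow.id] = np.inf
        k = min(self.params.herdmate_count, self.n - 1)
        mates = np.argpartition(d, k - 1)[:k]
        mean_d = float(d[mates].mean())
        hd = self.params.herd_distance_m
        if cow.role == ROLE_INDEPENDENT:
            if mean_d > 2.5 * hd:
                away = False
            elif mean_d < 0.5 * hd:
                away = True
            else:
                return False
        else:
            if mean_d <= hd:
                return False
            away = False
        cx = float(self.xs[mates].mean())
        cy = float(self.ys[mates].mean())
        bearing = (cx - cow.x, cy - cow.y)
        if away:
            bearing = (-bearing[0], -bearing[1])
        if bearing == (0.0, 0.0):
            return False
        target = self._pick_move_cell(cow, self._annulus, bearing)
        if target is None:
            target = self._nearest_toward(cow, bearing)
        if target is None:
            return False
        self._move_cow(cow, *target)
        self.herd_moves += 1
        return True

    def _nearest_toward(
        self, cow: Cow, bearing: tuple[float, float]
    ) -> tuple[int, int] | None:
        """Fallback when the whole annulus is fenced off: the accessible
        cell within 25 m best aligned with *bearing* (nearest on ties)."""
        row, col = cow.cell
        table = self._env[10.0]
        rows = row + table.offs[:, 0]
        cols = col + table.offs[:, 1]
        ok = (rows >= 0) & (rows < self.H) & (cols >= 0) & (cols < self.W)
        rows_c = np.clip(rows, 0, self.H - 1)
        cols_c = np.clip(cols, 0, self.W - 1)
        ok &= self.pasture.accessible[rows_c, cols_c]
        if not ok.any():
            return None
        bnorm = math.hypot(*bearing)
        cosang = (
            table.units[:, 1] * (bearing[0] / bnorm)
            + table.units[:, 0] * (bearing[1] / bnorm)
        )
        idx = np.flatnonzero(ok)
        best = idx[np.lexsort((table.norms[idx], -cosang[idx]))[0]]
        return int(rows[best]), int(cols[best])

    def environmental_movement(self, cow: Cow) -> bool:
        """Local forage-seeking move for a cow that did not herd up.

        In relatively ungrazed surroundings (10 m mean times-grazed < 0.5)
        the cow looks only 2 m ahead; in well-grazed surroundings it looks
        10 m afield.  Target: max available forage within +/-45 deg of the
        current heading (cone widens if needed).
        """
        row, col = cow.cell
        local = self._local_grazed_mean(row, col)
        table = self._env[2.0] if local < 0.5 else self._env[10.0]
        theta = math.radians(cow.heading_deg)
        target = self._pick_move_cell(cow, table, (math.cos(theta), math.sin(theta)))
        if target is None:
            return False  # isolated cell: stay put, graze in place
        self._move_cow(cow, *target)
        self.env_moves += 1
        return True

    def eat(self, cow: Cow) -> tuple[float, float]:
        """Graze the cow's current cell; returns (forage g, MSAL mg) intake.

        Removes 40% of available forage on a cell's first grazing, 50% of
        the remainder on the second, 60% on later visits.  Alkaloid intake
        scales with the cow's larkspur attraction, capped at the cell
        content.  Hydration depletes by grams eaten.
        """
        row, col = cow.cell
        p = self.pasture
        if p.forage_g[row, col] < -1e-9 or p.msal_mg[row, col] < -1e-9:
            raise InvariantViolation("negative cell content")
        f = eat_fraction(int(p.times_grazed[row, col]))
        forage_intake = f * p.forage_g[row, col]
        msal_intake = min(
            float(p.msal_mg[row, col]),
            f * p.msal_mg[row, col] * cow.larkspur_attraction,
        )
        p.forage_g[row, col] -= forage_intake
        p.msal_mg[row, col] -= msal_intake
        p.times_grazed[row, col] += 1
        if p.accessible[row, col]:
            self._tg_sum += 1
        cow.cumulative_consumption_g += forage_intake
        cow.day_consumption_g += forage_intake
        cow.hydration_g -= forage_intake
        cow.day_msal_mg += msal_intake
        cow.total_msal_mg += msal_intake
        cow.msal_level_mg += msal_intake
        self.total_consumed_g += forage_intake
        self.total_msal_consumed_mg += msal_intake
        self._day_sum_g += forage_intake
        self.eat_events += 1
        return forage_intake, msal_intake

    def end_of_grazing_day(self) -> list[DeathEvent]:
        """Close out a grazing-day: record intakes, assess toxicosis, halve
        body burdens, reset daily ledgers."""
        events: list[DeathEvent] = []
        travel = 0.0
        for cow in self.cows:
            died = cow.msal_level_mg > cow.msal_tolerance_mg
            if self.collect_daily:
                self.daily_records.append(
                    (
                        self.grazing_day,
                        cow.id,
                        cow.role,
                        cow.day_msal_mg,
                        cow.day_consumption_g,
                        died,
                    )
                )
            cow.max_day_msal_mg = max(cow.max_day_msal_mg, cow.day_msal_mg)
            if died:
                cow.death_count += 1
                ev = DeathEvent(
                    cow_id=cow.id,
                    grazing_day=self.grazing_day,
                    msal_level_at_event_mg=cow.msal_level_mg,
                    tolerance_mg=cow.msal_tolerance_mg,
                    attraction=cow.larkspur_attraction,
                    role=cow.role,
                )
                events.append(ev)
                self.death_events.append(ev)
                cow.msal_level_mg = 0.0
            cow.msal_level_mg *= 0.5
            cow.day_consumption_g = 0.0
            cow.day_msal_mg = 0.0
            travel += cow.travel_m_today
            cow.travel_m_today = 0.0
        self.daily_travel_means_m.append(travel / self.n)
        self._day_sum_g = 0.0
        self.grazing_day += 1
        return events

    # -- scheduling -------------------------------------------------------

    def tick(self) -> TickContext:
        """Execute one tick; returns a context describing what happened."""
        ctx = TickContext(
            tick_index=self.tick_index,
            grazing_day_index=self.grazing_day,
            mean_times_grazed_global=self.global_mean_times_grazed,
        )
        order = self.rng.permutation(self.n)
        leaders_in_order = [
            self.cows[i] for i in order if self._is_leader[i]
        ]
        # 1) watering preempts everything
        if any(self.check_hydration(c) for c in leaders_in_order):
            self.go_to_water()
            ctx.watering_tick = True
            self.tick_index += 1
            return ctx
        # 2) site-change assessment; first triggering leader wins the tick
        for leader in leaders_in_order:
            action = self.check_site_change(leader)
            if action == "water_first":
                self.go_to_water()
                ctx.watering_tick = True
                self.tick_index += 1
                return ctx
            if action == "site_change":
                site = self.select_new_site(leader)
                self.change_site(site)
                ctx.site_change_tick = True
                self.tick_index += 1
                return ctx
        # 3) grazing: every cow moves, then eats its destination cell
        tick_intake = 0.0
        for i in order:
            cow = self.cows[i]
            if not self.assess_herd(cow):
                self.environmental_movement(cow)
            forage_intake, _ = self.eat(cow)
            tick_intake += forage_intake
        if tick_intake < 1e-6 * self.n:
            self._zero_intake_ticks += 1
            if self._zero_intake_ticks > 100:
                self.forage_exhausted = True
        else:
            self._zero_intake_ticks = 0
        if self._day_sum_g / self.n >= self.config.daily_intake_g:
            self.end_of_grazing_day()
            ctx.day_completed = True
        if self.check_every_tick:
            self.assert_conservation()
        self.tick_index += 1
        return ctx

    # -- invariants --------------------------------------------------------

    def conservation_errors(self) -> dict[str, float]:
        """Relative forage/MSAL conservation errors and times-grazed slack."""
        p = self.pasture
        forage_removed = self._initial_forage_total - p.total_forage_g()
        msal_removed = self._initial_msal_total - p.total_msal_mg()
        ledger_forage = sum(c.cumulative_consumption_g for c in self.cows)
        ledger_msal = sum(c.total_msal_mg for c in self.cows)
        denom_f = max(self._initial_forage_total, 1.0)
        denom_m = max(self._initial_msal_total, 1.0)
        return {
            "forage_rel_err": abs(forage_removed - ledger_forage) / denom_f,
            "msal_rel_err": abs(msal_removed - ledger_msal) / denom_m,
            "times_grazed_mismatch": abs(
                int(p.times_grazed.sum()) - self.eat_events
            ),
        }

    def assert_conservation(self, rel_tol: float = 1e-6) -> None:
        errs = self.conservation_errors()
        if errs["forage_rel_err"] > rel_tol:
            raise InvariantViolation(f"forage conservation: {errs}")
        if errs["msal_rel_err"] > rel_tol:
            raise InvariantViolation(f"MSAL conservation: {errs}")
        if errs["times_grazed_mismatch"] != 0:
            raise InvariantViolation(f"times-grazed ledger: {errs}")
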
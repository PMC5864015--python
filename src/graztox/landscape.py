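"""Synthetic pasture landscapes for the grazing/toxicosis simulation.

The simulation world is a grid of 1 m^2 cells ("patches"), each carrying
usable forage (g), toxic MSAL alkaloid held in larkspur plants (mg), a
times-grazed counter, and an accessibility flag (cells outside the fence
line cannot be grazed).  Real study pastures are initialized from remote
sensing and field-mapped larkspur layers; this module generates statistical
stand-ins with the same structure:

* a spatially autocorrelated productivity index in [0, 1] (the analogue of
  a soil-adjusted vegetation index),
* forage mass distributed exponentially in that index so the poorest cells
  hold one third of the mean forage and the richest three times the mean,
* a clustered (Poisson-cluster) larkspur distribution with dense patches
  (>1 plant per m^2) on a sparse background, plant mass scaled +/-50%
  around the median by the same index,
* a stream-like linear water feature, optionally broken into intermittent
  segments.

Grids are serialized as ESRI ASCII rasters (one file per layer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GridFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "LandscapeConfig",
    "Pasture",
    "generate_index_field",
    "forage_from_index",
    "generate_larkspur_field",
    "generate_water_feature",
    "neighborhood_mean",
    "disc_offsets",
    "read_ascii_grid",
    "write_ascii_grid",
]

# Sub-stream keys so each generation step has its own reproducible RNG.
_STREAM_INDEX = 11
_STREAM_LARKSPUR = 12
_STREAM_WATER = 13


@dataclass(frozen=True)
class LandscapeConfig:
    """Inputs for synthetic pasture generation.

    One cell is 1 m^2.  Defaults describe a dangerous, productive larkspur
    year: 500 kg/ha usable forage, 3.5 g median plant mass at 3.0 mg/g
    MSAL alkaloid concentration, and patchy larkspur averaging roughly
    0.2 plants per m^2 overall.
    """

    width_cells: int = 400
    height_cells: int = 400
    seed: int = 0
    correlation_length_m: float = 25.0
    kgs_per_hectare: float = 500.0
    patch_intensity_per_ha: float = 0.38
    patch_radius_m: float = 25.0
    within_patch_density: float = 4.0
    background_density: float = 0.02
    median_plant_mass_g: float = 3.5
    msal_concentration_mg_per_g: float = 3.0
    fence_margin_cells: int = 2
    stream_break_fraction: float = 0.25

    def __post_init__(self):
        if self.width_cells < 1 or self.height_cells < 1:
            raise ConfigurationError("grid dimensions must be >= 1 cell")
        if self.correlation_length_m <= 0:
            raise ConfigurationError("correlation_length_m must be > 0")
        if self.kgs_per_hectare <= 0:
            raise ConfigurationError("kgs_per_hectare must be > 0")
        if not (self.within_patch_density > 1.0):
            raise ConfigurationError(
                "within_patch_density must exceed 1 plant/m^2 (patch definition)"
            )
        if self.background_density < 0 or self.background_density > 1.0:
            raise ConfigurationError("background_density must be in [0, 1]")
        if self.within_patch_density <= self.background_density:
            raise ConfigurationError(
                "within_patch_density must exceed background_density"
            )
        if self.patch_intensity_per_ha < 0 or self.patch_radius_m <= 0:
            raise ConfigurationError("patch intensity must be >= 0, radius > 0")
        if self.median_plant_mass_g < 0 or self.msal_concentration_mg_per_g < 0:
            raise ConfigurationError("plant mass and concentration must be >= 0")
        if self.fence_margin_cells < 0:
            raise ConfigurationError("fence_margin_cells must be >= 0")
        if not (0.0 <= self.stream_break_fraction <= 1.0):
            raise ConfigurationError("stream_break_fraction must be in [0, 1]")
        if (self.width_cells <= 2 * self.fence_margin_cells
                or self.height_cells <= 2 * self.fence_margin_cells):
            raise ConfigurationError("fence margin leaves no accessible cells")

    @property
    def area_ha(self) -> float:
        return self.width_cells * self.height_cells / 10_000.0


@lru_cache(maxsize=32)
def disc_offsets(radius_m: float) -> np.ndarray:
    """Integer (drow, dcol) offsets whose cell-center distance is <= radius.

    Cell centers sit at integer+0.5 coordinates, so the distance between
    two cell centers equals the Euclidean norm of the integer offset.
    """
    r = int(np.floor(radius_m))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy * dy + dx * dx <= radius_m * radius_m
    return np.column_stack([dy[keep], dx[keep]])


def neighborhood_mean(grid: np.ndarray, radius_m: float) -> np.ndarray:
    """Disc mean of *grid* at every cell (truncated disc at edges).

    A cell's neighborhood is the set of cells whose center lies within
    ``radius_m`` of its own center (the cell itself included).
    """
    if radius_m < 1:
        raise ConfigurationError("radius_m must be >= 1")
    grid = np.asarray(grid, dtype=float)
    offs = disc_offsets(radius_m)
    r = int(np.abs(offs).max())
    size = 2 * r + 1
    kernel = np.zeros((size, size))
    kernel[offs[:, 0] + r, offs[:, 1] + r] = 1.0
    total = ndimage.convolve(grid, kernel, mode="constant", cval=0.0)
    count = ndimage.convolve(np.ones_like(grid), kernel, mode="constant", cval=0.0)
    return total / count


def generate_index_field(config: LandscapeConfig) -> np.ndarray:
    """Spatially autocorrelated productivity index in [0, 1].

    Gaussian white noise smoothed at ``correlation_length_m`` and min-max
    normalized so the grid attains both 0 and 1.  Deterministic in
    ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_INDEX]))
    noise = rng.standard_normal((config.height_cells, config.width_cells))
    # sigma = L/2 puts most of the pair correlation inside the stated scale
    sigma = config.correlation_length_m / 2.0
    if sigma > 1e-3:
        fielded = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    else:
        fielded = noise
    lo, hi = fielded.min(), fielded.max()
    if hi == lo:
        raise ConfigurationError("degenerate index field (constant noise)")
    return (fielded - lo) / (hi - lo)


def forage_from_index(
    index: np.ndarray,
    kgs_per_hectare: float,
    accessible: np.ndarray | None = None,
) -> np.ndarray:
    """Map index u in [0,1] to initial forage (g per 1 m^2 cell).

    Uses the exponential f(u) = m * 3^(2u-1), the minimal exponential map
    whose endpoints are one third and three times the pre-rescale mean m.
    A single global rescale then pins the accessible-cell mean exactly to
    ``kgs_per_hectare / 10`` g per cell, preserving the 9:1 max/min ratio.
    """
    index = np.asarray(index, dtype=float)
    if index.min() < -1e-12 or index.max() > 1 + 1e-12:
        raise ConfigurationError("index values must lie in [0, 1]")
    if kgs_per_hectare <= 0:
        raise ConfigurationError("kgs_per_hectare must be > 0")
    if accessible is None:
        accessible = np.ones(index.shape, dtype=bool)
    if not accessible.any():
        raise ConfigurationError("no accessible cells to receive forage")
    raw = 3.0 ** (2.0 * index - 1.0)
    target_mean_g = kgs_per_hectare / 10.0  # kg/ha -> g/m^2
    scale = target_mean_g / raw[accessible].mean()
    return raw * scale


def generate_larkspur_field(
    index: np.ndarray, config: LandscapeConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Clustered larkspur plant counts and per-cell MSAL alkaloid (mg).

    Plants follow a Poisson-cluster process: Poisson patch centers at
    ``patch_intensity_per_ha``, disc patches of radius ``patch_radius_m``
    with per-cell Poisson(``within_patch_density``) counts, and a
    Poisson(``background_density``) background elsewhere.  Patch centers
    are placed with probability proportional to the productivity index:
    larkspur grows most densely in productive areas, which are also the
    most desirable foraging areas - the spatial coincidence that drives
    toxicosis risk.  Per-plant mass scales linearly with the index:
    mass(u) = median * (0.5 + u), so cells at the index extremes carry
    plants 50% smaller/larger than the median.  MSAL per cell =
    count * mass(u) * concentration.
    """
    index = np.asarray(index, dtype=float)
    if config.background_density < 0 or config.within_patch_density < 0:
        raise ConfigurationError("densities must be >= 0")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STREAM_LARKSPUR])
    )
    h, w = index.shape
    in_patch = np.zeros((h, w), dtype=bool)
    n_patches = rng.poisson(config.patch_intensity_per_ha * h * w / 10_000.0)
    if n_patches > 0:
        weights = index.ravel() + 1e-12
        cells = rng.choice(h * w, size=n_patches, p=weights / weights.sum())
        cy = cells // w + rng.uniform(0, 1, size=n_patches)
        cx = cells % w + rng.uniform(0, 1, size=n_patches)
        r = config.patch_radius_m
        offs = disc_offsets(r + 1.0)
        for py, px in zip(cy, cx):
            rows = np.clip(np.round(py - 0.5).astype(int) + offs[:, 0], 0, h - 1)
            cols = np.clip(np.round(px - 0.5).astype(int) + offs[:, 1], 0, w - 1)
            d2 = (rows + 0.5 - py) ** 2 + (cols + 0.5 - px) ** 2
            keep = d2 <= r * r
            in_patch[rows[keep], cols[keep]] = True
    lam = np.where(in_patch, config.within_patch_density, config.background_density)
    counts = rng.poisson(lam).astype(np.int64)
    mass_g = config.median_plant_mass_g * (0.5 + index)
    msal_mg = counts * mass_g * config.msal_concentration_mg_per_g
    return counts, msal_mg


def generate_water_feature(
    config: LandscapeConfig, accessible: np.ndarray | None = None
) -> set[tuple[int, int]]:
    """Random-walk stream across the pasture, as a set of (row, col) cells.

    The walk runs top to bottom with lateral drift; ``stream_break_fraction``
    of its segments are then removed to mimic an intermittently subsurface
    stream.  At least one water cell is always retained.
    """
    if accessible is None:
        accessible = accessible_mask(config)
    if not accessible.any():
        raise ConfigurationError("no accessible cells for a water feature")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_WATER]))
    h, w = accessible.shape
    rows_ok, cols_ok = np.where(accessible)
    r0, r1 = rows_ok.min(), rows_ok.max()
    c0, c1 = cols_ok.min(), cols_ok.max()
    col = int(rng.integers(c0 + (c1 - c0) // 4, c1 - (c1 - c0) // 4 + 1))
    drift = 0.0
    path: list[tuple[int, int]] = []
    for row in range(r0, r1 + 1):
        drift = 0.8 * drift + rng.normal(0, 0.7)
        col = int(np.clip(col + round(drift), c0, c1))
        if accessible[row, col]:
            path.append((row, col))
    if not path:
        # fence carved the walk away entirely; fall back to one valid cell
        k = int(rng.integers(len(rows_ok)))
        return {(int(rows_ok[k]), int(cols_ok[k]))}
    # break into ~10 segments, drop each with prob stream_break_fraction
    n_seg = min(10, len(path))
    segments = np.array_split(np.arange(len(path)), n_seg)
    kept: list[tuple[int, int]] = []
    for seg in segments:
        if rng.uniform() >= config.stream_break_fraction:
            kept.extend(path[i] for i in seg)
    if not kept:  # floor rule: never return an empty water set
        mid = segments[len(segments) // 2]
        kept = [path[i] for i in mid]
    return set(kept)


def accessible_mask(config: LandscapeConfig) -> np.ndarray:
    """Boolean grid: True inside the fence line."""
    mask = np.zeros((config.height_cells, config.width_cells), dtype=bool)
    m = config.fence_margin_cells
    mask[m:config.height_cells - m or None, m:config.width_cells - m or None] = True
    return mask


@dataclass
class Pasture:
    """Mutable grid state of one pasture during a simulation run.

    All layers are (height, width) arrays over 1 m^2 cells; ``water_cells``
    is the set of accessible (row, col) watering locations.  ``n_forage_g``
    is the 3 m disc mean of initial forage, a stable "neighborhood quality"
    layer used when scoring candidate feeding sites.
    """

    accessible: np.ndarray
    forage_g: np.ndarray
    initial_forage_g: np.ndarray
    n_forage_g: np.ndarray
    msal_mg: np.ndarray
    initial_msal_mg: np.ndarray
    times_grazed: np.ndarray
    water_cells: set[tuple[int, int]]
    index: np.ndarray | None = None
    config: LandscapeConfig | None = None
    plant_counts: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def generate(cls, config: LandscapeConfig) -> "Pasture":
        """Build a full synthetic pasture from one config (seed-deterministic)."""
        index = generate_index_field(config)
        accessible = accessible_mask(config)
        forage = forage_from_index(index, config.kgs_per_hectare, accessible)
        counts, msal = generate_larkspur_field(index, config)
        water = generate_water_feature(config, accessible)
        return cls(
            accessible=accessible,
            forage_g=forage.copy(),
            initial_forage_g=forage.copy(),
            n_forage_g=neighborhood_mean(forage, 3.0),
            msal_mg=msal.copy(),
            initial_msal_mg=msal.copy(),
            times_grazed=np.zeros(index.shape, dtype=np.int64),
            water_cells=water,
            index=index,
            config=config,
            plant_counts=counts,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.accessible.shape

    @property
    def accessible_ha(self) -> float:
        return float(self.accessible.sum()) / 10_000.0

    def total_forage_g(self) -> float:
        return float(self.forage_g[self.accessible].sum())

    def total_msal_mg(self) -> float:
        return float(self.msal_mg[self.accessible].sum())

    def initial_total_forage_g(self) -> float:
        return float(self.initial_forage_g[self.accessible].sum())

    def initial_total_msal_mg(self) -> float:
        return float(self.initial_msal_mg[self.accessible].sum())

    def water_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for r, c in self.water_cells:
            mask[r, c] = True
        return mask

    def save(self, directory: str | Path) -> None:
        """Write all layers as ESRI ASCII grids into *directory*."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        inaccessible = ~self.accessible
        forage = self.initial_forage_g.copy()
        forage[inaccessible] = np.nan
        msal = self.initial_msal_mg.copy()
        msal[inaccessible] = np.nan
        write_ascii_grid(forage, directory / "forage.asc")
        write_ascii_grid(msal, directory / "msal.asc")
        if self.index is not None:
            write_ascii_grid(self.index, directory / "index.asc")
        write_ascii_grid(self.water_mask().astype(float), directory / "water.asc")

    @classmethod
    def load(cls, directory: str | Path) -> "Pasture":
        """Rebuild a pasture from ASCII layers written by :meth:`save`."""
        directory = Path(directory)
        forage = read_ascii_grid(directory / "forage.asc")
        msal = read_ascii_grid(directory / "msal.asc")
        water_grid = read_ascii_grid(directory / "water.asc")
        accessible = ~np.isnan(forage)
        forage = np.nan_to_num(forage, nan=0.0)
        msal = np.nan_to_num(msal, nan=0.0)
        water_cells = {
            (int(r), int(c))
            for r, c in zip(*np.where(np.nan_to_num(water_grid, nan=0.0) > 0.5))
            if accessible[r, c]
        }
        index_path = directory / "index.asc"
        index = read_ascii_grid(index_path) if index_path.exists() else None
        return cls(
            accessible=accessible,
            forage_g=forage.copy(),
            initial_forage_g=forage.copy(),
            n_forage_g=neighborhood_mean(forage, 3.0),
            msal_mg=msal.copy(),
            initial_msal_mg=msal.copy(),
            times_grazed=np.zeros(forage.shape, dtype=np.int64),
            water_cells=water_cells,
            index=index,
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_ascii_grid(
    grid: np.ndarray, path: str | Path, nodata: float = -9999.0
) -> None:
    """Serialize *grid* as an ESRI ASCII raster; NaN cells become NODATA."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise GridFormatError("only 2-D grids can be written")
    nrows, ncols = grid.shape
    out = np.where(np.isnan(grid), nodata, grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write("cellsize 1.0\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in out:  # row 0 is the top row
            fh.write(" ".join(format(v, ".10g") for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> np.ndarray:
    """Parse an ESRI ASCII raster; NODATA cells come back as NaN.

    Cell size other than 1 is accepted with a warning and treated as 1 m
    model cells (the simulation is defined on 1 m^2 feeding stations).
    """
    path = Path(path)
    header: dict[str, float] = {}
    nodata = None
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(parts) != 2:
                raise GridFormatError(f"malformed header entry {parts[0]!r}", i + 1)
            try:
                val = float(parts[1])
            except ValueError:
                raise GridFormatError(
                    f"non-numeric header value for {parts[0]!r}", i + 1
                ) from None
            if key == "nodata_value":
                nodata = val
            else:
                header[key] = val
        else:
            break
    for k in ("ncols", "nrows"):
        if k not in header:
            raise GridFormatError(f"missing required header key {k!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if header.get("cellsize", 1.0) != 1.0:
        logger.warning(
            "%s: cellsize %g treated as 1 m model cells", path, header["cellsize"]
        )
    for j in range(i, len(lines)):
        parts = lines[j].split()
        if not parts:
            continue
        try:
            row = np.array([float(p) for p in parts])
        except ValueError:
            raise GridFormatError("non-numeric data value", j + 1) from None
        if row.size != ncols:
            raise GridFormatError(
                f"expected {ncols} values per row, found {row.size}", j + 1
            )
        rows.append(row)
    if len(rows) != nrows:
        raise GridFormatError(f"expected {nrows} data rows, found {len(rows)}")
    grid = np.vstack(rows)
    if nodata is not None:
        grid[grid == nodata] = np.nan
    return grid
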
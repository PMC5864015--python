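"""Observation metrics computed from run logs, and CSV interchange.

All standard deviations here are population standard deviations
(divisor n), applied consistently across per-run intake statistics and
the grazing-heterogeneity measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import SchemaError
from .landscape import Pasture

__all__ = [
    "IntakeStats",
    "intake_statistics",
    "grazing_heterogeneity",
    "herd_move_fraction",
    "detect_subherds",
    "write_run_summaries",
    "read_run_summaries",
    "write_daily_records",
    "read_daily_records",
    "REQUIRED_RUN_COLUMNS",
    "REQUIRED_DAILY_COLUMNS",
]


@dataclass(frozen=True)
class IntakeStats:
    """Per-run alkaloid-intake statistics.

    ``mean_daily``/``sd_daily`` summarize all cow-day intakes; the max
    statistics first take each cow's worst day, then summarize across
    cows; ``cv_total`` is the coefficient of variation of per-cow total
    intake (a dilution/evenness measure).
    """

    mean_daily: float
    sd_daily: float
    mean_max: float
    sd_max: float
    cv_total: float


def intake_statistics(daily: pd.DataFrame) -> IntakeStats:
    """Summarize one run's daily alkaloid intake records.

    Expects columns ``cow_id`` and ``daily_msal_mg`` (one row per cow per
    grazing-day).
    """
    if len(daily) == 0:
        raise SchemaError("intake_statistics requires at least one record")
    vals = daily["daily_msal_mg"].to_numpy(dtype=float)
    per_cow = daily.groupby("cow_id")["daily_msal_mg"]
    maxima = per_cow.max().to_numpy(dtype=float)
    totals = per_cow.sum().to_numpy(dtype=float)
    total_mean = totals.mean()
    cv = float(totals.std(ddof=0) / total_mean) if total_mean > 0 else 0.0
    return IntakeStats(
        mean_daily=float(vals.mean()),
        sd_daily=float(vals.std(ddof=0)),
        mean_max=float(maxima.mean()),
        sd_max=float(maxima.std(ddof=0)),
        cv_total=cv,
    )


def grazing_heterogeneity(pasture: Pasture) -> float:
    """Population SD of times-grazed over accessible cells (grazing evenness)."""
    return float(pasture.times_grazed[pasture.accessible].std(ddof=0))


def herd_move_fraction(move_log) -> float:
    """Fraction of patch-choice moves made by herding (vs environmental).

    *move_log* is a sequence whose truthy entries (or entries equal to
    ``"herd"``) are herd-up moves.
    """
    moves = list(move_log)
    if not moves:
        raise SchemaError("herd_move_fraction requires at least one move")
    n_herd = sum(1 for m in moves if m == "herd" or m is True)
    return n_herd / len(moves)


def detect_subherds(
    positions: np.ndarray, linkage_distance_m: float = 50.0
) -> tuple[int, list[int]]:
    """Single-linkage clusters of cow positions at the linkage distance.

    Returns (cluster count, sorted descending cluster sizes).  Two cows
    belong to the same subherd if a chain of cows with consecutive
    distances <= ``linkage_distance_m`` connects them.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(pos)
    if n == 0:
        raise SchemaError("detect_subherds requires at least one cow")
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = cKDTree(pos)
    for a, b in tree.query_pairs(linkage_distance_m):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots = [find(i) for i in range(n)]
    sizes = pd.Series(roots).value_counts().to_list()
    return len(sizes), sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

REQUIRED_RUN_COLUMNS = ("hcf", "sd", "deaths")
REQUIRED_DAILY_COLUMNS = ("run_id", "grazing_day", "cow_id", "daily_msal_mg")


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def write_run_summaries(df: pd.DataFrame, path: str | Path) -> None:
    """Write a run-summary table (UTF-8, comma-separated, one header row)."""
    df.to_csv(path, index=False)


def read_run_summaries(path: str | Path) -> pd.DataFrame:
    """Read a run-summary CSV; unknown columns are preserved.

    Requires at least the factor columns ``hcf`` and ``sd`` and the
    response ``deaths``, so externally produced end-of-run tables with
    extra columns load unchanged.
    """
    return _read_csv(path, REQUIRED_RUN_COLUMNS)


def write_daily_records(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_daily_records(path: str | Path) -> pd.DataFrame:
    """Read a daily-intake CSV (one row per cow per grazing-day)."""
    return _read_csv(path, REQUIRED_DAILY_COLUMNS)
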
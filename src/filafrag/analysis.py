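"""Threshold calibration, summary statistics, and threshold-grid scans.

Thresholds are calibrated so that different rules can be compared at the
same mean adult size: for a target size ``T`` the calibrator minimizes the
mean squared error ``mean((parent_size - T)^2)`` over a seeded batch of
fragmentation events, scanning a coarse grid and then refining around the
best coarse value. Every candidate is scored on the same child seed
sequence (common random numbers), which makes the noisy comparison between
neighbouring candidates paired; ties go to the smaller threshold.

Summaries report the adult-size distribution (mean, population standard
deviation, MSE against the target, fraction of events at exactly the
target, histogram) and reproduction-mode frequencies, optionally binned by
adult size. ``grid_scan`` maps the signed mean-size deviation and the L2
error (root mean squared error) over a (θ1, θ2) grid for Boolean
rule combinations.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import (
    EngineConfig,
    NonTerminationError,
    collect_events,
    run_many,
)
from .lifecycle import MODES, FragmentationEvent
from .rules import CombinedRuleSpec, RuleSpec

__all__ = [
    "SizeSummary",
    "ModeSummary",
    "CalibrationResult",
    "GridScan",
    "DEFAULT_SEARCH_GRIDS",
    "summarize",
    "binned_modes",
    "events_frame",
    "calibrate_threshold",
    "grid_scan",
]

#: coarse calibration grids bracketing the thresholds that yield a mean
#: adult size of ~32 cells for each rule family (pass an explicit grid for
#: very different targets)
DEFAULT_SEARCH_GRIDS: dict[str, np.ndarray] = {
    "cell_age": np.arange(2.0, 5.01, 0.5),
    "connection_age": np.arange(1.5, 7.51, 0.5),
    "compound": np.array(
        [120, 150, 170, 180, 185, 190, 195, 200, 205], float
    ),
    "stress": np.arange(1.0, 31.0),
    "stochastic_at_division": np.geomspace(0.01, 0.5, 10),
    "stochastic_in_time": np.geomspace(1e-4, 5e-3, 10),
}


@dataclass(frozen=True)
class SizeSummary:
    """Adult-size distribution of a batch of events."""

    n_events: int
    mean_adult_size: float
    sd_adult_size: float
    mse_vs_target: float
    fraction_at_target: float
    histogram: dict[int, int]
    target_size: int


@dataclass(frozen=True)
class ModeSummary:
    """Reproduction-mode frequencies of a batch of events."""

    frequencies: dict[str, float]
    n_events: int


def summarize(
    events: Sequence[FragmentationEvent], target_size: int
) -> tuple[SizeSummary, ModeSummary]:
    """Adult-size and mode summaries of an event batch."""
    if not events:
        raise ValueError("cannot summarize an empty event list")
    sizes = np.array([e.parent_size for e in events], dtype=float)
    hist = Counter(int(s) for s in sizes)
    size_summary = SizeSummary(
        n_events=len(events),
        mean_adult_size=float(sizes.mean()),
        sd_adult_size=float(sizes.std()),
        mse_vs_target=float(np.mean((sizes - target_size) ** 2)),
        fraction_at_target=float(np.mean(sizes == target_size)),
        histogram=dict(sorted(hist.items())),
        target_size=int(target_size),
    )
    counts = Counter(e.mode for e in events)
    freqs = {m: counts.get(m, 0) / len(events) for m in MODES}
    return size_summary, ModeSummary(frequencies=freqs, n_events=len(events))


def events_frame(events: Sequence[FragmentationEvent]) -> pd.DataFrame:
    """Events as a DataFrame (one row per event)."""
    return pd.DataFrame(
        {
            "time": [e.time for e in events],
            "parent_size": [e.parent_size for e in events],
            "offspring_sizes": [
                ";".join(str(s) for s in e.offspring_sizes) for e in events
            ],
            "n_offspring": [e.n_offspring for e in events],
            "mode": [e.mode for e in events],
            "rule": [e.rule for e in events],
        }
    )


def binned_modes(
    events: Sequence[FragmentationEvent], bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Reproduction-mode frequencies per adult-size bin.

    Bins are half-open ``[left, right)`` on adult size. Rows of bins that
    received no events hold NaN frequencies (flagged empty rather than
    zero-filled); every mode column is kept even below any display cutoff.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    df = events_frame(events)
    df["bin"] = pd.cut(df["parent_size"], bins=edges, right=False)
    out = []
    for interval, group in df.groupby("bin", observed=False):
        row: dict[str, float] = {"n_events": len(group)}
        for m in MODES:
            row[m] = (
                float((group["mode"] == m).mean()) if len(group) else math.nan
            )
        out.append(pd.Series(row, name=interval))
    result = pd.DataFrame(out)
    result.index.name = "adult_size_bin"
    result["n_events"] = result["n_events"].astype(int)
    return result


# --------------------------------------------------------------------- #
# calibration


RuleFamily = Callable[[float], RuleSpec | CombinedRuleSpec]


def _as_family(
    rule_family: str | RuleFamily, death_variant: bool
) -> tuple[RuleFamily, str | None]:
    if callable(rule_family):
        return rule_family, None
    cue = str(rule_family)
    return (
        lambda theta: RuleSpec(cue, float(theta), death_variant=death_variant),
        cue,
    )


def score_rule(
    spec: RuleSpec | CombinedRuleSpec,
    target_size: int,
    n_events: int,
    seed: int | None,
    *,
    aging: bool = False,
    **config_overrides,
) -> tuple[float, float]:
    """(MSE against target, mean adult size) of a seeded event batch.

    A rule that never fires within the engine's budget scores ``inf``.
    """
    config = EngineConfig(rule=spec, seed=seed, aging=aging, **config_overrides)
    try:
        records = run_many(config, n_events)
    except (NonTerminationError,):
        return math.inf, math.nan
    sizes = np.array(
        [e.parent_size for e in collect_events(records, n_events)], dtype=float
    )
    if sizes.size == 0:
        return math.inf, math.nan
    return float(np.mean((sizes - target_size) ** 2)), float(sizes.mean())


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a threshold search."""

    theta: float
    mse: float
    mean_adult_size: float
    table: pd.DataFrame = field(repr=False)

    def __float__(self) -> float:
        return self.theta


def calibrate_threshold(
    rule_family: str | RuleFamily,
    target_size: int = 32,
    events_per_candidate: int = 2000,
    search_grid: Sequence[float] | None = None,
    *,
    seed: int = 0,
    death_variant: bool = False,
    aging: bool = False,
    refine: bool = True,
    refine_points: int = 7,
    **config_overrides,
) -> CalibrationResult:
    """Find the threshold minimizing the mean squared adult-size error.

    ``rule_family`` is a cue name or a callable mapping θ to a rule spec.
    All candidates are scored on the same master seed (common random
    numbers). With ``refine`` a second pass scans ``refine_points`` values
    between the coarse best's neighbours. Ties break toward smaller θ.
    """
    family, cue = _as_family(rule_family, death_variant)
    if search_grid is None:
        if cue is None or cue not in DEFAULT_SEARCH_GRIDS:
            raise ValueError(
                "a search_grid is required for custom rule families"
            )
        search_grid = DEFAULT_SEARCH_GRIDS[cue]
    grid = np.sort(np.asarray(search_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("search_grid must be nonempty")
    if target_size < 2:
        raise ValueError("target_size must be at least 2")

    rows: list[dict[str, float]] = []

    def scan(values: np.ndarray) -> tuple[float, float, float]:
        best = (math.inf, math.nan, math.nan)  # mse, theta, mean
        for theta in values:
            mse, mean = score_rule(
                family(float(theta)),
                target_size,
                events_per_candidate,
                seed,
                aging=aging,
                **config_overrides,
            )
            rows.append(
                {"theta": float(theta), "mse": mse, "mean_adult_size": mean}
            )
            if mse < best[0]:
                best = (mse, float(theta), mean)
        return best

    best_mse, best_theta, best_mean = scan(grid)
    if math.isinf(best_mse):
        raise NonTerminationError(
            "no candidate threshold produced fragmentation events; "
            "widen the search grid"
        )
    if refine and grid.size > 1:
        i = int(np.argmin(np.abs(grid - best_theta)))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        fine = np.linspace(lo, hi, refine_points)
        mse2, theta2, mean2 = scan(fine)
        # strictly better only: equal scores keep the earlier (smaller) θ
        if mse2 < best_mse or (mse2 == best_mse and theta2 < best_theta):
            best_mse, best_theta, best_mean = mse2, theta2, mean2
    table = pd.DataFrame(rows).sort_values("theta").reset_index(drop=True)
    return CalibrationResult(
        theta=best_theta, mse=best_mse, mean_adult_size=best_mean, table=table
    )


# --------------------------------------------------------------------- #
# grid scans for combined rules


@dataclass(frozen=True)
class GridScan:
    """Mean-size deviation and L2 error over a (θ1, θ2) grid."""

    theta1: np.ndarray
    theta2: np.ndarray
    logic: str
    mean_deviation: np.ndarray  # signed, mean(parent) - target; [i, j]
    l2_error: np.ndarray  # sqrt(mean squared error)
    events_per_cell: int
    target_size: int


def grid_scan(
    cue1: str,
    cue2: str,
    theta1_grid: Sequence[float],
    theta2_grid: Sequence[float],
    logic: str,
    target_size: int = 32,
    events_per_cell: int = 2000,
    *,
    seed: int = 0,
    scope: str = "cell",
    **config_overrides,
) -> GridScan:
    """Scan a Boolean combination of two rules over a threshold grid.

    Cell ``[i, j]`` uses ``theta1_grid[i]`` and ``theta2_grid[j]``; every
    cell is scored on the same child seeds. Cells where the combined rule
    never fires hold NaN deviation and infinite L2 error.
    """
    t1 = np.asarray(theta1_grid, dtype=float)
    t2 = np.asarray(theta2_grid, dtype=float)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("threshold grids must be nonempty")
    if np.any(np.diff(t1) <= 0) or np.any(np.diff(t2) <= 0):
        raise ValueError("threshold grids must be strictly increasing")
    dev = np.full((t1.size, t2.size), math.nan)
    l2 = np.full((t1.size, t2.size), math.inf)
    for i, a in enumerate(t1):
        for j, b in enumerate(t2):
            spec = CombinedRuleSpec(
                rule1=RuleSpec(cue1, float(a)),
                rule2=RuleSpec(cue2, float(b)),
                logic=logic,  # type: ignore[arg-type]
                scope=scope,  # type: ignore[arg-type]
            )
            mse, mean = score_rule(
                spec, target_size, events_per_cell, seed, **config_overrides
            )
            if math.isfinite(mse):
                dev[i, j] = mean - target_size
                l2[i, j] = math.sqrt(mse)
    return GridScan(
        theta1=t1,
        theta2=t2,
        logic=logic,
        mean_deviation=dev,
        l2_error=l2,
        events_per_cell=events_per_cell,
        target_size=target_size,
    )
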
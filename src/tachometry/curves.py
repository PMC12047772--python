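"""Tachometric functions: accuracy as a smooth function of raw processing time.

The pipeline is: pool trials (aggregated over participants) into 1-ms rPT
bins, i.e. mean correctness at each integer rPT value with at least one
trial; smooth the binwise accuracies with LOESS (span 0.2, degree 2,
tricube weights); read off curve features such as the global minimum, whose
sampling variability is estimated by a trial-level bootstrap.

Curves are functions on the observed-bin support only — grid values with
no trials are never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .smoothing import loess_fit
from .trials import CONGRUENCIES, TrialTable

DEFAULT_SPAN = 0.2
DEFAULT_DEGREE = 2


@dataclass
class BinnedCurvePoints:
    """Raw binwise accuracies: for each grid value, mean correctness and n."""

    rpt_ms: np.ndarray       # integer grid values (bin centers), sorted
    accuracy: np.ndarray     # mean correctness per grid value, in [0, 1]
    n: np.ndarray            # trial count per grid value, >= 1
    bin_width: int = 1

    def __len__(self) -> int:
        return len(self.rpt_ms)


@dataclass
class TachometricCurve:
    """A smoothed accuracy curve for one congruency condition."""

    rpt_grid: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int
    condition: str
    n_points: int
    points: BinnedCurvePoints | None = field(default=None, repr=False)


@dataclass
class CurveMinimum:
    """Location and depth of a curve's global minimum within a search range."""

    rpt_at_min: int
    value: float
    search_lo: int
    search_hi: int

    @property
    def drop_vs_chance(self) -> float:
        return self.value - 0.5


@dataclass
class BootstrapSE:
    """Bootstrap SE of a curve-minimum value (trial-level resampling)."""

    n_reps: int
    replicate_minima: np.ndarray
    se: float
    seed: int
    condition: str


def _pool_arrays(
    rpt: np.ndarray, correct: np.ndarray, bin_width: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast binwise pooling on plain arrays; returns (centers, accuracy, n)."""
    if bin_width > 1:
        centers = np.floor_divide(rpt, bin_width) * bin_width + bin_width // 2
    else:
        centers = rpt
    lo = centers.min()
    shifted = centers - lo
    n = np.bincount(shifted)
    hits = np.bincount(shifted, weights=correct.astype(float))
    support = n > 0
    grid = np.flatnonzero(support) + lo
    return grid, hits[support] / n[support], n[support]


def pool_accuracy_1ms(table: TrialTable, bin_width: int = 1) -> BinnedCurvePoints:
    """Pool trials into rPT bins of ``bin_width`` ms (default 1).

    With the default width the grid is simply every integer rPT value
    carrying at least one trial; wider bins (labeled by center) are a speed
    option for simulation studies. Accuracy times n is an integer count by
    construction. The table should already be exclusion-filtered.
    """
    if len(table) == 0:
        raise ValueError("cannot pool an empty trial table")
    rpt = table.data["rpt_ms"].to_numpy("int64")
    correct = table.data["correct"].to_numpy(bool)
    grid, acc, n = _pool_arrays(rpt, correct, bin_width)
    return BinnedCurvePoints(grid, acc, n, bin_width=bin_width)


def local_regression_smooth(
    points: BinnedCurvePoints,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    condition: str = "",
    count_weighted: bool = False,
) -> TachometricCurve:
    """Smooth binwise accuracies with LOESS, evaluated at every grid point.

    The fit is unweighted by bin counts by default (the binwise means enter
    the regression as equal observations); ``count_weighted=True``
    multiplies the tricube weights by each bin's trial count.
    """
    w = points.n.astype(float) if count_weighted else None
    fitted = loess_fit(
        points.rpt_ms.astype(float), points.accuracy,
        span=span, degree=degree, weights=w,
    )
    return TachometricCurve(
        rpt_grid=points.rpt_ms.copy(), fitted=fitted, span=span,
        degree=degree, condition=condition, n_points=len(points), points=points,
    )


def tachometric_curves(
    table: TrialTable,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    bin_width: int = 1,
    count_weighted: bool = False,
) -> dict[str, TachometricCurve]:
    """One pooled-and-smoothed curve per congruency condition."""
    out = {}
    for cond in CONGRUENCIES:
        sub = table.data[table.data["congruency"] == cond]
        if len(sub) == 0:
            raise ValueError(f"no trials in the {cond!r} condition")
        pts = pool_accuracy_1ms(
            TrialTable(sub.reset_index(drop=True), deadline_ms=table.deadline_ms),
            bin_width=bin_width,
        )
        out[cond] = local_regression_smooth(
            pts, span=span, degree=degree, condition=cond,
            count_weighted=count_weighted,
        )
    return out


def curve_minimum(
    curve: TachometricCurve, search_lo: int = -200, search_hi: int = 1000
) -> CurveMinimum:
    """Global minimum of the fitted curve over grid points in the range.

    Ties are broken toward the smallest rPT.
    """
    mask = (curve.rpt_grid >= search_lo) & (curve.rpt_grid <= search_hi)
    if not mask.any():
        raise ValueError(
            f"curve has no grid points in [{search_lo}, {search_hi}]"
        )
    vals = curve.fitted[mask]
    grid = curve.rpt_grid[mask]
    i = int(np.argmin(vals))  # argmin returns the first (smallest-rpt) tie
    return CurveMinimum(
        rpt_at_min=int(grid[i]), value=float(vals[i]),
        search_lo=search_lo, search_hi=search_hi,
    )


def bootstrap_minimum_se(
    table: TrialTable,
    condition: str,
    n_reps: int = 1000,
    seed: int = 0,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    bin_width: int = 1,
    search_lo: int = -200,
    search_hi: int = 1000,
) -> BootstrapSE:
    """Bootstrap SE of one condition's minimum accuracy.

    Trials of the condition are resampled with replacement (same n); each
    replicate repeats pooling, smoothing and minimum extraction; the SE is
    the standard deviation (ddof=1) of the replicate minimum values.
    """
    sub = table.data[table.data["congruency"] == condition]
    if len(sub) < 2:
        raise ValueError(f"need >= 2 trials in condition {condition!r}")
    rpt = sub["rpt_ms"].to_numpy("int64")
    correct = sub["correct"].to_numpy(bool)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    minima = np.empty(n_reps)
    for r in range(n_reps):
        take = rng.integers(0, len(rpt), size=len(rpt))
        grid, acc, _ = _pool_arrays(rpt[take], correct[take], bin_width)
        fitted = loess_fit(grid.astype(float), acc, span=span, degree=degree)
        m = (grid >= search_lo) & (grid <= search_hi)
        minima[r] = fitted[m].min()
    se = float(minima.std(ddof=1)) if n_reps > 1 else 0.0
    return BootstrapSE(
        n_reps=n_reps, replicate_minima=minima, se=se, seed=seed,
        condition=condition,
    )


def curves_to_frame(curves: dict[str, TachometricCurve]) -> pd.DataFrame:
    """Flatten curves to a tidy frame (condition, rpt_ms, fitted, accuracy, n)."""
    frames = []
    for cond, c in curves.items():
        frames.append(pd.DataFrame({
            "condition": cond,
            "rpt_ms": c.rpt_grid,
            "fitted": c.fitted,
            "accuracy": c.points.accuracy if c.points is not None else np.nan,
            "n": c.points.n if c.points is not None else 0,
        }))
    return pd.concat(frames, ignore_index=True)


def minima_to_json(
    minima: dict[str, CurveMinimum],
    ses: dict[str, BootstrapSE] | None = None,
    path: str | Path | None = None,
) -> dict:
    """Serialize minima (and optional bootstrap SEs) to a JSON record."""
    rec = {}
    for cond, m in minima.items():
        rec[cond] = {
            "rpt_at_min": m.rpt_at_min,
            "value": m.value,
            "drop_vs_chance": m.drop_vs_chance,
            "search_lo": m.search_lo,
            "search_hi": m.search_hi,
        }
        if ses and cond in ses:
            rec[cond]["bootstrap_se"] = ses[cond].se
            rec[cond]["bootstrap_reps"] = ses[cond].n_reps
    if path is not None:
        Path(path).write_text(json.dumps(rec, indent=2))
    return rec
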
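"""Size-versus-position profiles.

A *size profile* records a cell- or organ-level dimension (length, width or
thickness) as a function of distance from the leaf base, one profile per
biological replicate.  Raw measurements are aggregated per position, smoothed
with a tricube-weighted local polynomial onto a regular millimetre grid, and
averaged across replicates with a standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SizeProfile",
    "SmoothedProfile",
    "read_profiles",
    "write_profiles",
    "smooth_profile",
    "aggregate_replicates",
]

DIMENSIONS = ("length", "width", "thickness")
LEVELS = ("cell", "organ")
#: organ-level length is handled through the leaf elongation rate, not a profile
VALID_COMBOS = frozenset(
    [("cell", d) for d in DIMENSIONS] + [("organ", "width"), ("organ", "thickness")]
)

REQUIRED_COLUMNS = ("replicate", "dimension", "level", "position_mm", "size")


@dataclass
class SizeProfile:
    """Per-replicate sizes versus distance from the leaf base.

    Positions are millimetres from the visible leaf base.  Sizes are in the
    measurement units of the level: µm for cell dimensions and leaf thickness,
    mm for leaf width.  ``counts`` records how many raw measurements (e.g.
    individual cells) were averaged at each position.
    """

    replicate_id: str
    dimension: str
    level: str
    positions: np.ndarray
    sizes: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if (self.level, self.dimension) not in VALID_COMBOS:
            raise ValueError(
                f"invalid combination level={self.level!r} dimension={self.dimension!r}"
            )
        if self.positions.ndim != 1 or self.positions.shape != self.sizes.shape:
            raise ValueError("positions and sizes must be 1-D arrays of equal length")
        if np.any(self.positions < 0):
            raise ValueError("positions must be >= 0 (mm from leaf base)")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing after aggregation")
        if np.any(self.sizes <= 0) or not np.all(np.isfinite(self.sizes)):
            raise ValueError("sizes must be finite and strictly positive")
        if self.counts is None:
            self.counts = np.ones_like(self.sizes)
        else:
            self.counts = np.asarray(self.counts, dtype=float)

    @property
    def span(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass
class SmoothedProfile:
    """A profile evaluated on a regular grid, with cross-replicate SE."""

    grid: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_reps: int = 1
    dimension: str | None = None
    level: str | None = None
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (len(self.grid) == len(self.mean) == len(self.se)):
            raise ValueError("grid, mean and se must have equal length")
        steps = np.diff(self.grid)
        if len(steps) and not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("grid step must be uniform")

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if len(self.grid) > 1 else np.nan

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the smoothed mean (no extrapolation)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.grid[0] - 1e-9) or np.any(x > self.grid[-1] + 1e-9):
            raise ValueError("evaluation outside the smoothed range")
        return np.interp(x, self.grid, self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid_mm": self.grid,
                "mean": self.mean,
                "se": self.se,
                "n": self.n_reps,
            }
        )


def read_profiles(path, sep: str | None = None) -> list[SizeProfile]:
    """Read size profiles from a delimited text file.

    Expects columns ``replicate, dimension, level, position_mm, size``.
    Repeated (replicate, dimension, level, position) rows — e.g. the ~20
    individual cells measured per position — are reduced to their mean, with
    the count preserved in :attr:`SizeProfile.counts`.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    bad = df.index[~(df["size"] > 0) | ~np.isfinite(df["size"])]
    if len(bad):
        raise ValueError(
            f"non-positive or non-finite size at row {int(bad[0])} of {path}"
        )
    unknown = set(df["dimension"].unique()) - set(DIMENSIONS)
    if unknown:
        row = int(df.index[df["dimension"].isin(unknown)][0])
        raise ValueError(f"unknown dimension {unknown} at row {row} of {path}")

    profiles = []
    grouped = df.groupby(["replicate", "dimension", "level"], sort=True)
    for (rep, dim, level), g in grouped:
        agg = g.groupby("position_mm")["size"].agg(["mean", "count"]).sort_index()
        profiles.append(
            SizeProfile(
                replicate_id=str(rep),
                dimension=str(dim),
                level=str(level),
                positions=agg.index.to_numpy(),
                sizes=agg["mean"].to_numpy(),
                counts=agg["count"].to_numpy(),
            )
        )
    return profiles


def write_profiles(profiles: list[SizeProfile], path, sep: str = ",") -> None:
    """Write profiles in the same tabular dialect that :func:`read_profiles` reads."""
    rows = []
    for p in profiles:
        for x, s, c in zip(p.positions, p.sizes, p.counts):
            rows.append((p.replicate_id, p.dimension, p.level, x, s, int(c)))
    pd.DataFrame(
        rows, columns=["replicate", "dimension", "level", "position_mm", "size", "n_measured"]
    ).to_csv(path, sep=sep, index=False)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def smooth_profile(
    profile: SizeProfile,
    bandwidth: float = 0.3,
    degree: int = 2,
    grid_step: float = 1.0,
) -> SmoothedProfile:
    """Local polynomial smoothing onto a regular grid.

    At each grid point a polynomial of ``degree`` is fitted by weighted least
    squares to the observations within a window of half-width
    ``bandwidth * span`` (tricube weights).  Windows holding fewer than
    ``degree + 2`` points are widened to the nearest ``degree + 2`` points so
    the fit stays determined on sparse sampling schemes.  The grid is clipped
    to the sampled range — no extrapolation — and includes position 0 only if
    it was sampled.
    """
    if not 0 < bandwidth <= 1:
        raise ValueError("bandwidth must be in (0, 1] (fraction of sampled span)")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x, y = profile.positions, profile.sizes
    if len(np.unique(x)) < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} distinct positions, got {len(np.unique(x))}"
        )
    span = profile.span
    if span <= 0:
        raise ValueError("all positions identical; nothing to smooth")

    lo, hi = x[0], x[-1]
    grid = np.arange(0.0, hi + 1e-9, grid_step)
    grid = grid[grid >= lo - 1e-9]

    h0 = bandwidth * span
    k_min = degree + 2
    mean = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = h0
        if np.count_nonzero(d < h) < k_min:
            h = np.partition(d, k_min - 1)[k_min - 1] * (1 + 1e-9)
        w = _tricube(d / h)
        # polyfit minimises sum (w_i * (y_i - p(x_i)))^2, so pass sqrt weights
        coeffs = np.polynomial.polynomial.polyfit(x - x0, y, degree, w=np.sqrt(w))
        mean[i] = coeffs[0]

    return SmoothedProfile(
        grid=grid,
        mean=mean,
        se=np.zeros_like(grid),
        n_reps=1,
        dimension=profile.dimension,
        level=profile.level,
        replicate_id=profile.replicate_id,
    )


def aggregate_replicates(smoothed: list[SmoothedProfile]) -> SmoothedProfile:
    """Pointwise mean and SE (sd/√n) across replicate profiles.

    Grids are intersected if they differ; a single replicate yields SE = 0 by
    convention.
    """
    if not smoothed:
        raise ValueError("no replicates to aggregate")
    common = smoothed[0].grid
    for p in smoothed[1:]:
        common = np.intersect1d(np.round(common, 9), np.round(p.grid, 9))
    if len(common) == 0:
        raise ValueError("replicate grids share no common positions")
    vals = np.vstack(
        [p.mean[np.isin(np.round(p.grid, 9), common)] for p in smoothed]
    )
    n = len(smoothed)
    mean = vals.mean(axis=0)
    se = vals.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    dims = {p.dimension for p in smoothed}
    levels = {p.level for p in smoothed}
    if len(dims) > 1 or len(levels) > 1:
        warnings.warn("aggregating profiles of mixed dimension/level", stacklevel=2)
    return SmoothedProfile(
        grid=common,
        mean=mean,
        se=se,
        n_reps=n,
        dimension=smoothed[0].dimension if len(dims) == 1 else None,
        level=smoothed[0].level if len(levels) == 1 else None,
    )
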
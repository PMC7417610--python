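"""Growth-zone delimitation from smoothed size profiles.

The growth zone ends where the profile reaches 95% of its mature (plateau)
size; the mature size is in turn the average of the profile distal to the
growth zone.  This mutual definition is resolved by fixed-point iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .profiles import SmoothedProfile

__all__ = ["GrowthZoneEstimate", "estimate_mature_size", "estimate_growth_zone"]


@dataclass
class GrowthZoneEstimate:
    """Growth-zone length and mature size for one dimension at one level."""

    L_gz: float
    mature_size: float
    threshold: float
    converged: bool
    plateau_detected: bool
    n_iter: int
    dimension: str | None = None
    level: str | None = None


def estimate_mature_size(profile: SmoothedProfile, L_gz: float) -> float:
    """Mean of the smoothed profile at grid positions strictly distal to ``L_gz``."""
    distal = profile.mean[profile.grid > L_gz + 1e-12]
    if len(distal) == 0:
        raise ValueError("profile does not extend beyond growth zone")
    return float(distal.mean())


def _crossing_position(grid: np.ndarray, y: np.ndarray, thr: float) -> float | None:
    """Smallest position after which the profile stays >= thr, sub-grid refined.

    Returns None when no suffix of the profile stays above the threshold.
    The "stays above" rule (rather than first touch) is robust to noise dips.
    """
    ok = y >= thr
    if not ok[-1]:
        return None
    below = np.flatnonzero(~ok)
    if len(below) == 0:
        return float(grid[0])
    i = int(below[-1]) + 1  # first index of the all-above suffix
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = y[i - 1], y[i]
    if y1 > y0:  # linear interpolation between bracketing grid points
        return float(x0 + (thr - y0) / (y1 - y0) * (x1 - x0))
    return float(x1)


def _plateau_detected(grid: np.ndarray, y: np.ndarray, rel_rise: float = 0.05) -> bool:
    """False when the distal 20% of the profile still rises by more than 5%.

    The rise is judged from a least-squares line over the distal window, so a
    single noisy endpoint does not decide the flag.
    """
    k = max(2, int(np.ceil(0.2 * len(grid))))
    xs, ys = grid[-k:], y[-k:]
    slope, intercept = np.polyfit(xs, ys, 1)
    start, end = slope * xs[0] + intercept, slope * xs[-1] + intercept
    if start <= 0:
        return True
    return (end - start) / start <= rel_rise


def estimate_growth_zone(
    profile: SmoothedProfile,
    threshold: float = 0.95,
    max_iter: int = 50,
) -> GrowthZoneEstimate:
    """Delimit the growth zone as the position where the profile reaches
    ``threshold`` (default 95%) of the mature size.

    Mature size is initialised from the distal 20% of the grid, the growth-zone
    end is located as the first position after which the profile stays above
    threshold x mature (with sub-grid linear refinement), the mature size is
    recomputed distal to it, and the two are iterated to a fixed point
    (change in L_gz below one grid step).
    """
    grid, y = profile.grid, profile.mean
    if len(grid) < 3:
        raise ValueError("profile too short to delimit a growth zone")
    if np.any(y < 0) or y[-1] <= 0:
        raise ValueError("profile values must be non-negative with a positive plateau")
    if y[-1] < y[0]:
        warnings.warn(
            "profile does not trend upward; growth-zone estimate may be meaningless",
            stacklevel=2,
        )
    step = profile.grid_step if len(grid) > 1 else 1.0

    k = max(1, int(np.ceil(0.2 * len(grid))))
    mature = float(y[-k:].mean())
    plateau = _plateau_detected(grid, y)

    L_gz = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        pos = _crossing_position(grid, y, threshold * mature)
        if pos is None:  # profile never settles above threshold
            L_gz = float(grid[-1])
            converged = False
            break
        if abs(pos - L_gz) < step:
            L_gz = pos
            converged = True
            break
        L_gz = pos
        if grid[-1] <= L_gz:
            converged = False
            break
        mature = estimate_mature_size(profile, L_gz)
    if converged and grid[-1] > L_gz:
        mature = estimate_mature_size(profile, L_gz)
    return GrowthZoneEstimate(
        L_gz=L_gz,
        mature_size=mature,
        threshold=threshold,
        converged=converged,
        plateau_detected=plateau,
        n_iter=n_iter,
        dimension=profile.dimension,
        level=profile.level,
    )
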
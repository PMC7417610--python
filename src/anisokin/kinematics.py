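"""Kinematic analysis of the leaf growth zone.

Under steady-state growth the spatial profile of cell length l(x) and the
leaf elongation rate (LER) determine the whole cellular dynamics of the
growth zone:

    P      = LER / l_mat              cell production rate (cells/h per file)
    D      = P / N_mer                average cell division rate (1/h)
    T_c    = ln 2 / D                 cell cycle duration (h)
    T_mer  = log2(N_mer) * T_c        residence time in the meristem (h)
    T_el   = N_el / P                 residence time in the elongation zone (h)
    N      = integral dx / l(x)       cells in an interval [a, b]
    F(x)   = P * x / L_mer  (x <= L_mer), else P        cell flux (cells/h)
    v(x)   = l(x) * F(x)              displacement velocity (mm/h)
    RGR(x) = dv/dx                    relative elemental growth rate (1/h)

Zone-averaged relative growth rates in all three dimensions use
RGR = ln(size2/size1)/dt with sizes read off the smoothed profile at the
zone boundaries and dt the residence time in the zone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .growthzone import GrowthZoneEstimate
from .profiles import SmoothedProfile

__all__ = [
    "KinematicParams",
    "FluxVelocityProfile",
    "leaf_elongation_rate",
    "cell_production_rate",
    "count_cells",
    "division_params",
    "elongation_residence",
    "flux_profile",
    "velocity_profile",
    "rgr_length_profile",
    "zone_rgr",
    "anisotropy_ratios",
    "percent_difference",
    "compute_kinematics",
]


@dataclass
class FluxVelocityProfile:
    """Cell flux, displacement velocity and elemental growth rate on a grid."""

    grid: np.ndarray            # mm from leaf base
    flux: np.ndarray            # cells/h
    velocity: np.ndarray        # mm/h
    rgr_length: np.ndarray      # 1/h


@dataclass
class KinematicParams:
    """The full kinematic parameter set for one genotype."""

    ler: float                  # mm/h
    l_mat: float                # mm, mature cell length
    L_mer: float                # mm, meristem length
    P: float                    # cells/h
    D: float                    # 1/h
    T_c: float                  # h
    N_mer: float                # cells
    T_mer: float                # h
    L_gz: dict = field(default_factory=dict)       # (dimension, level) -> mm
    N_el: dict = field(default_factory=dict)       # dimension -> cells (cell level)
    T_el: dict = field(default_factory=dict)       # dimension -> h
    mature_size: dict = field(default_factory=dict)  # (dimension, level) -> size
    zone_rgr: dict = field(default_factory=dict)   # (zone, dimension, level) -> 1/h
    anisotropy: dict = field(default_factory=dict)  # (zone, level) -> ratios
    profile: FluxVelocityProfile | None = None


def leaf_elongation_rate(series) -> float:
    """Mean of successive (delta length / delta time) over a leaf-length series.

    ``series`` is a sequence of (time_h, length_mm) pairs at roughly daily
    intervals.  A shrinking leaf yields a negative rate, allowed but flagged.
    """
    pts = sorted((float(t), float(L)) for t, L in series)
    if len(pts) < 2:
        raise ValueError("need at least two (time, length) observations")
    t = np.array([p[0] for p in pts])
    L = np.array([p[1] for p in pts])
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    rates = np.diff(L) / np.diff(t)
    if np.any(rates < 0):
        warnings.warn("leaf length decreased between observations", stacklevel=2)
    return float(rates.mean())


def cell_production_rate(ler: float, l_mat: float) -> float:
    """P = LER / l_mat (cells per hour leaving the meristem, per cell file)."""
    if l_mat <= 0:
        raise ValueError("mature cell length must be positive")
    return ler / l_mat


def count_cells(profile: SmoothedProfile, a: float, b: float) -> float:
    """Number of cells between positions ``a`` and ``b``: N = integral dx / l(x).

    The smoothed cell-length profile is treated as piecewise linear between
    grid points, for which the integral has the closed form
    (x2-x1)/(l2-l1) * ln(l2/l1) per segment; this evaluates the continuity
    integral exactly for the interpolated profile.
    """
    if a >= b:
        raise ValueError("interval start must be below interval end")
    grid, l = profile.grid, profile.mean
    if a < grid[0] - 1e-9 or b > grid[-1] + 1e-9:
        raise ValueError("interval outside the profile grid")
    if np.any(l <= 0):
        raise ValueError("cell lengths must be positive")
    # segment breakpoints: grid nodes inside (a, b) plus the endpoints
    inner = grid[(grid > a) & (grid < b)]
    xs = np.concatenate(([a], inner, [b]))
    ls = np.interp(xs, grid, l)
    dx = np.diff(xs)
    dl = np.diff(ls)
    n_seg = np.where(
        np.abs(dl) > 1e-12 * ls[:-1],
        dx / np.where(dl == 0, 1.0, dl) * np.log(ls[1:] / ls[:-1]),
        dx / (0.5 * (ls[1:] + ls[:-1])),
    )
    return float(n_seg.sum())


def division_params(P: float, N_mer: float) -> tuple[float, float, float]:
    """Division rate, cell cycle duration and meristem residence time.

    D = P/N_mer, T_c = ln2/D, T_mer = log2(N_mer) * T_c.
    """
    if N_mer <= 0:
        raise ValueError("N_mer must be positive")
    D = P / N_mer
    T_c = math.log(2) / D
    T_mer = math.log2(N_mer) * T_c
    return D, T_c, T_mer


def elongation_residence(N_el: float, P: float) -> float:
    """Residence time in the elongation zone, T_el = N_el / P.

    The longitudinal flux P is used for every dimension: cells expanding in
    width or thickness are still displaced by longitudinal growth, so only
    N_el (counted up to that dimension's growth-zone end) differs.
    """
    if P <= 0:
        raise ValueError("cell production rate must be positive")
    return N_el / P


def flux_profile(P: float, L_mer: float, grid: np.ndarray) -> np.ndarray:
    """Cell flux F(x): linear ramp 0 -> P across the meristem, P beyond."""
    if L_mer <= 0:
        raise ValueError("meristem length must be positive")
    grid = np.asarray(grid, dtype=float)
    return np.where(grid <= L_mer, P * grid / L_mer, P)


def velocity_profile(
    cell_length_profile: SmoothedProfile, flux: np.ndarray
) -> np.ndarray:
    """Displacement velocity v(x) = l(x) * F(x), with v = 0 at the base."""
    flux = np.asarray(flux, dtype=float)
    if flux.shape != cell_length_profile.grid.shape:
        raise ValueError("flux and cell-length profile grids are not aligned")
    v = cell_length_profile.mean * flux
    if abs(cell_length_profile.grid[0]) < 1e-12:
        v[0] = 0.0
    return v


def rgr_length_profile(velocity: np.ndarray, grid_step: float) -> np.ndarray:
    """Relative elemental growth rate RGR(x) = dv/dx.

    Central finite differences on the uniform grid, one-sided at the ends.
    """
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    return np.gradient(np.asarray(velocity, dtype=float), grid_step)


def zone_rgr(size1: float, size2: float, dt: float, mode: str = "log") -> float:
    """Zone-averaged relative growth rate from sizes at the zone boundaries.

    ``mode='log'`` (default): ln(size2/size1)/dt — the average RGR of a
    material element traversing the zone in time dt, consistent with
    RGR = dv/dx in the uniform-growth limit.  ``mode='difference'`` gives the
    literal (size2-size1)/dt and ``mode='simple-relative'`` the fractional
    change per unit time relative to size1.
    """
    if dt <= 0:
        raise ValueError("residence time must be positive")
    if mode == "log":
        if size1 <= 0 or size2 <= 0:
            raise ValueError("sizes must be positive in log mode")
        return math.log(size2 / size1) / dt
    if mode == "difference":
        return (size2 - size1) / dt
    if mode == "simple-relative":
        if size1 == 0:
            raise ValueError("size1 must be nonzero")
        return (size2 - size1) / size1 / dt
    raise ValueError(f"unknown mode {mode!r}")


def anisotropy_ratios(
    rgr_length: float, rgr_width: float, rgr_thickness: float | None = None
) -> dict:
    """Ratios of longitudinal to lateral and dorsoventral growth rates."""
    if rgr_length == 0:
        raise ValueError("longitudinal RGR must be nonzero")
    out = {"length_width": rgr_length / rgr_width if rgr_width else math.inf}
    if rgr_thickness is not None:
        out["length_thickness"] = (
            rgr_length / rgr_thickness if rgr_thickness else math.inf
        )
    return out


def percent_difference(
    control_mean: float, treatment_mean: float, rounded: bool = True
):
    """Percent change of treatment relative to control.

    With ``rounded`` (default) the result is the nearest integer, ties
    rounded away from zero, the convention of tabulated genotype contrasts.
    """
    if control_mean == 0:
        raise ValueError("control mean must be nonzero")
    pct = 100.0 * (treatment_mean - control_mean) / control_mean
    if not rounded:
        return pct
    return int(math.floor(pct + 0.5)) if pct >= 0 else int(math.ceil(pct - 0.5))


def compute_kinematics(
    ler: float,
    L_mer: float,
    profiles: dict,
    gz_estimates: dict,
    rgr_mode: str = "log",
) -> KinematicParams:
    """Full kinematic parameter set from smoothed profiles and growth zones.

    Parameters
    ----------
    ler : leaf elongation rate (mm/h).
    L_mer : meristem length (mm), measured independently (e.g. by DAPI).
    profiles : mapping (dimension, level) -> SmoothedProfile.  Cell widths,
        heights and leaf thickness are in µm, cell length in µm, leaf width
        in mm; cell length is converted to mm internally.
    gz_estimates : mapping (dimension, level) -> GrowthZoneEstimate.
    """
    cell_len = profiles[("length", "cell")]
    gz_len = gz_estimates[("length", "cell")]
    # cell lengths arrive in µm; kinematic equations work in mm
    cell_len_mm = SmoothedProfile(
        grid=cell_len.grid,
        mean=cell_len.mean / 1000.0,
        se=cell_len.se / 1000.0,
        n_reps=cell_len.n_reps,
        dimension="length",
        level="cell",
    )
    l_mat = gz_len.mature_size / 1000.0
    if not 0 < L_mer < gz_len.L_gz:
        raise ValueError("meristem length must lie inside the growth zone")

    P = cell_production_rate(ler, l_mat)
    N_mer = count_cells(cell_len_mm, cell_len_mm.grid[0], L_mer)
    D, T_c, T_mer = division_params(P, N_mer)

    params = KinematicParams(
        ler=ler, l_mat=l_mat, L_mer=L_mer, P=P, D=D, T_c=T_c,
        N_mer=N_mer, T_mer=T_mer,
    )
    for key, est in gz_estimates.items():
        params.L_gz[key] = est.L_gz
        params.mature_size[key] = est.mature_size

    # per-dimension elongation-zone residence times: same longitudinal flux,
    # cell counts taken up to that dimension's (cell-level) growth-zone end
    for dim in ("length", "width", "thickness"):
        est = gz_estimates.get((dim, "cell")) or gz_estimates.get((dim, "organ"))
        if est is None:
            continue
        end = min(est.L_gz, cell_len_mm.grid[-1])
        params.N_el[dim] = count_cells(cell_len_mm, L_mer, end)
        params.T_el[dim] = elongation_residence(params.N_el[dim], P)

    # flux / velocity / elemental growth rate on the cell-length grid
    F = flux_profile(P, L_mer, cell_len_mm.grid)
    v = velocity_profile(cell_len_mm, F)
    rgr = rgr_length_profile(v, cell_len_mm.grid_step)
    params.profile = FluxVelocityProfile(
        grid=cell_len_mm.grid, flux=F, velocity=v, rgr_length=rgr
    )

    # zone-averaged RGRs from sizes at zone boundaries
    for (dim, level), prof in profiles.items():
        est = gz_estimates.get((dim, level))
        if est is None:
            continue
        t_el = params.T_el.get(dim)
        base, end = prof.grid[0], min(est.L_gz, prof.grid[-1])
        s_base = float(prof(base))
        s_mer = float(prof(min(L_mer, prof.grid[-1])))
        s_gz = float(prof(end))
        params.zone_rgr[("meristem", dim, level)] = zone_rgr(
            s_base, s_mer, T_mer, mode=rgr_mode
        )
        if t_el is not None and t_el > 0:
            params.zone_rgr[("elongation", dim, level)] = zone_rgr(
                s_mer, s_gz, t_el, mode=rgr_mode
            )

    for zone in ("meristem", "elongation"):
        for level in ("cell", "organ"):
            rl = params.zone_rgr.get((zone, "length", "cell"))
            rw = params.zone_rgr.get((zone, "width", level))
            rt = params.zone_rgr.get((zone, "thickness", level))
            if rl and rw is not None:
                params.anisotropy[(zone, level)] = anisotropy_ratios(rl, rw, rt)
    return params
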
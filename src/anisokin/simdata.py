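"""Steady-state growth-zone simulator with known ground truth.

The generative model mirrors the kinematic framework it is used to test.  A
single cell file grows at steady state: in the meristem (0 <= x <= L_mer)
cells divide, keeping cell length at the division equilibrium l_div while the
cell flux ramps linearly from 0 to the production rate P; in the elongation
zone (L_mer < x < L_gz) the flux is constant at P and the relative elemental
growth rate declines linearly from R_el at the meristem exit to zero at the
end of the growth zone, with R_el = 2 P (l_mat - l_div) / (L_gz - L_mer) so
that cell length arrives exactly at its mature value l_mat.  Velocity follows
v(x) = l(x) F(x); the leaf elongation rate is LER = P l_mat.

Cell width and height are carried along material trajectories: their relative
growth rates in the elongation zone are fixed fractions (aniso_w, aniso_h) of
the longitudinal elemental growth rate, each declining to zero at its own,
possibly different, growth-zone end.  In the meristem, width and height sit
at a division equilibrium like cell length does.  Organ width is the cell
width times a fixed lateral file count; organ thickness is the epidermal cell
height times (1 + inner-tissue factor).

Sampling emulates the field protocol: cell sizes measured on ~20 cells per
fixed position (every centimetre over the basal decimetre for length/width;
sparser fixed sections for thickness), whole-leaf length recorded daily, and
meristem length measured once per replicate.  All size measurements carry
multiplicative lognormal noise of a configurable CV; leaf-length readings
carry additive millimetre-scale ruler noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad
from scipy.optimize import brentq

from .mri import LeafImage, LineProbe
from .profiles import SizeProfile

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticDataset",
    "SteadyStateModel",
    "simulate_growth_zone",
    "generate_section_image",
]

DEFAULT_POSITIONS_LW = tuple(float(x) for x in range(0, 101, 10))
DEFAULT_POSITIONS_T = (5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 60.0, 100.0, 170.0)


@dataclass
class SimConfig:
    """Parameters of the steady-state growth-zone model and its sampling.

    Defaults describe a wild-type maize fourth leaf: a 10-mm meristem inside
    a 60-mm growth zone, 20-µm dividing cells maturing at 147 µm, a cell
    production rate of 16 cells/h (hence LER = 2.35 mm/h), and lateral and
    dorsoventral growth at 0.5x and 0.25x the longitudinal rate, giving
    mature epidermal cells of ~24.4 x 18.1 µm and a ~23-mm, ~91-µm blade.
    """

    L_mer: float = 10.0                  # meristem length, mm
    L_gz: dict = field(
        default_factory=lambda: {"length": 60.0, "width": 60.0, "thickness": 60.0}
    )                                    # growth-zone length per dimension, mm
    l_div: float = 0.020                 # meristem cell length, mm
    l_mat: float = 0.147                 # mature cell length, mm
    w_base: float = 9.0                  # cell width at the base, µm
    h_base: float = 11.0                 # cell height at the base, µm
    aniso_w: float = 0.5                 # lateral RGR / longitudinal RGR
    aniso_h: float = 0.25                # dorsoventral RGR / longitudinal RGR
    P: float = 16.0                      # cell production rate, cells/h
    n_files: int = 950                   # lateral cell files across the blade
    inner_tissue_factor: float = 4.0     # inner tissue thickness / epidermis
    n_reps: int = 5
    cv_noise: float = 0.05               # CV of multiplicative size noise
    leaf_length_sd: float = 1.0          # additive ruler noise on leaf length, mm
    leaf_base_length: float = 200.0      # leaf length at first observation, mm
    n_days: int = 3                      # daily leaf-length intervals
    sample_positions_lw: tuple = DEFAULT_POSITIONS_LW
    sample_positions_t: tuple = DEFAULT_POSITIONS_T
    cells_per_position: int = 20
    seed: int = 0
    midvein_artifact: float = 0.0        # fractional width underestimation at base

    def validate(self) -> None:
        if not 0 < self.L_mer < min(self.L_gz.values()):
            raise ValueError("need 0 < L_mer < every growth-zone length")
        if self.l_div > self.l_mat:
            raise ValueError("dividing cells cannot exceed mature length")
        for name in ("l_div", "l_mat", "w_base", "h_base", "P"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.aniso_w < 0 or self.aniso_h < 0:
            raise ValueError("anisotropy factors must be >= 0")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be >= 0")
        if self.n_reps < 1 or self.cells_per_position < 1:
            raise ValueError("n_reps and cells_per_position must be >= 1")
        if not 0 <= self.midvein_artifact < 1:
            raise ValueError("midvein_artifact must be in [0, 1)")


@dataclass
class GroundTruth:
    """Noise-free kinematic quantities implied by a :class:`SimConfig`.

    ``L_gz`` holds the *operational* growth-zone lengths — the position where
    the noise-free profile reaches 95% of its mature size, i.e. the quantity
    the growth-zone estimator actually estimates.  ``L_gz_model`` holds the
    nominal ends of the elemental-growth-rate support, which lie further out
    because the last few percent of size gain accrue asymptotically.  N_el,
    T_el and the zone-averaged RGRs are defined over the operational zone.
    """

    ler: float                       # mm/h
    P: float                         # cells/h
    D: float                         # 1/h
    T_c: float                       # h
    N_mer: float                     # cells
    T_mer: float                     # h
    L_mer: float                     # mm
    L_gz: dict                       # dimension -> mm (operational, 95% rule)
    L_gz_model: dict                 # dimension -> mm (RGR support end)
    mature: dict                     # (dimension, level) -> size (see units)
    N_el: dict                       # dimension -> cells
    T_el: dict                       # dimension -> h
    zone_rgr: dict                   # (zone, dimension) -> 1/h
    rgr_meristem_spatial: float      # dv/dx in the meristem, 1/h
    model: "SteadyStateModel"

    def velocity(self, x):
        return self.model.velocity(x)


class SteadyStateModel:
    """Noise-free profiles l(x), w(x), h(x), v(x), RGR(x) for a config."""

    def __init__(self, config: SimConfig):
        config.validate()
        self.config = c = config
        self.L_gz_len = c.L_gz["length"]
        W = self.L_gz_len - c.L_mer
        self.R_el = 2.0 * c.P * (c.l_mat - c.l_div) / W if W > 0 else 0.0
        x_max = max(max(c.L_gz.values()),
                    max(c.sample_positions_lw), max(c.sample_positions_t))
        # dense cumulative integrals A_dim(x) = int RGR_dim / v from L_mer,
        # so material sizes are size_base * exp(aniso * A)
        xs = np.linspace(c.L_mer, x_max, 8001)
        v = self.velocity(xs)
        self._xs = xs
        self._A = {
            dim: cumulative_trapezoid(self._rgr_shape(xs, c.L_gz[dim]) / v, xs,
                                      initial=0.0)
            for dim in ("width", "thickness")
        }

    # -- longitudinal kinematics (closed forms) --

    def _rgr_shape(self, x, L_gz_dim):
        """Unit-amplitude elongation-zone RGR shape: R_el-scaled linear decline."""
        c = self.config
        x = np.asarray(x, dtype=float)
        frac = np.clip((L_gz_dim - x) / (L_gz_dim - c.L_mer), 0.0, 1.0)
        return np.where(x >= c.L_mer, self.R_el * frac, 0.0)

    def rgr_length(self, x):
        c = self.config
        x = np.asarray(x, dtype=float)
        mer = c.l_div * c.P / c.L_mer
        return np.where(x < c.L_mer, mer, self._rgr_shape(x, self.L_gz_len))

    def velocity(self, x):
        c = self.config
        x = np.asarray(x, dtype=float)
        W = self.L_gz_len - c.L_mer
        u = np.clip(x - c.L_mer, 0.0, W)
        v_mer = c.l_div * c.P * np.clip(x, 0.0, c.L_mer) / c.L_mer
        v_el = self.R_el * (u - u**2 / (2.0 * W)) if W > 0 else 0.0
        return v_mer + v_el

    def cell_length(self, x):
        """Cell length in mm: l_div in the meristem, v/P beyond, l_mat distally."""
        c = self.config
        x = np.asarray(x, dtype=float)
        return np.where(x <= c.L_mer, c.l_div,
                        np.minimum(self.velocity(x) / c.P, c.l_mat))

    # -- lateral / dorsoventral sizes (µm) --

    def _log_growth(self, x, dim):
        x = np.asarray(x, dtype=float)
        return np.interp(x, self._xs, self._A[dim])

    def cell_width(self, x):
        return self.config.w_base * np.exp(
            self.config.aniso_w * self._log_growth(x, "width"))

    def cell_height(self, x):
        return self.config.h_base * np.exp(
            self.config.aniso_h * self._log_growth(x, "thickness"))

    def organ_width(self, x):
        """Blade width in mm: lateral file count times mean cell width."""
        return self.config.n_files * self.cell_width(x) / 1000.0

    def organ_thickness(self, x):
        """Blade thickness in µm: epidermal height plus inner tissue."""
        return self.cell_height(x) * (1.0 + self.config.inner_tissue_factor)

    def size(self, x, dimension, level):
        if dimension == "length":
            if level != "cell":
                raise ValueError("organ length is tracked through LER, not a profile")
            return self.cell_length(x) * 1000.0  # µm
        fn = {
            ("width", "cell"): self.cell_width,
            ("width", "organ"): self.organ_width,
            ("thickness", "cell"): self.cell_height,
            ("thickness", "organ"): self.organ_thickness,
        }[(dimension, level)]
        return fn(x)

    # -- ground truth --

    def operational_growth_zone(self, dimension: str, threshold: float = 0.95) -> float:
        """Position where the noise-free profile reaches threshold x mature size."""
        c = self.config
        end = c.L_gz[dimension]
        level = "cell"
        mature = float(self.size(end, dimension, level))
        target = threshold * mature
        if float(self.size(0.0, dimension, level)) >= target:
            return 0.0
        return float(brentq(
            lambda t: float(self.size(t, dimension, level)) - target, 0.0, end,
            xtol=1e-10,
        ))

    def ground_truth(self) -> GroundTruth:
        c = self.config
        ler = c.P * c.l_mat
        N_mer = c.L_mer / c.l_div
        D = c.P / N_mer
        T_c = math.log(2) / D
        T_mer = math.log2(N_mer) * T_c
        N_el, T_el, zone_rgr, mature, L_gz_op = {}, {}, {}, {}, {}
        mature[("length", "cell")] = c.l_mat * 1000.0  # µm
        for dim in ("length", "width", "thickness"):
            L_gz_op[dim] = self.operational_growth_zone(dim)
            n, _ = quad(lambda t: 1.0 / self.cell_length(t), c.L_mer,
                        max(L_gz_op[dim], c.L_mer),
                        points=[self.L_gz_len], limit=200)
            N_el[dim] = n
            T_el[dim] = n / c.P
        if T_el["length"] > 0:
            zone_rgr[("elongation", "length")] = (
                math.log(self.cell_length(L_gz_op["length"]) / c.l_div)
                / T_el["length"])
        for dim, aniso in (("width", c.aniso_w), ("thickness", c.aniso_h)):
            if T_el[dim] > 0:
                lg = aniso * self._log_growth(L_gz_op[dim], dim)
                zone_rgr[("elongation", dim)] = float(lg / T_el[dim])
            zone_rgr[("meristem", dim)] = 0.0
        zone_rgr[("meristem", "length")] = 0.0  # cell length flat in the meristem
        mature[("width", "cell")] = float(self.cell_width(c.L_gz["width"]))
        mature[("width", "organ")] = float(self.organ_width(c.L_gz["width"]))
        mature[("thickness", "cell")] = float(self.cell_height(c.L_gz["thickness"]))
        mature[("thickness", "organ")] = float(
            self.organ_thickness(c.L_gz["thickness"]))
        return GroundTruth(
            ler=ler, P=c.P, D=D, T_c=T_c, N_mer=N_mer, T_mer=T_mer,
            L_mer=c.L_mer, L_gz=L_gz_op, L_gz_model=dict(c.L_gz),
            mature=mature, N_el=N_el, T_el=T_el, zone_rgr=zone_rgr,
            rgr_meristem_spatial=c.l_div * c.P / c.L_mer, model=self,
        )


@dataclass
class SyntheticDataset:
    """Sampled profiles, leaf-length series and measured meristem lengths."""

    profiles: list
    leaf_lengths: dict          # replicate -> list of (time h, length mm)
    L_mer_measured: dict        # replicate -> mm
    truth: GroundTruth
    config: SimConfig


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=size)


def simulate_growth_zone(config: SimConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset (all replicates) from the model."""
    model = SteadyStateModel(config)
    truth = model.ground_truth()
    c = config
    rng = np.random.default_rng(c.seed)

    combos = [
        ("length", "cell", c.sample_positions_lw),
        ("width", "cell", c.sample_positions_lw),
        ("width", "organ", c.sample_positions_lw),
        ("thickness", "cell", c.sample_positions_t),
        ("thickness", "organ", c.sample_positions_t),
    ]
    profiles = []
    leaf_lengths = {}
    L_mer_measured = {}
    for r in range(1, c.n_reps + 1):
        rep = f"rep{r}"
        for dim, level, positions in combos:
            pos = np.asarray(positions, dtype=float)
            true_vals = np.asarray(model.size(pos, dim, level), dtype=float)
            if dim == "width" and level == "organ" and c.midvein_artifact > 0:
                # width under-read near the base where the blade stays rolled
                L_ref = c.L_gz["width"]
                damp = 1.0 - c.midvein_artifact * np.clip(1.0 - pos / L_ref, 0, 1)
                true_vals = true_vals * damp
            if level == "cell":
                draws = true_vals[:, None] * _lognormal_factors(
                    rng, c.cv_noise, (len(pos), c.cells_per_position))
                sizes = draws.mean(axis=1)
                counts = np.full(len(pos), c.cells_per_position)
            else:
                sizes = true_vals * _lognormal_factors(rng, c.cv_noise, len(pos))
                counts = np.ones(len(pos))
            profiles.append(SizeProfile(
                replicate_id=rep, dimension=dim, level=level,
                positions=pos, sizes=sizes, counts=counts,
            ))
        times = 24.0 * np.arange(c.n_days + 1)
        lengths = (c.leaf_base_length + truth.ler * times
                   + rng.normal(0.0, c.leaf_length_sd, len(times)))
        leaf_lengths[rep] = list(zip(times.tolist(), lengths.tolist()))
        L_mer_measured[rep] = float(
            c.L_mer * _lognormal_factors(rng, c.cv_noise, 1)[0])
    return SyntheticDataset(
        profiles=profiles, leaf_lengths=leaf_lengths,
        L_mer_measured=L_mer_measured, truth=truth, config=config,
    )


def generate_section_image(
    thickness_px: int,
    n_segments: int,
    signal_mean: float,
    noise_mean: float,
    noise_sd: float,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
):
    """Synthetic cross-section phantom: parallel bright bands on noise.

    Returns a 16-bit :class:`LeafImage`-ready array (pixel size left to the
    caller), a truth record with the band rows and levels, and a vertical
    :class:`LineProbe` crossing all bands.
    """
    if thickness_px < 1:
        raise ValueError("band thickness must be >= 1 px")
    if signal_mean <= noise_mean:
        raise ValueError("signal mean must exceed noise mean")
    h, w = image_size
    gap = (h - n_segments * thickness_px) // (n_segments + 1)
    if gap < 1:
        raise ValueError("bands do not fit in the image")
    rng = np.random.default_rng(seed)
    img = np.full((h, w), float(noise_mean))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, (h, w))
    band_rows = []
    row = gap
    for _ in range(n_segments):
        img[row:row + thickness_px, :] += signal_mean - noise_mean
        band_rows.append((row, row + thickness_px))
        row += thickness_px + gap
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    probe = LineProbe(start=(0, w // 2), end=(h - 1, w // 2),
                      n_segments=n_segments)
    truth = {
        "band_rows": band_rows,
        "thickness_px": thickness_px,
        "n_segments": n_segments,
        "signal_mean": float(signal_mean),
        "noise_mean": float(noise_mean),
        "noise_sd": float(noise_sd),
    }
    return img, truth, probe
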
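# Methods

## Kinematic framework

The analysis assumes steady-state growth: the spatial profiles of cell and
organ size along the leaf axis are stationary in time, so a single harvest
characterises the whole developmental trajectory of a cell file. Distance
from the leaf base `x` (mm) then doubles as a developmental axis. The
primary observables are

- the smoothed epidermal cell-length profile `l(x)` (µm, converted to mm
  internally),
- the leaf elongation rate LER (mm h⁻¹), the mean of successive daily
  length increments divided by their time interval,
- the meristem length `L_mer` (mm), measured independently (most distal
  mitotic figures), and
- size profiles for cell width/height and organ width/thickness.

From these the full parameter set follows: production rate `P = LER/l_mat`;
meristem cell number `N_mer = ∫₀^L_mer dx/l(x)`; division rate `D = P/N_mer`;
cycle duration `T_c = ln2/D`; meristem residence `T_mer = log₂(N_mer)·T_c`;
elongation-zone cell number `N_el = ∫_{L_mer}^{L_gz} dx/l(x)` and residence
`T_el = N_el/P`. The flux is modelled as a linear ramp `F(x) = P·x/L_mer`
inside the meristem (flux vanishes at the base, equals `P` at the meristem
exit) and is constant at `P` beyond; velocity is `v(x) = l(x)·F(x)` with
`v(0) = 0` enforced, and the relative elemental growth rate is `RGR = dv/dx`
by central finite differences (one-sided at the grid ends).

Residence times are dimension-specific only through the integration bound:
cells expanding in width or thickness are transported by the same
longitudinal flux, so `T_el,dim = N_el(L_mer, L_gz,dim)/P` with the
dimension's own growth-zone length. Meristem timing is shared across
dimensions.

Zone-averaged relative growth rates use the logarithmic form
`RGR = ln(size₂/size₁)/Δt`, with sizes interpolated from the smoothed
profile at the zone boundaries (leaf base and meristem exit for the
meristem, meristem exit and growth-zone end for the elongation zone) and
`Δt = T_mer` or `T_el,dim`. The logarithmic form is used because a relative
growth rate must carry units of h⁻¹ and reduce to the elemental `dv/dx`
definition in the uniform-growth limit; a literal difference quotient
`(size₂−size₁)/Δt` and a simple-relative form are available as modes.
Anisotropy is reported as the ratio of the longitudinal zone RGR to the
lateral and dorsoventral zone RGRs.

## Profile smoothing

Raw size measurements (~20 cells per fixed position per replicate) are
averaged per position, then each replicate profile is smoothed with a
tricube-weighted local polynomial (default degree 2, bandwidth 0.3 of the
sampled span; 0.5 for the sparsely sectioned thickness profiles) evaluated
on a 1-mm grid clipped to the sampled range — never extrapolated. Windows
with fewer than `degree + 2` points widen to the nearest `degree + 2`
points so the fit stays determined on sparse schemes. Replicates are
smoothed first and aggregated afterwards (pointwise mean and SE = sd/√n),
which keeps the SE interpretable as between-plant variation; the opposite
order is available by smoothing a pooled profile.

A local quadratic reproduces any quadratic exactly, so smoothing is
idempotent on slowly varying profiles. Its known failure mode is the
meristem exit, where the true cell-length profile has a slope
discontinuity: the smoother smears the kink over roughly one half-window,
inflating values just proximal of it by up to tens of percent of the small
meristem cell length. Quantities that integrate `1/l` across the meristem
are only mildly affected (errors partially cancel; the cell cycle duration
is recovered within a few percent in the validation suite), and anisotropy
ratios are almost immune because the longitudinal and lateral boundary
reads share the bias. Zone-averaged RGR magnitudes, however, inherit a
systematic downward bias of order 10–15% under centimetre-scale sampling;
comparisons between genotypes analysed identically are unaffected.

## Growth-zone delimitation

The growth zone ends where the profile reaches a threshold fraction
(default 0.95) of the mature size; the mature size is the mean of the
smoothed profile distal to the growth zone. The two are defined in terms of
each other, so the implementation iterates to a fixed point: the mature
size is initialised from the distal 20% of the grid, the crossing is
located as the first position after which the profile *stays* above
threshold × mature (robust to noise dips, with sub-grid linear
refinement), the mature size is recomputed distal to the crossing, and the
loop stops when the crossing moves by less than one grid step (typically 2
iterations, capped at 50 with a `converged` flag). Profiles whose distal
20% still rises by more than 5% (judged from a fitted line over that
window) are flagged `plateau_detected = False` rather than rejected — some
genotypes genuinely do not plateau in width within the sampled region.

Because realistic profiles approach their plateau asymptotically, the
distal average includes a short stretch still slightly below the plateau;
the mature-size estimate therefore carries a small intrinsic downward bias
(~0.4% on the simulator defaults), well inside the 2% recovery tolerance
used in validation.

## The synthetic-data generator

`simdata` draws datasets from a steady-state model chosen to be the
simplest shape with the correct boundary behaviour and a closed-form
velocity: in the meristem, cell length is constant at the division
equilibrium `l_div` and the flux ramps linearly, so `v = l_div·P·x/L_mer`;
in the elongation zone the elemental growth rate declines linearly from
`R_el = 2P(l_mat−l_div)/(L_gz−L_mer)` at the meristem exit to zero at the
end of the growth zone, which integrates to a quadratic velocity reaching
exactly `v = P·l_mat = LER`, and `l(x) = v(x)/P`. Cell width and height are
carried along material trajectories with elemental growth rates equal to
fixed fractions (`aniso_w`, `aniso_h`) of the longitudinal rate, each
declining to zero at its own growth-zone end; in the meristem they sit at a
division equilibrium like cell length does. Organ width is cell width times
a fixed lateral file count; organ thickness is epidermal cell height times
`1 + inner-tissue factor` (default 4.0, placing a ~18-µm epidermis on a
~90-µm blade).

Defaults describe a wild-type maize fourth leaf: `L_mer = 10` mm,
`L_gz = 60` mm in all dimensions, `l_div = 20` µm, `l_mat = 147` µm,
`P = 16` cells h⁻¹ (LER = 2.35 mm h⁻¹), `w_base = 9` µm and `h_base = 11`
µm with `aniso_w = 0.5` and `aniso_h = 0.25` (mature cell ≈ 24 × 18 µm),
950 lateral files (≈ 23-mm mature blade width), five replicates. Cell
length/width and leaf width are sampled every 10 mm over the basal 100 mm
with 20 cells per position; thickness sections sit at 5–170 mm, matching
the sparse fixed-section protocol. Sizes carry multiplicative lognormal
noise with mean 1 and CV 0.05 (sizes are positive, so lognormal is the
natural choice); leaf-length readings carry additive Gaussian noise of 1 mm
(ruler precision — a multiplicative CV on a 200-mm leaf would imply
implausible ±10-mm reading errors); the measured meristem length carries
the size CV. An optional midvein artifact multiplicatively depresses basal
organ-width samples, emulating the rolled-blade underestimation seen in
very narrow genotypes; no estimator corrects for it.

An important subtlety: the generator's `L_gz` parameter is the end of the
RGR support, but the 95% rule by construction stops earlier, where the
profile crosses 95% of mature — on the defaults at ≈ 48 mm of the nominal
60. `GroundTruth.L_gz` therefore records the *operational* 95% position on
the noise-free profile (the estimand of the growth-zone estimator), with
the nominal support end kept as `L_gz_model`; `N_el`, `T_el` and the
zone-averaged RGRs are defined over the operational zone, so that
`T_el = N_el/P = ∫dx/v` holds exactly along material trajectories.

What the generator does not emulate: non-steady-state drift of the
profiles, cell-to-cell correlation along files, division placement,
stomatal lineages, or 3-D tissue geometry. Passing recovery tests therefore
demonstrate estimator correctness under steady state with independent
multiplicative noise — not robustness to the time-dependence or spatial
correlation structure of real leaves.

Cross-section phantoms for the thickness module are horizontal bright bands
of exact pixel thickness on a Gaussian background, quantised to 16-bit;
with the default 256×256 image, six 3-px bands at 39 µm/px give a true
117-µm thickness per segment.

## Thickness from line probes

The cutoff is `(noise + signal)/2`, with the noise level the mean of a
user-designated background region and the signal level the mean of seed
pixels in the middle of the leaves (means on both sides for symmetry). The
probe is traversed at unit pixel steps (Bresenham); samples at or above the
cutoff count as filled, and the thickness is
`filled × (physical probe length / (samples − 1)) / n_segments`. The
half-sum cutoff is itself the partial-volume correction — edge pixels
containing half tissue sit near the midpoint — so no sub-pixel
interpolation is applied; on noiseless phantoms the result is exact to
within one pixel per segment.

## Numerical choices

- Cell counts integrate `1/l` over the *piecewise-linearly interpolated*
  profile, for which each segment has the exact primitive
  `Δx/Δl · ln(l₂/l₁)` (the limit `Δx/l` for flat segments). This reproduces
  the logarithmic closed form on linear profiles to machine precision,
  where plain trapezoid quadrature of `1/l` at 1-mm spacing errs by ~0.4%
  near 20-µm cells.
- `RGR = dv/dx` uses central differences; their trapezoid integral
  telescopes exactly to `v(end) − v(0) = LER`, so the conservation identity
  holds to machine precision. At the two kink points of the piecewise
  velocity the analytic derivative does not exist and the central
  difference returns the average of the one-sided slopes.
- The width/height material-trajectory integrals use a dense (8001-point)
  cumulative trapezoid of `RGR_dim/v` from the meristem exit; residence
  times use adaptive quadrature with a breakpoint at the zone end.
- Percent differences round to the nearest integer with ties away from
  zero, the convention of the bundled reference table.
- Fixed-point convergence for the growth zone is declared when the crossing
  moves by less than one grid step; non-convergent profiles return the last
  iterate flagged `converged = False`.
- Validation problem sizes: five replicates at 5% CV for recovery tests,
  1,000 parameter draws for the identity chain, 10³-step Euler trajectories
  (dt = 0.001 h) for residence-time oracles — all chosen so the full suite
  runs in well under a minute on one core.

## Known limitations

- Steady state is assumed throughout; genotypes or stages with drifting
  width profiles violate it and bias the width kinematics.
- The 95% rule under-reports the growth zone of any profile with an
  asymptotic plateau approach; this is a property of the operational
  definition, not of the estimator, and is consistent between genotypes.
- Zone-averaged RGR magnitudes are biased downward by the boundary smear of
  local-polynomial smoothing at centimetre-scale sampling (see above);
  ratios and genotype contrasts are robust.
- Organ-level length kinematics are represented only through LER; there is
  no organ length profile.
- The thickness probe assumes approximately perpendicular crossings; oblique
  sections inflate the per-segment thickness geometrically.
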
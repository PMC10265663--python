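# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer should know about.

## Containers and units

All analyses run on four containers: `Trajectory` (frames of positions in
nm with per-frame orthorhombic boxes and strictly increasing times in ps),
`AtomSet` (per-atom element, van der Waals radius, molecule id, optional
donor/acceptor/hydrogen role flags and species tags), `TimeSeries`
(scalar observable vs time), and `ThermoSeries` (specific volume vs
temperature). Boxes are orthorhombic only; triclinic inputs are rejected
with an explicit error rather than silently mishandled, since every
pair-distance routine here uses the per-axis minimum-image convention.
Coordinate I/O (GRO/PDB/XYZ, read and write) goes through MDAnalysis with
Å→nm conversion at the boundary; XYZ frames without time stamps are
assigned 0, 1, 2, … ps. van der Waals radii come from a Bondi-style table
shipped as package data (`core/data/vdw_radii.yaml`, user-overridable);
elements absent from the table fall back to 0.17 nm.

## Glass transition and thermal expansion

The specific volume at each temperature is the mean box volume over the
trailing window of the volume trace (default 500 ps) divided by the system
mass. T_g is located by broken-stick regression: unweighted OLS lines
through the `n_low` coldest and `n_high` hottest points (both default 7),
intersected analytically. Parallel lines raise; an intersection outside
the temperature range is returned but flagged. Unweighted OLS is the
default even when per-point standard deviations exist, because the fit is
meant to reproduce the plain two-line construction used in practice; a
weighted fit is a one-line change if ever needed.

**Estimator geometry worth knowing.** On a 150–575 K grid in 25 K steps,
the seven hottest points span 425–575 K. The estimator is exact (machine
precision) whenever the kink lies strictly between the two fit windows,
i.e. in (300, 425) K on the default grid. When the kink sits *inside* a
fit window the contaminated line biases the intersection: for a kink at
450 K the 425 K point lies on the glassy branch, and the OLS perturbation
moves the noiseless intersection to exactly 440 K — a −10 K bias that is
independent of the two slopes (it is a pure geometry effect of the grid
and window). The unit tests freeze this 440 K value from the analytic
perturbation calculation. Users fitting materials whose T_g falls near
either fit window should shrink `n_low`/`n_high` or re-grid.

CTE = (1/v̄)(dv/dT) with the slope taken by OLS over a temperature range
that defaults to the glassy-side window (the fitted line below T_g);
for exponential v(T) = v₀e^{αT} the estimator returns α up to the
linearization error of the window, which is < 10⁻⁹ K⁻¹ on a 75 K window.

The Archimedes utility implements ρ₂ = A/(A−B)(ρ₀−ρ₁)+ρ₁ with n-heptane
(0.6838 g/cm³) and air (0.0012 g/cm³) defaults, and a replicate helper
returning mean and sample sd.

## Tensile analysis

True stress is σ = −P_z·10⁻⁴ GPa from the pressure-tensor component along
the pull direction; engineering strain is ε = L_t/L₀ − 1. Because P_z
fluctuates strongly in NPT deformation runs, the curve is smoothed by a
rolling average over a strain window of ±2.5 % around each point
(strain-indexed, not time-indexed, so non-uniform strain sampling is
handled by sorting). The part of an early window that would reach below
ε = 0 is filled with virtual zero-stress points: each truncated window is
topped up to the point count a fully interior window holds on the
(near-uniform) strain grid. Consequence: the smoothed curve is pulled
toward zero for ε < 2.5 % — deliberately, since the material genuinely
carried no stress before the deformation started. The modulus therefore
uses the *raw* curve (OLS slope on 0.3–3 % strain, where the padding has
no influence on raw data and start-up transients are excluded), while the
yield strength is the maximum of the *smoothed* curve on 3–97 % strain,
ties resolved to the earliest strain. Uniform per-frame weights are used
inside the window; at constant strain rate frames are uniform in strain,
so this matches uniform-in-strain weighting.

Face-shift averaging (re-analysing the same box with its periodic faces
translated in equidistant steps, e.g. five shifts of 20 % of the box
length) is a pointwise mean of the member curves on the first curve's
strain grid, with linear interpolation for mismatched grids.

## Diffusivity

MSD(τ) is averaged over every time origin and every center of the chosen
grouping (per-molecule by default). Group centers are unweighted means of
member positions — `AtomSet` carries no masses, and for the homogeneous
synthetic particles the center of mass and geometric center coincide;
for real heteroatomic polymers this is an approximation that displaces
each chain's reference point by a fixed intramolecular offset and leaves
the long-time slope unchanged. Frames must be uniformly spaced and
unwrapped; a frame-to-frame displacement exceeding half the smallest box
edge raises with a pointer to `unwrap_trajectory`, which rebuilds
continuous paths from minimum-image step displacements (valid when no
particle moves more than half a box per frame).

D = slope/6 (3-D) of the OLS line through MSD vs τ inside the fit window.
`window="auto"` scans contiguous candidate windows (nominally 30–70 % of
the maximum lag, with neighbouring start/end fractions) and keeps the one
whose log–log slope is closest to 1, i.e. the most random-walk-like
stretch; the log–log slope is also the diagnostic: outside [0.8, 1.2] the
result is flagged non-diffusive (ballistic motion gives 2, caged motion
below 1). No finite-size hydrodynamic correction is applied.

## Hydrogen bonds

Detection is geometric: donor–acceptor distance < 0.35 nm and
hydrogen–donor–acceptor angle (at the donor) < 30°, both minimum-image.
Hydrogens are associated to their covalent donor as the nearest
donor-flagged atom within 0.12 nm in the first frame (covalent O–H/N–H
range); the association is static, which is exact for non-reactive force
fields. Bond identity is the (donor, hydrogen, acceptor) triple; species
pair tags (PP/PW/WW) come from per-atom species labels.

The time autocorrelation is the *intermittent* form

    C_HB(τ) = ⟨Σᵢ hᵢ(t)hᵢ(t+τ)⟩_t / ⟨Σᵢ hᵢ(t)⟩_t ,  C_HB(0) = 1,

so a bond that breaks and re-forms keeps contributing — the only
convention under which the extremely long lifetimes of glassy
hydrogen-bonded polymers are meaningful. It is computed by FFT over the
time axis with per-lag origin normalization. Note a finite-window bias:
with T total frames the τ-lag average divides by T−τ origins, which
inflates C at lags approaching T; in practice fitted time constants on
the synthetic decay fixtures come out ~5 % high at T ≈ 20 τ. Use windows
much longer than the decay of interest, or cap `max_lag_ps`.

C_HB is fitted with Σᵢ Kᵢ e^{−τ/τᵢ} under Kᵢ ≥ 0, ΣKᵢ = 1, τᵢ > 0
(squared-weight normalization and log-τ parameterization inside
`scipy.optimize.least_squares`), with 8 multi-start initializations
log-spaced over the lag range and the residuals evaluated on a log-spaced
subsample of the lag grid so short and long times are balanced. Two terms
are the default for extrapolation. A fitted time constant exceeding 100×
the observed window is capped and flagged as unresolved. The average
lifetime is the trapezoidal integral of the observed C plus the analytic
tail of the fit, Σ Kᵢτᵢ(e^{−t_max/τᵢ} − e^{−horizon/τᵢ}), up to a horizon
(default 100 ns); if C(t_max) > 0.5 the value is flagged as a lower bound
— the population had not half-decayed inside the observation window, as
happens for near-permanent polymer–polymer bonds.

## Fractional free volume

A point is occupied for probe radius p if it lies within r_vdW,i + p of
any atom center (minimum image). FFV(p) is the unoccupied fraction,
evaluated either on a regular grid (default spacing 0.02 nm — ≲1 % error
on a single-sphere analytic test) or by uniform Monte-Carlo insertion.
The same grid or sample points are reused across the probe sweep
(defaults 0.01/0.05/0.1 nm), which makes the profile non-increasing in p
by construction, not just statistically. The profile is cumulative FFV
vs probe radius (not a density in radius).

## Debye-equation XRD

I(q) = Σᵢ fᵢ² + 2Σ_{i<j} fᵢfⱼ sin(qr)/(qr) over minimum-image pair
distances up to a cutoff (default one third of the smallest box edge),
with q = 4π sin θ/λ and λ defaulting to Cu Kα (1.54 Å). Distances are
binned at 0.1 Å by default (the "step size" of the reference workflow is
read as this pair-distance bin); `bin_width=None` switches to exact
distances with identical values merged, which is both exact and fast for
lattices. The 2θ output grid is independent (default 5–60° in 0.05°).
Form factors are unit by default and tabulated 4-Gaussian
parameterizations (H, C, N, O) behind a flag.

Truncating the pair sum in a *dense periodic* system produces a large
forward-scattering tail and termination ripples; by default the
contribution of a uniform medium at the system's average scattering
density inside the cutoff sphere, (Σf)²/V·4π(sin qr_c − qr_c cos qr_c)/q³,
is subtracted (the standard cutoff correction for Debye sums with
periodic data), and residual negative ripple undershoot is clipped at
zero. The correction must be disabled for isolated clusters in vacuum,
where the plain Debye sum is already exact — the two-atom closed form
I = 2(1 + sinc qd) is reproduced to 10⁻¹⁰ that way.

`peak_two_theta` reports the most prominent local maximum
(`scipy.signal.find_peaks`), which is insensitive to the forward tail and
ripples. Two finite-size facts show up in the simple-cubic validation
fixture: (i) with *unit* form factors the (100) and (110) powder peaks are
asymptotically equally intense — multiplicity 6 vs 12 cancels exactly
against the 1/q² Lorentz factor that the Debye orientation average
produces — so which one "dominates" is decided by truncation noise;
tabulated form factors restore the physical dominance of the first peak.
(ii) The apex of a finite-crystallite peak (Scherrer width ≈ 0.9λ/L cos θ,
several degrees at desk scale) sits on a sloped envelope and is displaced
from the ideal Bragg angle by a few tenths of a degree; agreement with
2 arcsin(λ/2a) is therefore asserted at the 2θ-equivalent of one 0.1 Å
distance bin (≈0.56° at d = 4 Å), not at the 0.05° output-grid step.

## RDF

Standard g(r): minimum-image pair-distance histogram between two
selections, frame-averaged, normalized by n_ref · (n_pairs/V) · shell
volume; identical atoms in overlapping selections are excluded. r_max
must stay below half the smallest box edge. Grids are in Å to match
diffraction conventions.

## Synthetic generators

Every generator is a pure function of its arguments including the integer
seed (numpy `default_rng`; no global state). They emulate the *shape and
statistics* of MD observables, not their physics:

- **Brownian trajectories** — Gaussian steps of variance 2D·dt per axis,
  unwrapped (MSD must not see wrapping). No inertia, no caging: the MSD is
  linear at all lags, unlike a real polymer melt whose short-time regime
  is ballistic/caged. Default study condition: 500 particles × 1000 frames
  at 1 ps for the recovery checks.
- **PVT series** — bilinear v(T), continuous at the kink, multiplicative
  Gaussian noise (`noise_sd` is relative; 0.001 = 0.1 %, the scale of the
  triplicate scatter seen in NPT cooling runs). Default grid 150–575 K in
  25 K steps (18 points). Real PVT data curves smoothly through the
  transition; the sharp kink is the idealization the broken-stick
  estimator targets.
- **Bond telegraph** — all bonds start present; on-states survive
  exponentially with mean τ_true; a reformation rate is available but
  defaults to 0, because with reformation the intermittent C(τ) plateaus
  at the equilibrium on-probability and any finite-horizon lifetime
  integral is dominated by the plateau rather than τ_true. A
  `frac_permanent` sub-population models the never-breaking bonds of
  glassy systems.
- **Sphere packings / lattices** — uniform placements (optionally
  non-overlapping by rejection, packing fraction < 0.3) and simple-cubic
  lattices with analytic free volume and diffraction oracles.
- **Elastic traces** — elastic–perfectly-plastic σ(ε) = min(Eε, σ_y) plus
  Gaussian noise in absolute GPa (0.003 GPa ≈ 1 % of the default yield
  plateau), with the box length growing linearly. Real curves strain-
  soften after yield and show rate effects; none of that is emulated.
- **Chain composition** — exactly round(f·N) ring-opened units placed
  uniformly at random without replacement (exact count rather than
  binomial, for deterministic tests; placement is global, not stratified
  per chain).

Passing the recovery tests therefore demonstrates that the estimators are
correct and well-calibrated on data matching their model assumptions; it
does not validate force fields, equilibration, or any other MD-side
concern.

## Study orchestration

`run_study` executes the configured stages for each system on synthetic
inputs whose ground truths vary smoothly with composition (T_g, modulus,
yield and H-bond lifetime fall with ring opening and water content;
diffusivity and FFV probe radius rise). Per-system, per-stage seeds derive
deterministically from the study seed via `SeedSequence` spawn keys, so
stages are isolated (disabling one never changes another) and reruns are
byte-identical; wall-clock timings go only to `run.log`, never into
summaries. T_g ground truths are kept in the 300–425 K band where the
7+7 broken-stick windows are both clean (see above). Stage failures are
recorded in the report and do not abort the sweep; the CLI exits non-zero
if any occurred. Every tunable default lives in one `STAGE_DEFAULTS`
block (7-point fits, ±2.5 % stress window, 0.3–3 % modulus window,
3–97 % yield window, 0.35 nm/30° H-bond criteria, 1.54 Å wavelength,
box/3 cutoff) so deviations are visible in one place.

Problem sizes in the default test and acceptance runs (hundreds of bonds
or particles, hundreds to a couple of thousand frames, ≤14³-site
lattices) are the package's chosen desk-scale study conditions; they keep
every statistical recovery inside its documented tolerance while the full
suite runs in about a minute.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- No binary trajectory formats (XTC/TRR/DCD); text formats only.
- MSD grouping ignores masses (geometric centers).
- The intermittent C_HB carries the finite-window origin bias described
  above; lifetimes from windows shorter than ~20× the decay constant are
  a few percent high.
- Debye peak apexes carry the finite-crystallite displacement described
  above; desk-scale patterns locate peaks to tenths of a degree, not to
  the output-grid step.
- The broken-stick T_g estimator is biased when the true kink lies inside
  either fit window (exact geometry given above); this is a property of
  the two-line construction itself, not of the implementation.
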
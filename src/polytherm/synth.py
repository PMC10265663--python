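"""Synthetic inputs with known ground truth for every analysis stage.

Each generator is a pure function of its arguments including the integer
seed, and emits the same containers the readers produce, so the whole
pipeline can be exercised and validated without an MD engine:

* Brownian particle trajectories with a prescribed diffusivity,
* bilinear specific-volume-vs-temperature series with a known kink,
* binary bond-occupancy (telegraph) processes with known on-state
  kinetics,
* random sphere packings and simple-cubic lattices with analytic free
  volume and diffraction,
* elastic-plastic stress traces with known modulus and yield,
* chain composition tables with an exact ring-opened unit count.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from polytherm.core.radii import vdw_radius
from polytherm.core.types import AtomSet, Box, TimeSeries, Trajectory
from polytherm.hbonds import BondOccupancy
from polytherm.thermo import ThermoSeries
from polytherm.units import ANGSTROM_TO_NM, CM2_PER_S_TO_NM2_PER_PS, GPA_TO_BAR

DEFAULT_PVT_GRID = np.arange(150.0, 575.0 + 1e-9, 25.0)  # K, 18 points


def _atoms_for(positions: np.ndarray, element: str = "C", radius: Optional[float] = None,
               molecule_ids: Optional[np.ndarray] = None) -> AtomSet:
    n = len(positions)
    r = radius if radius is not None else vdw_radius(element)
    return AtomSet(
        positions=positions,
        elements=np.array([element] * n, dtype=object),
        vdw_radii=np.full(n, r),
        molecule_ids=molecule_ids if molecule_ids is not None else np.arange(n),
    )


def gen_brownian_trajectory(
    n_particles: int,
    d_true_cm2_s: float,
    dt_ps: float,
    n_frames: int,
    box: Box,
    seed: int = 0,
) -> Trajectory:
    """Ideal Brownian particles with diffusivity ``d_true_cm2_s``.

    Per-step displacements are Gaussian with variance 2 D dt per axis.
    Coordinates are left unwrapped (they may leave the box) because the
    MSD must not see periodic wrapping; the box is carried for geometry.
    """
    if d_true_cm2_s < 0:
        raise ValueError("diffusivity must be non-negative")
    if dt_ps <= 0:
        raise ValueError("time step must be positive")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    d_nm2_ps = d_true_cm2_s * CM2_PER_S_TO_NM2_PER_PS
    sigma = np.sqrt(2.0 * d_nm2_ps * dt_ps)
    start = rng.uniform(0.0, 1.0, size=(n_particles, 3)) * box.lengths
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_particles, 3)) if sigma > 0 else np.zeros((n_frames - 1, n_particles, 3))
    coords = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    times = np.arange(n_frames) * dt_ps
    return Trajectory(times=times, coordinates=coords, boxes=[box] * n_frames, atoms=_atoms_for(start))


def gen_pvt_series(
    tg_true: float,
    slope_glass: float,
    slope_rubber: float,
    v_at_tg: float,
    t_grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ThermoSeries:
    """Bilinear specific-volume series, continuous at the kink ``tg_true``.

    Slopes are cm^3/(g K); ``noise_sd`` is the *relative* sd of
    multiplicative Gaussian noise (0.001 means 0.1% noise). The default
    grid is 150-575 K in 25 K steps (18 points).
    """
    t = np.asarray(DEFAULT_PVT_GRID if t_grid is None else t_grid, dtype=float)
    if not (slope_rubber > slope_glass > 0):
        raise ValueError("require slope_rubber > slope_glass > 0")
    if not (t.min() <= tg_true <= t.max()):
        raise ValueError(f"tg_true={tg_true} K lies outside the grid [{t.min()}, {t.max()}] K")
    v = np.where(t < tg_true, v_at_tg + slope_glass * (t - tg_true), v_at_tg + slope_rubber * (t - tg_true))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + noise_sd * rng.standard_normal(len(t)))
    return ThermoSeries(temperatures=t, specific_volumes=v)


def gen_bond_telegraph(
    n_bonds: int,
    tau_true_ps: float,
    frac_permanent: float,
    dt_ps: float,
    n_frames: int,
    seed: int = 0,
    reform_rate_per_ps: float = 0.0,
) -> BondOccupancy:
    """Binary bond-existence traces with exponential on-state survival.

    All bonds start present; a non-permanent bond's on-state survives
    with mean ``tau_true_ps``. With the default ``reform_rate_per_ps=0``
    broken bonds stay broken, so the intermittent autocorrelation of the
    population decays as exp(-tau/tau_true); a positive reformation rate
    turns each trace into a genuine telegraph process. A fraction
    ``frac_permanent`` of bonds is always on. Triples are synthetic
    (bond i -> atoms (3i, 3i+1, 3i+2)).
    """
    if tau_true_ps <= 0:
        raise ValueError("tau_true must be positive")
    if not 0.0 <= frac_permanent <= 1.0:
        raise ValueError("frac_permanent must lie in [0, 1]")
    if dt_ps >= tau_true_ps / 2.0:
        warnings.warn("frame spacing is coarse relative to the bond lifetime", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_perm = int(round(frac_permanent * n_bonds))
    matrix = np.ones((n_bonds, n_frames), dtype=np.uint8)
    p_break = 1.0 - np.exp(-dt_ps / tau_true_ps)
    p_reform = 1.0 - np.exp(-reform_rate_per_ps * dt_ps) if reform_rate_per_ps > 0 else 0.0
    n_free = n_bonds - n_perm
    if n_free > 0 and n_frames > 1:
        state = np.ones(n_free, dtype=bool)
        for f in range(1, n_frames):
            u = rng.random(n_free)
            state = np.where(state, u >= p_break, u < p_reform)
            matrix[n_perm:, f] = state
    times = np.arange(n_frames) * dt_ps
    triples = [(3 * i, 3 * i + 1, 3 * i + 2) for i in range(n_bonds)]
    return BondOccupancy(matrix=matrix, triples=triples, times=times)


def gen_sphere_config(
    n_atoms: int,
    radius_nm: float,
    box: Box,
    allow_overlap: bool = True,
    seed: int = 0,
    element: str = "C",
) -> Trajectory:
    """Single frame of equal-radius spheres, random-uniform in the box.

    With ``allow_overlap=False`` spheres are placed by rejection so no
    two centers come within 2 r (minimum image); the packing fraction
    n (4 pi/3) r^3 / V must then stay below 0.3.
    """
    rng = np.random.default_rng(seed)
    if n_atoms == 0:
        atoms = AtomSet(
            positions=np.empty((0, 3)),
            elements=np.empty(0, dtype=object),
            vdw_radii=np.empty(0),
            molecule_ids=np.empty(0, dtype=int),
        )
        return Trajectory(times=[0.0], coordinates=np.empty((1, 0, 3)), boxes=[box], atoms=atoms)
    if not allow_overlap:
        packing = n_atoms * (4.0 / 3.0) * np.pi * radius_nm**3 / box.volume
        if packing >= 0.3:
            raise ValueError(f"packing fraction {packing:.3f} too high for non-overlapping placement")
        placed = np.empty((0, 3))
        attempts = 0
        while len(placed) < n_atoms:
            cand = rng.uniform(0.0, 1.0, size=3) * box.lengths
            attempts += 1
            if attempts > 10000 * n_atoms:
                raise RuntimeError("rejection sampling failed; lower the packing fraction")
            if len(placed):
                d = placed - cand
                d -= box.lengths * np.round(d / box.lengths)
                if np.min(np.sum(d * d, axis=1)) < (2 * radius_nm) ** 2:
                    continue
            placed = np.vstack([placed, cand])
        positions = placed
    else:
        positions = rng.uniform(0.0, 1.0, size=(n_atoms, 3)) * box.lengths
    atoms = _atoms_for(positions, element=element, radius=radius_nm)
    return Trajectory(times=[0.0], coordinates=positions[None], boxes=[box], atoms=atoms)


def gen_lattice_config(
    lattice: str = "simple_cubic",
    a_angstrom: float = 4.0,
    n_cells_per_axis: int = 4,
    element: str = "C",
) -> Trajectory:
    """Atoms on a simple-cubic lattice; box edge = n_cells * a per axis."""
    if lattice != "simple_cubic":
        raise ValueError(f"unsupported lattice {lattice!r}")
    if n_cells_per_axis < 2:
        raise ValueError("need at least 2 cells per axis")
    a_nm = a_angstrom * ANGSTROM_TO_NM
    grid = np.arange(n_cells_per_axis) * a_nm
    xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
    positions = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    edge = n_cells_per_axis * a_nm
    box = Box(edge, edge, edge)
    atoms = _atoms_for(positions, element=element)
    return Trajectory(times=[0.0], coordinates=positions[None], boxes=[box], atoms=atoms)


def gen_elastic_trace(
    e_true_gpa: float,
    yield_true_gpa: float,
    strain_rate_per_ps: float,
    dt_ps: float,
    n_frames: int,
    noise_sd_gpa: float = 0.0,
    l0_nm: float = 10.0,
    seed: int = 0,
) -> Tuple[TimeSeries, TimeSeries]:
    """Elastic-perfectly-plastic deformation trace.

    Returns the pressure-tensor component along the pull direction
    (bar; -P_z = min(E eps, yield) + noise) and the box length (nm,
    growing linearly at ``strain_rate_per_ps``).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    times = np.arange(n_frames) * dt_ps
    strain = strain_rate_per_ps * times
    if strain_rate_per_ps > 0:
        max_strain = strain[-1]
        if yield_true_gpa > e_true_gpa * max_strain:
            raise ValueError("yield stress is never reached: yield_true > E_true * max strain")
    stress = np.minimum(e_true_gpa * strain, yield_true_gpa)
    if noise_sd_gpa > 0:
        rng = np.random.default_rng(seed)
        stress = stress + noise_sd_gpa * rng.standard_normal(n_frames)
    pressure = TimeSeries(name="Pres-ZZ", times=times, values=-stress * GPA_TO_BAR, unit="bar")
    length = TimeSeries(name="Box-Z", times=times, values=l0_nm * (1.0 + strain), unit="nm")
    return pressure, length


def gen_chain_composition(
    n_chains: int,
    units_per_chain: int,
    ro_fraction: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-unit labels for chains with a given degree of ring opening.

    The global number of ring-opened (dialcohol) units is exactly
    round(ro_fraction * n_chains * units_per_chain); their placement is
    uniform over all units, without replacement.
    """
    if not 0.0 <= ro_fraction <= 1.0:
        raise ValueError("ro_fraction must lie in [0, 1]")
    total = n_chains * units_per_chain
    n_ro = int(round(ro_fraction * total))
    rng = np.random.default_rng(seed)
    ro_sites = rng.choice(total, size=n_ro, replace=False)
    labels = np.full(total, "cellulose", dtype=object)
    labels[ro_sites] = "dialcohol"
    return pd.DataFrame(
        {
            "chain": np.repeat(np.arange(n_chains), units_per_chain),
            "unit": np.tile(np.arange(units_per_chain), n_chains),
            "label": labels,
        }
    )
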
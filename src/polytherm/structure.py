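"""Structural analyses: fractional free volume, Debye-equation XRD, RDF.

Fractional free volume (FFV) is the fraction of the box not covered by
the atoms' van der Waals spheres inflated by a spherical probe radius:
FFV(p) = 1 - V_occupied(p) / V_total, evaluated either on a regular
grid or by Monte-Carlo insertion. Powder diffraction patterns come from
the Debye scattering equation, the orientation average over pairwise
interatomic distances I(q) = sum_ij f_i f_j sin(q r_ij)/(q r_ij), with
q = 4 pi sin(theta) / lambda. The radial distribution function g(r) is
the standard pair-distance histogram normalized by the ideal-gas shell
expectation. All pair distances use the minimum-image convention in an
orthorhombic box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from polytherm.core.geometry import min_image_displacement
from polytherm.core.types import AtomSet, Box, PolythermError, Trajectory
from polytherm.units import NM_TO_ANGSTROM

DEFAULT_GRID_RESOLUTION = 0.02  # nm
DEFAULT_PROBE_RADII = (0.01, 0.05, 0.1)  # nm
DEFAULT_WAVELENGTH = 1.54  # Angstrom (Cu K-alpha)
DEFAULT_XRD_BIN_WIDTH = 0.1  # Angstrom, pair-distance histogram bin

# 4-Gaussian X-ray form-factor parameterizations, f(s) = sum a_k exp(-b_k s^2) + c
# with s = sin(theta)/lambda = q/(4 pi) in 1/Angstrom.
FORM_FACTOR_COEFFS = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879], [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000], [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630], [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000], [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
}


@dataclass
class FFVProfile:
    """FFV vs probe radius (cumulative unoccupied fraction)."""

    probe_radii: np.ndarray  # nm
    ffv: np.ndarray  # in [0, 1], non-increasing with radius
    method: str
    resolution: float  # grid spacing (nm) or MC sample count

    def __post_init__(self) -> None:
        self.probe_radii = np.asarray(self.probe_radii, dtype=float)
        self.ffv = np.asarray(self.ffv, dtype=float)
        if self.probe_radii.shape != self.ffv.shape:
            raise ValueError("probe radii and FFV values must match")
        if np.any((self.ffv < 0) | (self.ffv > 1)):
            raise ValueError("FFV values must lie in [0, 1]")
        order = np.argsort(self.probe_radii)
        if np.any(np.diff(self.ffv[order]) > 1e-12):
            raise ValueError("FFV must be non-increasing with probe radius")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"probe radius (nm)": self.probe_radii, "FFV": self.ffv})


@dataclass
class DiffractionPattern:
    """Simulated powder pattern: intensity vs scattering angle 2-theta."""

    two_theta: np.ndarray  # degrees, uniform grid
    intensity: np.ndarray  # arbitrary units, >= 0
    wavelength: float  # Angstrom
    cutoff: float  # Angstrom, pair-distance cutoff

    def __post_init__(self) -> None:
        self.two_theta = np.asarray(self.two_theta, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.two_theta.shape != self.intensity.shape:
            raise ValueError("grid and intensity must match")
        steps = np.diff(self.two_theta)
        if len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError("2-theta grid must be uniform")

    @property
    def peak_two_theta(self) -> float:
        """Position (degrees) of the dominant diffraction peak.

        The most prominent local maximum, which ignores both the
        low-angle forward-scattering tail (monotone, no local maximum)
        and truncation ripples (low prominence). Falls back to the
        global maximum when no local peak exists.
        """
        from scipy.signal import find_peaks

        idx, props = find_peaks(self.intensity, prominence=0.0)
        if len(idx) == 0:
            return float(self.two_theta[int(np.argmax(self.intensity))])
        return float(self.two_theta[idx[int(np.argmax(props["prominences"]))]])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"two_theta (deg)": self.two_theta, "intensity (a.u.)": self.intensity})


@dataclass
class RDFCurve:
    """g(r) on a radial grid in Angstrom."""

    r: np.ndarray  # bin centers, Angstrom
    g: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.r.shape != self.g.shape:
            raise ValueError("r grid and g(r) must match")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r (Angstrom)": self.r, "g(r)": self.g})


def _occupied_mask_grid(atoms: AtomSet, box: Box, radii: np.ndarray, resolution: float) -> np.ndarray:
    """Boolean occupancy on a regular grid; a cell is occupied iff its
    center lies within radii[i] of atom i under minimum image."""
    lengths = box.lengths
    n_cells = np.maximum(1, np.round(lengths / resolution).astype(int))
    spacing = lengths / n_cells
    occupied = np.zeros(tuple(n_cells), dtype=bool)
    axes = [(np.arange(n_cells[k]) + 0.5) * spacing[k] for k in range(3)]
    for pos, radius in zip(atoms.positions, radii):
        # sub-box of cells that can possibly be inside the sphere, with wrap
        idx = []
        for k in range(3):
            lo = int(np.floor((pos[k] - radius) / spacing[k])) - 1
            hi = int(np.ceil((pos[k] + radius) / spacing[k])) + 1
            idx.append(np.arange(lo, hi + 1) % n_cells[k])
        dx = [axes[k][idx[k]] - pos[k] for k in range(3)]
        dx = [d - lengths[k] * np.round(d / lengths[k]) for k, d in enumerate(dx)]
        d2 = dx[0][:, None, None] ** 2 + dx[1][None, :, None] ** 2 + dx[2][None, None, :] ** 2
        sub = d2 <= radius * radius
        occupied[np.ix_(idx[0], idx[1], idx[2])] |= sub
    return occupied


def fractional_free_volume(
    atoms: AtomSet,
    box: Box,
    probe_radii: Sequence[float] = DEFAULT_PROBE_RADII,
    method: str = "grid",
    resolution: float = DEFAULT_GRID_RESOLUTION,
    n_samples: int = 100_000,
    seed: int = 0,
) -> FFVProfile:
    """FFV vs probe radius by grid or Monte-Carlo probe insertion.

    A point is occupied for probe radius p iff it lies within
    (r_vdw,i + p) of any atom center under minimum image. The same grid
    (or the same random sample points) is reused across probe radii, so
    the profile is exactly non-increasing. ``resolution`` is the grid
    spacing in nm; Monte-Carlo uses ``n_samples`` uniform points.
    """
    probe_radii = np.asarray(sorted(probe_radii), dtype=float)
    if np.any(probe_radii < 0):
        raise ValueError("probe radii must be non-negative")
    if atoms.n_atoms and np.min(atoms.vdw_radii) < resolution and method == "grid":
        import warnings

        warnings.warn("grid resolution is coarser than the smallest vdW radius", stacklevel=2)
    ffv = np.empty(len(probe_radii))
    if atoms.n_atoms == 0:
        ffv[:] = 1.0
        return FFVProfile(probe_radii, ffv, method, resolution)
    if method == "grid":
        for i, p in enumerate(probe_radii):
            occ = _occupied_mask_grid(atoms, box, atoms.vdw_radii + p, resolution)
            ffv[i] = 1.0 - occ.mean()
        return FFVProfile(probe_radii, ffv, method, resolution)
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        points = rng.uniform(0.0, 1.0, size=(n_samples, 3)) * box.lengths
        # distance from each sample to the nearest atom surface, chunked
        min_gap = np.full(n_samples, np.inf)
        chunk = max(1, int(5e6 // max(atoms.n_atoms, 1)))
        for s in range(0, n_samples, chunk):
            pts = points[s : s + chunk]
            d = pts[:, None, :] - atoms.positions[None, :, :]
            d = min_image_displacement(d, box)
            r = np.sqrt(np.sum(d * d, axis=-1)) - atoms.vdw_radii[None, :]
            min_gap[s : s + chunk] = r.min(axis=1)
        for i, p in enumerate(probe_radii):
            ffv[i] = float(np.mean(min_gap > p))
        return FFVProfile(probe_radii, ffv, method, float(n_samples))
    raise ValueError(f"method must be 'grid' or 'montecarlo', got {method!r}")


def _form_factors(elements: np.ndarray, q: np.ndarray, kind: str) -> np.ndarray:
    """(n_elements_unique,) -> (n_atoms? ) per-atom f(q): returns (n_atoms, n_q)."""
    if kind == "unit":
        return np.ones((len(elements), len(q)))
    if kind != "tabulated":
        raise ValueError("form_factors must be 'unit' or 'tabulated'")
    s2 = (q / (4.0 * np.pi)) ** 2
    cache: dict[str, np.ndarray] = {}
    out = np.empty((len(elements), len(q)))
    for i, e in enumerate(elements):
        sym = str(e).capitalize()
        if sym not in cache:
            if sym not in FORM_FACTOR_COEFFS:
                raise PolythermError(f"no tabulated form factor for element {sym!r}")
            a, b, c = FORM_FACTOR_COEFFS[sym]
            cache[sym] = np.sum([ak * np.exp(-bk * s2) for ak, bk in zip(a, b)], axis=0) + c
        out[i] = cache[sym]
    return out


def _aggregate_distances(
    r: np.ndarray, cutoff: float, bin_width: Optional[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse pair distances to (values, multiplicities).

    ``bin_width`` set: histogram at that width, values = bin centers.
    ``bin_width=None``: exact distances, identical ones merged.
    """
    if bin_width is not None:
        n_bins = int(np.ceil(cutoff / bin_width))
        counts, edges = np.histogram(r, bins=n_bins, range=(0.0, n_bins * bin_width))
        centers = 0.5 * (edges[:-1] + edges[1:])
        nz = counts > 0
        return centers[nz], counts[nz].astype(float)
    values, counts = np.unique(np.round(r, 9), return_counts=True)
    return values, counts.astype(float)


def _sinc_sum(r_values: np.ndarray, weights: np.ndarray, q: np.ndarray, chunk: int = 20000) -> np.ndarray:
    """sum_k w_k sinc(q r_k), chunked to bound the (r, q) matrix size."""
    out = np.zeros(len(q))
    for s in range(0, len(r_values), chunk):
        out += weights[s : s + chunk] @ np.sinc(np.outer(r_values[s : s + chunk], q) / np.pi)
    return out


def debye_xrd(
    atoms: AtomSet,
    box: Box,
    wavelength: float = DEFAULT_WAVELENGTH,
    cutoff: Optional[float] = None,
    two_theta_grid: Optional[np.ndarray] = None,
    bin_width: Optional[float] = DEFAULT_XRD_BIN_WIDTH,
    form_factors: str = "unit",
    continuum_correction: bool = True,
) -> DiffractionPattern:
    """Debye-equation powder pattern from one frame.

    Pair distances (minimum image, in Angstrom) up to ``cutoff``
    (default: one third of the smallest box edge) enter
    I(q) = sum_i f_i^2 + 2 sum_{i<j} f_i f_j sin(q r_ij)/(q r_ij),
    mapped to 2-theta through q = 4 pi sin(theta)/lambda. Distances are
    binned at ``bin_width`` (Angstrom); ``bin_width=None`` uses exact
    distances (small systems). ``form_factors``: 'unit' or 'tabulated'
    (4-Gaussian parameterizations for H, C, N, O).

    ``continuum_correction`` subtracts the scattering a uniform medium
    of the same average density would contribute inside the cutoff
    sphere, (sum_i f_i)^2/V * 4 pi (sin(q r_c) - q r_c cos(q r_c))/q^3.
    Truncating the pair sum at r_c in a dense periodic system otherwise
    floods the pattern with termination ripples and a huge forward-
    scattering tail; disable it for isolated clusters in vacuum, where
    the plain Debye sum is exact.
    """
    if atoms.n_atoms < 1:
        raise ValueError("need at least one atom")
    if two_theta_grid is None:
        two_theta_grid = np.arange(5.0, 60.0 + 1e-9, 0.05)
    two_theta_grid = np.asarray(two_theta_grid, dtype=float)
    pos = atoms.positions * NM_TO_ANGSTROM
    box_a = box.lengths * NM_TO_ANGSTROM
    if cutoff is None:
        cutoff = float(min(box_a)) / 3.0
    theta = np.deg2rad(two_theta_grid) / 2.0
    q = 4.0 * np.pi * np.sin(theta) / wavelength
    elements = atoms.elements
    f = _form_factors(elements, q, form_factors)  # (n_atoms, n_q)
    intensity = np.sum(f * f, axis=0)  # self terms
    n = atoms.n_atoms
    if n > 1:
        iu, ju = np.triu_indices(n, k=1)
        d = pos[iu] - pos[ju]
        d -= box_a * np.round(d / box_a)
        r = np.sqrt(np.sum(d * d, axis=1))
        keep = r <= cutoff
        r, iu, ju = r[keep], iu[keep], ju[keep]
        if len(r):
            if form_factors == "unit":
                centers, counts = _aggregate_distances(r, cutoff, bin_width)
                intensity = intensity + 2.0 * _sinc_sum(centers, counts, q)
            else:
                # element-resolved aggregation so f_i f_j can depend on q
                groups: dict[tuple[str, str], list] = {}
                for a_i, a_j, rr in zip(elements[iu], elements[ju], r):
                    key = tuple(sorted((str(a_i), str(a_j))))
                    groups.setdefault(key, []).append(rr)
                fq = {
                    str(e): _form_factors(np.array([e], dtype=object), q, form_factors)[0]
                    for e in set(map(str, elements))
                }
                for (e1, e2), rr in groups.items():
                    centers, counts = _aggregate_distances(np.asarray(rr), cutoff, bin_width)
                    intensity = intensity + 2.0 * fq[e1] * fq[e2] * _sinc_sum(centers, counts, q)
    if continuum_correction:
        total_f = np.sum(f, axis=0)  # sum_i f_i(q)
        volume = float(np.prod(box_a))
        with np.errstate(divide="ignore", invalid="ignore"):
            shape = (np.sin(q * cutoff) - q * cutoff * np.cos(q * cutoff)) / q**3
        shape = np.where(q > 0, shape, cutoff**3 / 3.0)  # q -> 0 limit
        intensity = intensity - total_f**2 / volume * 4.0 * np.pi * shape
        intensity = np.maximum(intensity, 0.0)  # ripple undershoot is unphysical
    return DiffractionPattern(
        two_theta=two_theta_grid,
        intensity=intensity,
        wavelength=float(wavelength),
        cutoff=float(cutoff),
    )


def rdf(
    traj: Trajectory,
    ref_indices: Sequence[int],
    target_indices: Sequence[int],
    r_max: float = 10.0,
    bin_width: float = 0.1,
) -> RDFCurve:
    """Radial distribution function between two atom selections.

    ``r_max`` and ``bin_width`` are in Angstrom; ``r_max`` must not
    exceed half the smallest box edge. Frames are averaged; identical
    ref/target atoms are excluded from the pair count.
    """
    ref = np.asarray(ref_indices, dtype=int)
    tgt = np.asarray(target_indices, dtype=int)
    if len(ref) == 0 or len(tgt) == 0:
        raise ValueError("selections must be non-empty")
    n_bins = int(np.round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    hist = np.zeros(n_bins)
    ideal_factor = 0.0
    for fidx in range(traj.n_frames):
        pos = traj.coordinates[fidx] * NM_TO_ANGSTROM
        box_a = traj.boxes[fidx].lengths * NM_TO_ANGSTROM
        if r_max > min(box_a) / 2.0 + 1e-9:
            raise ValueError(
                f"r_max {r_max} A exceeds half the smallest box edge ({min(box_a) / 2:.2f} A)"
            )
        d = pos[ref][:, None, :] - pos[tgt][None, :, :]
        d -= box_a * np.round(d / box_a)
        r = np.sqrt(np.sum(d * d, axis=-1))
        same = ref[:, None] == tgt[None, :]
        r = r[~same]
        hist += np.histogram(r, bins=edges)[0]
        volume = float(np.prod(box_a))
        n_pairs = len(ref) * len(tgt) - int(same.sum())
        ideal_factor += n_pairs / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (shell * ideal_factor)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFCurve(r=centers, g=g)
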
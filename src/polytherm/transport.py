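"""Mean-square displacement and Einstein-relation diffusivity.

MSD(tau) is averaged over all time origins and over all centers of the
chosen grouping (per-molecule centers by default). In three dimensions
the long-time slope of MSD vs lag equals 6 D; only the linear (random
walk) part of the curve should be fitted, so the fit window is explicit
and an automatic selector picks the most linear contiguous window. The
fit is flagged non-diffusive when the log-log slope of MSD vs lag falls
outside [0.8, 1.2] (ballistic motion gives 2, caged motion < 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy import stats

from polytherm.core.types import PolythermError, Trajectory
from polytherm.units import NM2_PER_PS_TO_CM2_PER_S

LOGLOG_DIFFUSIVE_BAND = (0.8, 1.2)


@dataclass
class MSDCurve:
    """MSD (nm^2) vs lag time (ps) with the number of origin pairs per lag."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(self.lags) == len(self.msd) == len(self.n_pairs)):
            raise ValueError("lags, msd and pair counts must be equally long")
        if len(self.msd) and (self.msd[0] != 0.0 or np.any(self.msd < 0)):
            raise ValueError("MSD must start at 0 and be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"lag (ps)": self.lags, "MSD (nm^2)": self.msd, "n_pairs": self.n_pairs}
        )


@dataclass
class DiffusivityResult:
    diffusivity_cm2_s: float
    window_ps: Tuple[float, float]
    slope_sd: float  # sd of the fitted slope, in cm^2/s after the /6 conversion
    loglog_slope: float
    diffusive: bool


def unwrap_trajectory(traj: Trajectory) -> Trajectory:
    """Reconstruct continuous paths from wrapped coordinates.

    Applies the minimum-image convention to successive frame-to-frame
    displacements, assuming no particle moves more than half a box edge
    per frame, and accumulates them from the first frame.
    """
    coords = traj.coordinates
    out = np.empty_like(coords)
    out[0] = coords[0]
    for i in range(1, len(coords)):
        lengths = traj.boxes[i].lengths
        delta = coords[i] - coords[i - 1]
        delta -= lengths * np.round(delta / lengths)
        out[i] = out[i - 1] + delta
    return Trajectory(times=traj.times.copy(), coordinates=out, boxes=list(traj.boxes), atoms=traj.atoms)


def _group_centers(traj: Trajectory, grouping: str) -> np.ndarray:
    """(n_frames, n_groups, 3) array of unweighted group centers."""
    if grouping == "atom":
        return traj.coordinates
    if grouping != "molecule":
        raise ValueError(f"grouping must be 'molecule' or 'atom', got {grouping!r}")
    mol_ids = traj.atoms.molecule_ids
    unique, inverse = np.unique(mol_ids, return_inverse=True)
    counts = np.bincount(inverse).astype(float)
    f, n, _ = traj.coordinates.shape
    sums = np.zeros((f, len(unique), 3))
    np.add.at(sums, (slice(None), inverse), traj.coordinates)
    return sums / counts[None, :, None]


def msd(traj: Trajectory, grouping: str = "molecule", origin_stride: int = 1) -> MSDCurve:
    """All-origin mean-square displacement of group centers.

    Requires unwrapped coordinates: a frame-to-frame displacement larger
    than half the smallest box edge is taken as evidence of periodic
    wrapping and raises (use :func:`unwrap_trajectory` first).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for an MSD")
    if origin_stride < 1:
        raise ValueError("origin_stride must be >= 1")
    centers = _group_centers(traj, grouping)
    half_min_edge = min(min(b.lengths) for b in traj.boxes) / 2.0
    step = np.abs(np.diff(centers, axis=0)).max() if len(centers) > 1 else 0.0
    if step > half_min_edge:
        raise PolythermError(
            "frame-to-frame displacement exceeds half a box edge: coordinates look "
            "wrapped; unwrap with polytherm.transport.unwrap_trajectory first"
        )
    f = traj.n_frames
    lags = np.arange(f)
    out = np.zeros(f)
    n_pairs = np.zeros(f, dtype=int)
    n_pairs[0] = ((f - 1) // origin_stride + 1) * centers.shape[1]
    for tau in range(1, f):
        origins = np.arange(0, f - tau, origin_stride)
        disp = centers[origins + tau] - centers[origins]
        sq = np.sum(disp * disp, axis=-1)
        out[tau] = sq.mean()
        n_pairs[tau] = sq.size
    spacings = np.diff(traj.times)
    dt = float(spacings.mean())
    if not np.allclose(spacings, dt, rtol=1e-6):
        raise ValueError("all-origin MSD needs uniformly sampled frames")
    return MSDCurve(lags=lags * dt, msd=out, n_pairs=n_pairs)


def _loglog_slope(lags: np.ndarray, values: np.ndarray) -> float:
    mask = (lags > 0) & (values > 0)
    if mask.sum() < 2:
        return float("nan")
    res = stats.linregress(np.log(lags[mask]), np.log(values[mask]))
    return float(res.slope)


def fit_diffusivity(
    curve: MSDCurve, window: Union[Tuple[float, float], str] = "auto"
) -> DiffusivityResult:
    """Einstein-relation fit: D = slope/6 of MSD vs lag inside the window.

    ``window`` is (t_lo, t_hi) in ps, or ``"auto"`` to pick the
    contiguous window (by default spanning 30-70% of the maximum lag)
    whose log-log slope is closest to 1, i.e. the most random-walk-like
    stretch of the curve.
    """
    if isinstance(window, str):
        if window != "auto":
            raise ValueError(f"window must be (lo, hi) or 'auto', got {window!r}")
        window = _auto_window(curve)
    lo, hi = window
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    if mask.sum() < 5:
        raise ValueError(f"fewer than 5 lags inside the window [{lo}, {hi}] ps")
    lags, values = curve.lags[mask], curve.msd[mask]
    res = stats.linregress(lags, values)
    d = float(res.slope) / 6.0 * NM2_PER_PS_TO_CM2_PER_S
    slope_sd = float(res.stderr) / 6.0 * NM2_PER_PS_TO_CM2_PER_S
    ll = _loglog_slope(lags, values)
    diffusive = bool(LOGLOG_DIFFUSIVE_BAND[0] <= ll <= LOGLOG_DIFFUSIVE_BAND[1])
    return DiffusivityResult(
        diffusivity_cm2_s=max(d, 0.0) if diffusive else d,
        window_ps=(float(lo), float(hi)),
        slope_sd=slope_sd,
        loglog_slope=ll,
        diffusive=diffusive,
    )


def _auto_window(curve: MSDCurve, span_bounds: Tuple[float, float] = (0.3, 0.7)) -> Tuple[float, float]:
    """Scan candidate contiguous windows and return the most linear one."""
    t_max = curve.lags[-1]
    starts = np.linspace(0.1, 0.6, 6)
    best: tuple[float, tuple[float, float]] = (np.inf, (span_bounds[0] * t_max, span_bounds[1] * t_max))
    for f0 in starts:
        for f1 in np.linspace(f0 + 0.2, 0.9, 4):
            lo, hi = f0 * t_max, f1 * t_max
            mask = (curve.lags >= lo) & (curve.lags <= hi)
            if mask.sum() < 5:
                continue
            ll = _loglog_slope(curve.lags[mask], curve.msd[mask])
            score = abs(ll - 1.0)
            if np.isfinite(score) and score < best[0]:
                best = (score, (lo, hi))
    return best[1]
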
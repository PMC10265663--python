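"""Stress-strain analysis of uniaxial deformation runs.

True stress is the negative pressure-tensor component along the pull
direction, sigma = -P_z (converted bar -> GPa); engineering strain is
the relative box elongation eps = L_t/L_0 - 1. The raw stress
fluctuates strongly, so the curve is smoothed by a rolling average over
a strain window of +/-2.5% around each point, with the missing part of
the window before the start of the deformation filled with virtual
zero-stress points. Young's modulus is the least-squares slope of the
raw curve between 0.3 and 3% strain; the yield strength is the maximum
of the smoothed curve between 3 and 97% strain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from polytherm.core.types import PolythermError, TimeSeries
from polytherm.units import BAR_TO_GPA

DEFAULT_HALF_WINDOW = 0.025
DEFAULT_MODULUS_WINDOW = (0.003, 0.03)
DEFAULT_YIELD_WINDOW = (0.03, 0.97)


@dataclass
class StressStrainCurve:
    """Engineering strain vs true stress (GPa), raw and smoothed."""

    strain: np.ndarray
    stress: np.ndarray
    smoothed: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        if not (self.strain.shape == self.stress.shape == self.smoothed.shape):
            raise ValueError("strain, stress and smoothed stress must share a shape")
        if len(self.strain):
            if abs(self.strain[0]) > 1e-12:
                raise ValueError("strain must start at 0")
            if np.any(np.diff(self.strain) < 0):
                raise ValueError("strain must be non-decreasing")
        if not np.all(np.isfinite(self.stress)):
            raise ValueError("stress must be finite")

    def __len__(self) -> int:
        return len(self.strain)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "strain": self.strain,
                "stress (GPa)": self.stress,
                "smoothed stress (GPa)": self.smoothed,
            }
        )


@dataclass
class ModulusFit:
    modulus_gpa: float
    window: Tuple[float, float]
    n_points: int
    elastic: bool  # False when the in-window response carries no positive slope


@dataclass
class YieldResult:
    yield_gpa: float
    strain_at_yield: float
    window: Tuple[float, float]


@dataclass
class TensileResult:
    modulus_gpa: float
    yield_gpa: float
    strain_at_yield: float
    modulus_window: Tuple[float, float]
    yield_window: Tuple[float, float]
    elastic: bool


def engineering_strain(box_length_series: TimeSeries) -> TimeSeries:
    """eps(t) = L_t / L_0 - 1 from the box-length series (nm)."""
    L = box_length_series.values
    if len(L) == 0:
        raise ValueError("empty box-length series")
    if L[0] <= 0:
        raise ValueError("initial box length must be positive")
    return TimeSeries(name="strain", times=box_length_series.times, values=L / L[0] - 1.0, unit="")


def _smooth(strain: np.ndarray, stress: np.ndarray, half_window: float) -> np.ndarray:
    """Rolling mean over [eps-h, eps+h] with virtual zero-stress pre-start points.

    The count of virtual points brings each truncated early window up to
    the size a fully interior window would have on the (near-uniform)
    strain grid, implementing the zero-stress padding before the start
    of the deformation.
    """
    n = len(strain)
    if n == 0:
        return np.empty(0)
    order = np.argsort(strain, kind="stable")
    e, s = strain[order], stress[order]
    if n > 1 and e[-1] > e[0]:
        spacing = (e[-1] - e[0]) / (n - 1)
        n_full = int(round(2.0 * half_window / spacing)) + 1
    else:
        spacing = np.inf
        n_full = n
    lo = np.searchsorted(e, e - half_window, side="left")
    hi = np.searchsorted(e, e + half_window, side="right")
    csum = np.concatenate([[0.0], np.cumsum(s)])
    window_sum = csum[hi] - csum[lo]
    count = (hi - lo).astype(float)
    # pad only windows truncated at the low-strain end
    truncated = e - half_window < e[0]
    n_virtual = np.where(truncated, np.maximum(0, n_full - (hi - lo)), 0)
    smoothed_sorted = window_sum / (count + n_virtual)
    out = np.empty(n)
    out[order] = smoothed_sorted
    return out


def stress_curve(
    pressure_z: TimeSeries,
    strain: TimeSeries,
    half_window_strain: float = DEFAULT_HALF_WINDOW,
) -> StressStrainCurve:
    """Build the stress-strain curve from -P_z (bar) and strain, and smooth it."""
    if len(pressure_z) != len(strain) or not np.allclose(pressure_z.times, strain.times):
        raise PolythermError("pressure and strain series are not aligned on time")
    sigma = -pressure_z.values * BAR_TO_GPA
    eps = strain.values
    smoothed = _smooth(eps, sigma, half_window_strain)
    return StressStrainCurve(strain=eps, stress=sigma, smoothed=smoothed)


def youngs_modulus(
    curve: StressStrainCurve, window: Tuple[float, float] = DEFAULT_MODULUS_WINDOW
) -> ModulusFit:
    """Least-squares slope of the raw stress over the elastic strain window."""
    lo, hi = window
    mask = (curve.strain >= lo) & (curve.strain <= hi)
    if mask.sum() < 2:
        raise ValueError(f"fewer than 2 points in the strain window [{lo}, {hi}]")
    e, s = curve.strain[mask], curve.stress[mask]
    slope = float(np.polyfit(e, s, 1)[0])
    spread = float(np.std(s))
    elastic = slope > 0 and (spread == 0.0 or slope * (hi - lo) > 1e-9 * max(spread, 1e-300))
    if np.allclose(s, s[0]):
        elastic = False
        slope = 0.0
    return ModulusFit(modulus_gpa=slope, window=(lo, hi), n_points=int(mask.sum()), elastic=elastic)


def yield_strength(
    curve: StressStrainCurve, window: Tuple[float, float] = DEFAULT_YIELD_WINDOW
) -> YieldResult:
    """Maximum of the smoothed stress in the strain window; ties take the earliest strain."""
    lo, hi = window
    mask = (curve.strain >= lo) & (curve.strain <= hi)
    if not mask.any():
        raise ValueError(f"no points in the strain window [{lo}, {hi}]")
    e, s = curve.strain[mask], curve.smoothed[mask]
    best = int(np.argmax(s))  # argmax returns the first maximum -> earliest strain
    return YieldResult(yield_gpa=float(s[best]), strain_at_yield=float(e[best]), window=(lo, hi))


def tensile_result(
    curve: StressStrainCurve,
    modulus_window: Tuple[float, float] = DEFAULT_MODULUS_WINDOW,
    yield_window: Tuple[float, float] = DEFAULT_YIELD_WINDOW,
) -> TensileResult:
    """Convenience wrapper: modulus and yield from one curve."""
    m = youngs_modulus(curve, modulus_window)
    y = yield_strength(curve, yield_window)
    return TensileResult(
        modulus_gpa=m.modulus_gpa,
        yield_gpa=y.yield_gpa,
        strain_at_yield=y.strain_at_yield,
        modulus_window=m.window,
        yield_window=y.window,
        elastic=m.elastic,
    )


def face_shift_average(curves: Sequence[StressStrainCurve]) -> StressStrainCurve:
    """Pointwise mean of several curves (e.g. five box-face shifts of 20% each).

    Curves are resampled onto the first curve's strain grid by linear
    interpolation when grids differ; raw and smoothed stresses are both
    averaged.
    """
    if not curves:
        raise ValueError("need at least one curve to average")
    grid = curves[0].strain
    raw = np.zeros_like(grid)
    smooth = np.zeros_like(grid)
    for c in curves:
        if len(c.strain) == len(grid) and np.allclose(c.strain, grid):
            raw += c.stress
            smooth += c.smoothed
        else:
            raw += np.interp(grid, c.strain, c.stress)
            smooth += np.interp(grid, c.strain, c.smoothed)
    k = float(len(curves))
    return StressStrainCurve(strain=grid.copy(), stress=raw / k, smoothed=smooth / k)
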
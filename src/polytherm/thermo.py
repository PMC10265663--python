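"""PVT analysis: specific volume, density, glass transition, thermal expansion.

The glass-transition temperature is located by broken-stick regression:
one straight line through the coldest points (glassy regime), one
through the hottest (rubbery regime); Tg is the abscissa of their
intersection. The coefficient of thermal expansion is
CTE = (1/v) dv/dT evaluated from the least-squares slope below Tg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from polytherm.core.types import PolythermError, TimeSeries
from polytherm.units import NM3_TO_CM3


@dataclass
class ThermoSeries:
    """Specific volume (cm^3/g) on a temperature grid (K)."""

    temperatures: np.ndarray
    specific_volumes: np.ndarray
    sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.specific_volumes = np.asarray(self.specific_volumes, dtype=float)
        if self.temperatures.shape != self.specific_volumes.shape:
            raise ValueError("temperature and volume grids must match")
        d = np.diff(self.temperatures)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("temperatures must be strictly monotone")
        if not np.all(self.specific_volumes > 0):
            raise ValueError("specific volumes must be positive")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.temperatures.shape:
                raise ValueError("per-point sd must match the grid")

    def __len__(self) -> int:
        return len(self.temperatures)

    def sorted(self) -> "ThermoSeries":
        order = np.argsort(self.temperatures)
        return ThermoSeries(
            self.temperatures[order],
            self.specific_volumes[order],
            None if self.sd is None else self.sd[order],
        )

    def to_frame(self):
        import pandas as pd

        data = {
            "temperature (K)": self.temperatures,
            "specific volume (cm^3/g)": self.specific_volumes,
        }
        if self.sd is not None:
            data["sd (cm^3/g)"] = self.sd
        return pd.DataFrame(data)


@dataclass
class TgResult:
    """Broken-stick fit: Tg plus both fitted lines and their residuals."""

    tg: float
    glass_slope: float
    glass_intercept: float
    rubber_slope: float
    rubber_intercept: float
    glass_residuals: np.ndarray
    rubber_residuals: np.ndarray
    in_range: bool
    flags: Tuple[str, ...] = ()

    def line_glass(self, T: np.ndarray) -> np.ndarray:
        return self.glass_slope * np.asarray(T) + self.glass_intercept

    def line_rubber(self, T: np.ndarray) -> np.ndarray:
        return self.rubber_slope * np.asarray(T) + self.rubber_intercept


@dataclass
class SpecificVolumeResult:
    specific_volume: float  # cm^3/g
    density: float  # g/cm^3
    window_ps: float
    n_frames: int


def specific_volume(
    volume_series: TimeSeries, total_mass_g: float, window_ps: float = 500.0
) -> SpecificVolumeResult:
    """Specific volume from the trailing-window mean of box volume.

    ``volume_series`` is box volume in nm^3 vs time in ps; the mean over
    the final ``window_ps`` of the series, divided by the total system
    mass, gives v in cm^3/g (density 1/v reported alongside).
    """
    if total_mass_g <= 0:
        raise ValueError("total mass must be positive")
    t = volume_series.times
    span = t[-1] - t[0]
    if span < window_ps:
        raise ValueError(f"series spans {span} ps, shorter than the {window_ps} ps window")
    mask = t >= t[-1] - window_ps
    mean_volume_nm3 = float(np.mean(volume_series.values[mask]))
    v = mean_volume_nm3 * NM3_TO_CM3 / total_mass_g
    return SpecificVolumeResult(
        specific_volume=v,
        density=1.0 / v,
        window_ps=window_ps,
        n_frames=int(mask.sum()),
    )


def _fit_line(T: np.ndarray, v: np.ndarray) -> tuple[float, float, np.ndarray]:
    slope, intercept = np.polyfit(T, v, 1)
    residuals = v - (slope * T + intercept)
    return float(slope), float(intercept), residuals


def broken_stick_tg(series: ThermoSeries, n_low: int = 7, n_high: int = 7) -> TgResult:
    """Locate Tg as the intersection of cold-end and hot-end fit lines.

    Least-squares lines through the ``n_low`` coldest and ``n_high``
    hottest points; their intersection is Tg. Parallel lines raise; an
    intersection outside the data range is returned but flagged.
    """
    s = series.sorted()
    n = len(s)
    if n_low < 2 or n_high < 2:
        raise ValueError("need at least two points per segment")
    if n_low + n_high > n:
        raise ValueError(f"n_low + n_high = {n_low + n_high} exceeds the {n} available points")
    T, v = s.temperatures, s.specific_volumes
    g_slope, g_int, g_res = _fit_line(T[:n_low], v[:n_low])
    r_slope, r_int, r_res = _fit_line(T[-n_high:], v[-n_high:])
    denom = g_slope - r_slope
    scale = max(abs(g_slope), abs(r_slope), 1e-300)
    if abs(denom) <= 1e-12 * scale:
        raise PolythermError("no intersection: glassy and rubbery fit lines are parallel")
    tg = (r_int - g_int) / denom
    flags = []
    in_range = bool(T[0] <= tg <= T[-1])
    if not in_range:
        flags.append("tg outside data range")
    if r_slope < g_slope:
        flags.append("rubbery slope below glassy slope")
    return TgResult(
        tg=float(tg),
        glass_slope=g_slope,
        glass_intercept=g_int,
        rubber_slope=r_slope,
        rubber_intercept=r_int,
        glass_residuals=g_res,
        rubber_residuals=r_res,
        in_range=in_range,
        flags=tuple(flags),
    )


def thermal_expansion(series: ThermoSeries, t_range: Tuple[float, float]) -> float:
    """CTE (1/K) = (1/v̄)(dv/dT) over ``t_range``.

    dv/dT is the least-squares slope of specific volume vs temperature
    restricted to the range; v̄ is the mean specific volume there.
    """
    lo, hi = min(t_range), max(t_range)
    s = series.sorted()
    mask = (s.temperatures >= lo) & (s.temperatures <= hi)
    if mask.sum() < 2:
        raise ValueError(f"need at least 2 points in [{lo}, {hi}] K, found {int(mask.sum())}")
    T, v = s.temperatures[mask], s.specific_volumes[mask]
    slope, _, _ = _fit_line(T, v)
    return float(slope / np.mean(v))


def archimedes_density(
    weight_air_g: float,
    weight_liquid_g: float,
    rho_liquid: float = 0.6838,
    rho_air: float = 0.0012,
) -> float:
    """Sample density (g/cm^3) from weights in air and in an immersion liquid.

    rho = A/(A-B) * (rho_liquid - rho_air) + rho_air, with A the weight
    in air and B the weight in the liquid. Defaults are n-heptane
    (0.6838 g/cm^3) and air (0.0012 g/cm^3) at room temperature.
    """
    A, B = float(weight_air_g), float(weight_liquid_g)
    if A <= 0:
        raise ValueError("weight in air must be positive")
    if A <= B:
        raise ValueError("weight in air must exceed weight in liquid (buoyancy)")
    return A / (A - B) * (rho_liquid - rho_air) + rho_air


def archimedes_density_replicates(
    weights_air_g: Sequence[float],
    weights_liquid_g: Sequence[float],
    rho_liquid: float = 0.6838,
    rho_air: float = 0.0012,
) -> tuple[float, float, np.ndarray]:
    """Mean, sample sd and per-replicate densities for replicate weighings."""
    if len(weights_air_g) != len(weights_liquid_g):
        raise ValueError("replicate lists must have equal length")
    densities = np.array(
        [
            archimedes_density(a, b, rho_liquid=rho_liquid, rho_air=rho_air)
            for a, b in zip(weights_air_g, weights_liquid_g)
        ]
    )
    sd = float(np.std(densities, ddof=1)) if len(densities) > 1 else 0.0
    return float(np.mean(densities)), sd, densities
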
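"""Domain containers shared by all analysis stages.

All containers validate their invariants on construction. Positions are
stored in nm, times in ps; boxes are orthorhombic (edge lengths along
the Cartesian axes). Positions may lie outside the box; pair-distance
code applies the minimum-image convention, and :meth:`AtomSet.wrapped`
wraps on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np


class PolythermError(Exception):
    """Base class for all polytherm errors."""


class ParseError(PolythermError):
    """A file could not be parsed under its declared format."""


class StructuralError(PolythermError):
    """Parsed data violates a structural invariant (e.g. mixed atom counts)."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic simulation box with edge lengths in nm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ValueError(f"box edges must be positive, got {self.lengths}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def volume(self) -> float:
        """Box volume in nm^3."""
        return float(self.lx * self.ly * self.lz)


@dataclass
class AtomSet:
    """One frame of atoms: positions plus static per-atom metadata.

    Parameters
    ----------
    positions
        (n_atoms, 3) array in nm.
    elements
        Element symbol per atom ('C', 'O', 'H', ...). Required.
    vdw_radii
        van der Waals radius per atom in nm; all > 0.
    molecule_ids
        Integer molecule id per atom (contiguous ids not required).
    is_donor, is_acceptor, is_hydrogen
        Optional boolean role flags used by hydrogen-bond detection.
    species
        Optional per-atom species tag (e.g. 'polymer', 'water') used to
        label hydrogen-bond pairs.
    """

    positions: np.ndarray
    elements: np.ndarray
    vdw_radii: np.ndarray
    molecule_ids: np.ndarray
    is_donor: Optional[np.ndarray] = None
    is_acceptor: Optional[np.ndarray] = None
    is_hydrogen: Optional[np.ndarray] = None
    species: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.elements = np.asarray(self.elements, dtype=object)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        for name in ("elements", "vdw_radii", "molecule_ids"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if n and not np.all(self.vdw_radii > 0):
            raise ValueError("all van der Waals radii must be > 0")
        if n and any(not e for e in self.elements):
            raise ValueError("every atom must have an element symbol")
        for name in ("is_donor", "is_acceptor", "is_hydrogen"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=bool)
                if len(arr) != n:
                    raise ValueError(f"{name} has length {len(arr)}, expected {n}")
                setattr(self, name, arr)
        if self.species is not None:
            self.species = np.asarray(self.species, dtype=object)
            if len(self.species) != n:
                raise ValueError("species must have one tag per atom")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def wrapped(self, box: Box) -> "AtomSet":
        """Return a copy with positions wrapped into [0, L) per axis."""
        pos = np.mod(self.positions, box.lengths)
        return replace(self, positions=pos)


@dataclass
class Trajectory:
    """Ordered frames of atom coordinates with per-frame boxes.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in nm; ``times`` is
    strictly increasing in ps; ``boxes`` is a sequence of one Box per
    frame. Static atom metadata (elements, radii, molecule ids, role
    flags) is shared across frames via ``atoms`` (its positions are the
    first frame and are ignored by :meth:`frame`).
    """

    times: np.ndarray
    coordinates: np.ndarray
    boxes: Sequence[Box]
    atoms: AtomSet

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        f, n, _ = self.coordinates.shape
        if len(self.times) != f:
            raise ValueError("times and coordinates disagree on frame count")
        if len(self.boxes) != f:
            raise StructuralError("one box required per frame")
        if f > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.atoms.n_atoms != n:
            raise StructuralError(
                f"atom metadata covers {self.atoms.n_atoms} atoms, frames have {n}"
            )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> tuple[float, AtomSet, Box]:
        """Return (time, AtomSet, Box) for frame ``i``."""
        atoms = replace(self.atoms, positions=self.coordinates[i])
        return float(self.times[i]), atoms, self.boxes[i]


@dataclass
class TimeSeries:
    """Scalar observable vs time (box volume, pressure component, ...)."""

    name: str
    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equally long")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"times in series '{self.name}' must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        unit = f" ({self.unit})" if self.unit else ""
        return pd.DataFrame({"time (ps)": self.times, f"{self.name}{unit}": self.values})
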
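"""Readers and writers for the formats the pipeline touches.

Coordinates (GRO, PDB, XYZ) are read and written through MDAnalysis and
normalized to the internal units (nm, ps). Time-series tables come in as
CSV or as the XVG dialect produced by MD energy extractors (comment
lines starting with '#' or '@'). All derived curves are written as CSV
with headers naming quantity and units.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from polytherm.core.radii import load_radii_table, vdw_radius
from polytherm.core.types import (
    AtomSet,
    Box,
    ParseError,
    StructuralError,
    TimeSeries,
    Trajectory,
)
from polytherm.units import ANGSTROM_TO_NM, NM_TO_ANGSTROM

_COORD_FORMATS = {"gro", "pdb", "xyz"}

_TWO_LETTER = {"Cl", "Br", "Na", "Mg", "Ca", "Si", "Fe", "Zn", "He", "Ne", "Ar"}


def _infer_element(name: str) -> str:
    """Infer an element symbol from an atom name like 'OW', 'C4' or 'HO2'."""
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    two = stripped[:2].capitalize()
    if two in _TWO_LETTER:
        return two
    return stripped[0].upper()


def _format_from_path(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in _COORD_FORMATS:
        raise ValueError(f"unsupported coordinate format {fmt!r}; expected one of {sorted(_COORD_FORMATS)}")
    return fmt


def _check_orthorhombic(dimensions: np.ndarray, path) -> Box:
    if dimensions is None or not np.all(dimensions[:3] > 0):
        raise StructuralError(f"{path}: missing or degenerate box")
    if not np.allclose(dimensions[3:6], 90.0, atol=1e-3):
        raise StructuralError(
            f"{path}: triclinic box (angles {dimensions[3:6]}) — only orthorhombic boxes are supported"
        )
    return Box(*(dimensions[:3] * ANGSTROM_TO_NM))


def _validate_xyz(path: Path) -> None:
    """Cheap structural pre-check for XYZ: constant atom count per frame."""
    counts = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{i + 1}: expected an atom count, got {lines[i].strip()!r}")
        counts.append(n)
        i += n + 2
    if len(set(counts)) > 1:
        raise StructuralError(f"{path}: mixed atom counts across frames: {sorted(set(counts))}")


def load_coordinates(
    path: Union[str, Path],
    fmt: Optional[str] = None,
    radii_overrides: Optional[Mapping[str, float]] = None,
) -> Trajectory:
    """Load a GRO, PDB or XYZ file into a :class:`Trajectory` (nm, ps).

    Elements are taken from the file when present and inferred from atom
    names otherwise. XYZ frames without time stamps get times 0, 1, 2,
    ... ps by convention. van der Waals radii are assigned per element
    from the shipped table (``radii_overrides`` replaces entries).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _format_from_path(path, fmt)
    if fmt == "xyz":
        _validate_xyz(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(str(path), format=fmt)
            n_atoms = len(universe.atoms)
            try:
                elements = [str(e) for e in universe.atoms.elements]
                if any(not e for e in elements):
                    raise AttributeError
            except (AttributeError, mda.exceptions.NoDataError):
                elements = [_infer_element(str(n)) for n in universe.atoms.names]
            try:
                molecule_ids = np.asarray(universe.atoms.resids, dtype=int)
            except (AttributeError, mda.exceptions.NoDataError):
                molecule_ids = np.zeros(n_atoms, dtype=int)
            times, coords, boxes = [], [], []
            for ts in universe.trajectory:
                times.append(float(ts.time))
                coords.append(ts.positions.astype(float) * ANGSTROM_TO_NM)
                if fmt == "xyz":
                    # XYZ carries no box; use an effectively open box
                    boxes.append(Box(1e6, 1e6, 1e6))
                else:
                    boxes.append(_check_orthorhombic(ts.dimensions, path))
    except (StructuralError, ParseError, FileNotFoundError):
        raise
    except Exception as exc:  # MDAnalysis raises assorted ValueError/IOError subclasses
        raise ParseError(f"{path}: failed to parse as {fmt.upper()}: {exc}") from exc

    table = load_radii_table(radii_overrides)
    radii = np.array([vdw_radius(e, table) for e in elements])
    atoms = AtomSet(
        positions=coords[0],
        elements=np.asarray(elements, dtype=object),
        vdw_radii=radii,
        molecule_ids=molecule_ids,
    )
    return Trajectory(times=np.asarray(times), coordinates=np.stack(coords), boxes=boxes, atoms=atoms)


def write_coordinates(traj: Trajectory, path: Union[str, Path], fmt: Optional[str] = None) -> None:
    """Write a Trajectory to GRO (single frame), PDB or XYZ."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = _format_from_path(path, fmt)
    if fmt == "gro" and traj.n_frames > 1:
        raise ValueError("GRO holds a single frame; use PDB or XYZ for multi-frame output")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        u.add_TopologyAttr("names", [str(e) for e in traj.atoms.elements])
        u.add_TopologyAttr("elements", [str(e) for e in traj.atoms.elements])
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=traj.n_frames > 1) as writer:
            for i in range(traj.n_frames):
                _, atoms, box = traj.frame(i)
                u.atoms.positions = atoms.positions * NM_TO_ANGSTROM
                u.dimensions = [*(box.lengths * NM_TO_ANGSTROM), 90.0, 90.0, 90.0]
                writer.write(u.atoms)


def load_timeseries(
    path: Union[str, Path],
    column: Union[int, str],
    fmt: Optional[str] = None,
    unit: str = "",
    name: Optional[str] = None,
) -> TimeSeries:
    """Load one column of an XVG or CSV table as a :class:`TimeSeries`.

    The first column of the file is always time (ps). ``column`` selects
    a value column either positionally (0 = first value column) or by
    name: the CSV header, or an XVG ``@ sN legend "..."`` label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xvg":
        legends: dict[str, int] = {}
        data_lines = []
        for line in path.read_text().splitlines():
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                continue
            if s.startswith("@"):
                parts = s.split('"')
                if len(parts) >= 2 and " legend " in parts[0] and parts[0].split()[1].startswith("s"):
                    legends[parts[1]] = int(parts[0].split()[1][1:])
                continue
            data_lines.append(s)
        try:
            data = np.loadtxt(_io.StringIO("\n".join(data_lines)), ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: malformed XVG data: {exc}") from exc
        n_value_cols = data.shape[1] - 1
        if isinstance(column, str):
            if column not in legends:
                raise KeyError(f"column {column!r} not found; available: {sorted(legends)}")
            idx = legends[column]
        else:
            idx = int(column)
        if not 0 <= idx < n_value_cols:
            raise KeyError(f"column index {idx} out of range; file has {n_value_cols} value column(s)")
        return TimeSeries(
            name=name or (column if isinstance(column, str) else f"column{idx}"),
            times=data[:, 0],
            values=data[:, idx + 1],
            unit=unit,
        )
    if fmt == "csv":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ParseError(f"{path}: CSV needs a time column plus at least one value column")
        time_col = df.columns[0]
        if isinstance(column, str):
            matches = [c for c in df.columns[1:] if c == column or c.split(" (")[0] == column]
            if not matches:
                raise KeyError(f"column {column!r} not found; available: {list(df.columns[1:])}")
            col = matches[0]
        else:
            try:
                col = df.columns[1:][int(column)]
            except IndexError:
                raise KeyError(f"column index {column} out of range; available: {list(df.columns[1:])}")
        return TimeSeries(name=name or str(col).split(" (")[0], times=df[time_col].to_numpy(float), values=df[col].to_numpy(float), unit=unit)
    raise ValueError(f"unsupported time-series format {fmt!r}; expected 'xvg' or 'csv'")


def write_table(obj, path: Union[str, Path]) -> None:
    """Write any derived curve (anything with ``to_frame()``) or DataFrame as CSV."""
    if hasattr(obj, "to_frame"):
        frame = obj.to_frame()
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot tabulate object of type {type(obj).__name__}")
    frame.to_csv(path, index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table`."""
    return pd.read_csv(path)
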
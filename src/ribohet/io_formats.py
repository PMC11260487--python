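"""Readers and writers for the structural and tabular formats the pipeline consumes.

Three carriers are defined here:

``DensityVolume``
    a 3-D voxel grid with physical spacing and origin (Å), the unit that is
    scored for block occupancy;
``AtomicModel``
    a flat list of heavy-atom records parsed from PDB/mmCIF, e.g. a mature
    50S coordinate set used as the segmentation reference;
``GradientTrace``
    an absorbance-vs-position curve from a sucrose gradient run.

Map and structure I/O is backed by gemmi; traces are plain two-column
delimited text read with pandas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import EmptyModelError, MapFormatError, TraceFormatError

__all__ = [
    "DensityVolume",
    "AtomRecord",
    "AtomicModel",
    "GradientTrace",
    "read_density_map",
    "write_density_map",
    "read_structure",
    "read_gradient_trace",
    "write_gradient_trace",
]

_SUPPORTED_MODES = (0, 1, 2)  # int8, int16, float32


@dataclass
class DensityVolume:
    """A density map on a regular grid.

    ``data`` is indexed ``[ix, iy, iz]``; the physical position of voxel
    ``(i, j, k)`` is ``origin + (i, j, k) * voxel_size`` in Å. Axis order is
    normalized at load time regardless of the file's MAPC/MAPR/MAPS fields.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise MapFormatError(f"density grid must be 3-D, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise MapFormatError(f"voxel size must be positive, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)
        if not np.all(np.isfinite(self.data)):
            raise MapFormatError("density grid contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    resnum: int
    resname: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class AtomicModel:
    """Heavy-atom coordinates with author residue numbering preserved."""

    atoms: list[AtomRecord]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyModelError(f"model {self.source_id!r} has no atoms")

    def coordinates(self) -> np.ndarray:
        """N×3 array of Å coordinates in atom order."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class GradientTrace:
    """A260 absorbance against sedimentation position (top of gradient first)."""

    position: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.position.shape != self.absorbance.shape or self.position.ndim != 1:
            raise TraceFormatError("position and absorbance must be equal-length 1-D arrays")
        if self.position.size < 8:
            raise TraceFormatError(f"trace too short: {self.position.size} rows (need >= 8)")
        if not np.all(np.diff(self.position) > 0):
            raise TraceFormatError(f"positions of trace {self.label!r} are not strictly increasing")


def read_density_map(path: str | Path) -> DensityVolume:
    """Read an MRC/CCP4 2014 map (modes 0/1/2).

    The axis permutation encoded in MAPC/MAPR/MAPS is normalized so that
    ``data[ix, iy, iz]`` always follows the x, y, z crystallographic axes.
    Origin precedence: the ORIGIN header words when any is nonzero, else
    NXSTART/NYSTART/NZSTART times the voxel size.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise MapFormatError(f"{path}: zero-length file is not a map")
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in _SUPPORTED_MODES:
        raise MapFormatError(f"{path}: unsupported voxel mode {mode} (MODE header word)")
    mapc, mapr, maps_ = (m.header_i32(i) for i in (17, 18, 19))
    if sorted((mapc, mapr, maps_)) != [1, 2, 3]:
        raise MapFormatError(
            f"{path}: invalid axis permutation MAPC/MAPR/MAPS = {(mapc, mapr, maps_)}"
        )
    nstart = [m.header_i32(i) for i in (5, 6, 7)]
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    data = np.array(m.grid, copy=True)
    if not np.all(np.isfinite(data)):
        raise MapFormatError(f"{path}: map contains non-finite voxels")
    cell = m.grid.unit_cell
    nx, ny, nz = data.shape
    if cell.a <= 0 or cell.b <= 0 or cell.c <= 0:
        raise MapFormatError(f"{path}: non-positive cell dimensions (CELLA header words)")
    voxel = (cell.a / nx, cell.b / ny, cell.c / nz)
    origin = tuple(m.header_float(i) for i in (50, 51, 52))
    if all(v == 0.0 for v in origin):
        origin = tuple(s * v for s, v in zip(nstart, voxel))
    return DensityVolume(data=data, voxel_size=voxel, origin=origin, label=path.stem)


def write_density_map(volume: DensityVolume, path: str | Path) -> None:
    """Write a mode-2 (float32) MRC/CCP4 map; read_density_map inverts it bit-exactly."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data, dtype=np.float32))
    nx, ny, nz = volume.grid_shape
    vx, vy, vz = volume.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)
    for word, value in zip((50, 51, 52), volume.origin):
        m.set_header_float(word, value)
    m.write_ccp4_map(str(path))


def _best_altloc(group: list) -> "gemmi.Atom":
    """Highest-occupancy conformer; ties go to the earliest in file order."""
    return max(group, key=lambda a: a.occ)


def read_structure(path: str | Path) -> AtomicModel:
    """Parse a PDB or mmCIF coordinate file into an AtomicModel.

    Hydrogens are dropped; for alternate locations only the highest-occupancy
    conformer of each atom is kept; author residue numbering is preserved.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise EmptyModelError(f"{path}: {exc}") from exc
    st.remove_hydrogens()
    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    model = st[0]
    for chain in model:
        for residue in chain:
            # group alternate locations by atom name, keep the best conformer
            by_name: dict[str, list] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                atom = group[0] if len(group) == 1 else _best_altloc(group)
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        resname=residue.name.strip(),
                        atom_name=name,
                        element=atom.element.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    if not atoms:
        raise EmptyModelError(f"{path}: no atoms parsed")
    return AtomicModel(atoms=atoms, source_id=path.stem)


def read_gradient_trace(path: str | Path, label: str | None = None) -> GradientTrace:
    """Read a two-column (position, absorbance) CSV/TSV, optional header line."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc
    # tolerate a single non-numeric header row
    first = df.iloc[0]
    try:
        [float(v) for v in first]
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.shape[1] != 2:
        raise TraceFormatError(f"{path}: expected 2 columns, found {df.shape[1]}")
    try:
        pos = df.iloc[:, 0].astype(float).to_numpy()
        absb = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise TraceFormatError(f"{path}: non-numeric data: {exc}") from exc
    return GradientTrace(position=pos, absorbance=absb, label=label or path.stem)


def write_gradient_trace(trace: GradientTrace, path: str | Path) -> None:
    pd.DataFrame({"position": trace.position, "absorbance": trace.absorbance}).to_csv(
        path, index=False
    )
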
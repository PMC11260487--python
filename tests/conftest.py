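"""Shared fixtures: an independent minimal MRC writer, structure fixtures
written by hand in both PDB and mmCIF dialects, and a phantom model."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from ribohet.synthetic import make_phantom


def write_mrc_oracle(path, data, voxel=1.0, mapc=1, mapr=2, maps=3, origin=(0.0, 0.0, 0.0)):
    """Write an MRC2014 mode-2 map byte by byte, independent of any map library.

    ``data`` is indexed [ix, iy, iz]; the file stores columns fastest and
    sections slowest along the axes named by MAPC/MAPR/MAPS.
    """
    nx, ny, nz = data.shape
    axis_of = {1: 0, 2: 1, 3: 2}
    perm = (axis_of[mapc], axis_of[mapr], axis_of[maps])
    arr = np.transpose(np.asarray(data, dtype=np.float32), perm)  # [col, row, sec]
    h = b""
    h += struct.pack("<3i", *arr.shape)                      # NC NR NS
    h += struct.pack("<i", 2)                                # MODE
    h += struct.pack("<3i", 0, 0, 0)                         # NCSTART NRSTART NSSTART
    h += struct.pack("<3i", nx, ny, nz)                      # MX MY MZ
    h += struct.pack("<3f", nx * voxel, ny * voxel, nz * voxel)  # CELLA
    h += struct.pack("<3f", 90.0, 90.0, 90.0)                # CELLB
    h += struct.pack("<3i", mapc, mapr, maps)
    h += struct.pack("<3f", float(arr.min()), float(arr.max()), float(arr.mean()))
    h += struct.pack("<i", 1)                                # ISPG
    h += struct.pack("<i", 0)                                # NSYMBT
    h += b"\0" * (4 * 25)                                    # EXTRA
    h += struct.pack("<3f", *origin)                         # ORIGIN
    h += b"MAP "
    h += bytes([0x44, 0x44, 0, 0])                           # little-endian stamp
    h += struct.pack("<f", float(arr.std()))                 # RMS
    h += struct.pack("<i", 0)                                # NLABL
    h += b"\0" * (1024 - len(h))
    with open(path, "wb") as fh:
        fh.write(h)
        fh.write(np.ascontiguousarray(arr.transpose(2, 1, 0), dtype="<f4").tobytes())


def pdb_lines(records):
    """records: (serial, name, resname, chain, resnum, x, y, z, occ, altloc, element)."""
    lines = []
    for serial, name, resname, chain, resnum, x, y, z, occ, altloc, element in records:
        lines.append(
            f"ATOM  {serial:>5} {name:<4}{altloc:1}{resname:<3} {chain:1}{resnum:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{20.0:6.2f}          {element:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def mmcif_text(records):
    """Same records rendered as a minimal atom_site loop."""
    head = """data_fixture
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
"""
    rows = []
    for serial, name, resname, chain, resnum, x, y, z, occ, altloc, element in records:
        alt = altloc if altloc.strip() else "."
        rows.append(
            f"ATOM {serial} {element} {name.strip()} {alt} {resname} {chain} {resnum} "
            f"{x:.3f} {y:.3f} {z:.3f} {occ:.2f} 20.00 {resnum} {chain}"
        )
    return head + "\n".join(rows) + "\n"


THREE_ATOMS = [
    (1, " P  ", "G", "A", 10, 1.0, 2.0, 3.0, 1.0, " ", "P"),
    (2, " C1'", "G", "A", 11, 4.0, 5.0, 6.0, 1.0, " ", "C"),
    (3, " N1 ", "C", "B", 7, 7.0, 8.0, 9.0, 1.0, " ", "N"),
]


@pytest.fixture(scope="session")
def phantom():
    """Deterministic phantom model + library shared across tests."""
    return make_phantom(seed=2)
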
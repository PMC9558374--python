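"""File I/O: extended-XYZ trajectories and cells, point charges, topologies.

Formats
-------
* **Multi-frame extended XYZ** — repeated blocks of::

      <n_atoms>
      time=<ps> [Lattice="ax ay az bx by bz cx cy cz"] [Origin="ox oy oz"]
      <element> <x> <y> <z>

  All lengths in Å, times in ps. The comment line carries plain
  ``key=value`` fields; quoted values may contain spaces.
* **Point charges** — one ``x y z q`` line per site, fixed 6-decimal
  formatting, suitable for electrostatic-embedding input.
* **Topology YAML** — a list of per-atom mappings with keys
  ``name, element, molecule_id, role, charge, vdw_radius`` (the radius
  may be omitted for physical atoms, in which case the Bondi value of
  the element is used).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import (
    BONDI_RADII,
    AtomRecord,
    CybospecError,
    Frame,
    GeometryError,
    Topology,
    TopologyError,
    Trajectory,
    UnitCell,
)

__all__ = [
    "ParseError",
    "read_trajectory",
    "write_trajectory",
    "read_xyz_frame",
    "read_unit_cell",
    "write_unit_cell",
    "write_point_charges",
    "read_point_charges",
    "read_topology",
    "write_topology",
]


class ParseError(CybospecError):
    """A file could not be parsed; the message names the offending frame."""


_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(line)}


def _read_xyz_blocks(path):
    """Yield (frame_index, comment_fields, elements, coords) per XYZ block."""
    lines = Path(path).read_text().splitlines()
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise ParseError(f"frame {frame_index}: bad atom-count line {lines[pos]!r}")
        if pos + 1 + n >= len(lines) + 1 and n > 0:
            raise ParseError(f"frame {frame_index}: truncated block ({n} atoms declared)")
        fields = _parse_comment(lines[pos + 1])
        elements: list[str] = []
        coords = np.empty((n, 3), dtype=float)
        for i in range(n):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise ParseError(f"frame {frame_index}: malformed atom line {i}")
            elements.append(parts[0])
            coords[i] = [float(v) for v in parts[1:4]]
        yield frame_index, fields, elements, coords
        pos += 2 + n
        frame_index += 1


def read_trajectory(path, topology: Topology) -> Trajectory:
    """Read a multi-frame extended-XYZ file against a known topology.

    Frames missing a ``time=`` field are numbered 0, 1, 2, ... ps.
    """
    frames: list[Frame] = []
    for k, fields, elements, coords in _read_xyz_blocks(path):
        if len(elements) != topology.n_atoms:
            raise TopologyError(
                f"frame {k} has {len(elements)} atoms, topology has {topology.n_atoms}"
            )
        t = float(fields["time"]) if "time" in fields else float(k)
        frames.append(Frame(time=t, coordinates=coords))
    return Trajectory(topology=topology, frames=frames)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-frame extended XYZ (6-decimal floats)."""
    elements = [a.element for a in traj.topology.atoms]
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{len(elements)}\n")
            fh.write(f"time={fr.time:.6f}\n")
            for el, (x, y, z) in zip(elements, fr.coordinates):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_frame(path) -> tuple[list[str], np.ndarray]:
    """Read the first frame of an XYZ file → (elements, coordinates)."""
    for _, _, elements, coords in _read_xyz_blocks(path):
        return elements, coords
    raise ParseError(f"{path}: no frames found")


def read_unit_cell(path, topology: Topology | None = None) -> UnitCell:
    """Read a solvent cell from extended XYZ with a ``Lattice=`` comment.

    The nine ``Lattice`` numbers are the three cell vectors in row-major
    order; ``Origin`` defaults to zero. Without an explicit topology, a
    solvent-role topology is inferred from the ``mol_size`` comment field
    (atoms are grouped into consecutive blocks of that size; default 1),
    with Bondi radii and zero charges.
    """
    for k, fields, elements, coords in _read_xyz_blocks(path):
        if "Lattice" not in fields:
            raise ParseError(f"frame {k}: cell file lacks a Lattice field")
        nums = [float(v) for v in fields["Lattice"].split()]
        if len(nums) != 9:
            raise ParseError(f"frame {k}: Lattice needs 9 numbers, got {len(nums)}")
        lattice = np.array(nums, dtype=float).reshape(3, 3)
        origin = np.zeros(3)
        if "Origin" in fields:
            origin = np.array([float(v) for v in fields["Origin"].split()])
        if topology is None:
            if "mol_size" in fields:
                msize = int(fields["mol_size"])
            else:
                msize = 1
            atoms = [
                AtomRecord(
                    name=f"{el}{i}",
                    element=el,
                    molecule_id=i // msize,
                    role="solvent",
                    charge=0.0,
                    vdw_radius=BONDI_RADII.get(el, 1.5),
                )
                for i, el in enumerate(elements)
            ]
            topology = Topology(atoms)
        if topology.n_atoms != len(elements):
            raise TopologyError(
                f"cell has {len(elements)} atoms, topology has {topology.n_atoms}"
            )
        return UnitCell(origin=origin, lattice_vectors=lattice,
                        topology=topology, coordinates=coords)
    raise ParseError(f"{path}: no frames found")


def write_unit_cell(cell: UnitCell, path) -> None:
    lat = " ".join(f"{v:.6f}" for v in cell.lattice_vectors.ravel())
    org = " ".join(f"{v:.6f}" for v in cell.origin)
    sizes = {mid: len(cell.topology.indices(molecule_id=mid))
             for mid in cell.topology.molecule_ids()}
    msize = next(iter(sizes.values())) if len(set(sizes.values())) == 1 else 1
    with open(path, "w") as fh:
        fh.write(f"{cell.topology.n_atoms}\n")
        fh.write(f'Lattice="{lat}" Origin="{org}" mol_size={msize}\n')
        for a, (x, y, z) in zip(cell.topology.atoms, cell.coordinates):
            fh.write(f"{a.element} {x:.6f} {y:.6f} {z:.6f}\n")


def write_point_charges(atoms: Sequence[AtomRecord], coordinates, path) -> None:
    """Write ``x y z q`` lines (Å, e) for electrostatic embedding.

    ``atoms`` may also be a plain sequence of charges.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    charges = np.array(
        [a.charge if isinstance(a, AtomRecord) else float(a) for a in atoms],
        dtype=float,
    )
    if coordinates.shape != (len(charges), 3):
        raise TopologyError("coordinates do not match the atom list")
    if not (np.all(np.isfinite(charges)) and np.all(np.isfinite(coordinates))):
        raise GeometryError("non-finite charge or coordinate in point-charge export")
    with open(path, "w") as fh:
        for (x, y, z), q in zip(coordinates, charges):
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {q:.6f}\n")


def read_point_charges(path) -> tuple[np.ndarray, np.ndarray]:
    """Read ``x y z q`` lines → (coordinates (n,3), charges (n,))."""
    rows = []
    for ln in Path(path).read_text().splitlines():
        if ln.strip():
            rows.append([float(v) for v in ln.split()])
    if not rows:
        return np.empty((0, 3)), np.empty(0)
    arr = np.asarray(rows, dtype=float)
    return arr[:, :3], arr[:, 3]


def read_topology(path) -> Topology:
    """Read a topology from YAML (list of per-atom mappings)."""
    data = yaml.safe_load(Path(path).read_text())
    if isinstance(data, dict) and "atoms" in data:
        data = data["atoms"]
    atoms = []
    for rec in data:
        radius = rec.get("vdw_radius")
        if radius is None:
            radius = 0.0 if rec["role"] == "virtual_site" else BONDI_RADII.get(rec["element"], 1.5)
        atoms.append(
            AtomRecord(
                name=str(rec["name"]),
                element=str(rec["element"]),
                molecule_id=int(rec["molecule_id"]),
                role=str(rec["role"]),
                charge=float(rec.get("charge", 0.0)),
                vdw_radius=float(radius),
            )
        )
    return Topology(atoms)


def write_topology(topology: Topology, path) -> None:
    recs = [
        {
            "name": a.name,
            "element": a.element,
            "molecule_id": a.molecule_id,
            "role": a.role,
            "charge": float(a.charge),
            "vdw_radius": float(a.vdw_radius),
        }
        for a in topology.atoms
    ]
    Path(path).write_text(yaml.safe_dump({"atoms": recs}, sort_keys=False))
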
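"""Shared domain types: atoms, topologies, frames, trajectories, unit cells.

The whole workflow is non-periodic: coordinates are plain right-handed
Cartesian vectors in Å and no module ever wraps them back into a cell.
A :class:`UnitCell` appears only as the *input* to the solvation-sphere
builder, which replicates it into open space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "Molecule",
    "UnitCell",
    "CybospecError",
    "TopologyError",
    "GeometryError",
    "SelectionError",
    "AnalysisError",
    "make_lone_pair_sites",
]

ROLES = ("solute", "solvent", "virtual_site")


class CybospecError(Exception):
    """Base class for all package errors."""


class TopologyError(CybospecError):
    """Atom bookkeeping does not match between inputs."""


class GeometryError(CybospecError):
    """Degenerate or unphysical geometry."""


class SelectionError(CybospecError):
    """An atom selection could not be resolved."""


class AnalysisError(CybospecError):
    """An analysis has no well-defined answer on this input."""


@dataclass(frozen=True)
class AtomRecord:
    """One interaction site: a physical atom or a massless virtual site.

    Parameters
    ----------
    name:
        Site label, e.g. ``"O1"`` or ``"LP1"``.
    element:
        Element symbol; virtual sites use ``"X"``.
    molecule_id:
        Integer grouping atoms into rigid molecules.
    role:
        One of ``"solute"``, ``"solvent"``, ``"virtual_site"``.
    charge:
        Partial charge in elementary charges.
    vdw_radius:
        van der Waals radius in Å; ``0.0`` for virtual sites.
    """

    name: str
    element: str
    molecule_id: int
    role: str
    charge: float = 0.0
    vdw_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TopologyError(f"unknown role {self.role!r} for atom {self.name!r}")
        if self.role != "virtual_site" and self.vdw_radius <= 0.0:
            raise TopologyError(
                f"physical atom {self.name!r} needs a positive vdW radius, got {self.vdw_radius}"
            )
        if self.role == "virtual_site" and self.vdw_radius != 0.0:
            raise TopologyError(f"virtual site {self.name!r} must have zero vdW radius")
        if not np.isfinite(self.charge):
            raise TopologyError(f"non-finite charge on atom {self.name!r}")


#: Bondi van der Waals radii (Å) used as defaults when a topology file
#: does not override them.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "S": 1.80,
    "Cl": 1.75,
    "P": 1.80,
}

#: Standard atomic masses (g/mol) for the elements the generators use.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "X": 0.0,
}


@dataclass
class Topology:
    """Ordered list of :class:`AtomRecord` defining a system."""

    atoms: list[AtomRecord]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def indices(self, *, role: str | None = None, element: str | None = None,
                name: str | None = None, molecule_id: int | None = None) -> np.ndarray:
        """Indices of atoms matching every given criterion."""
        out = []
        for i, a in enumerate(self.atoms):
            if role is not None and a.role != role:
                continue
            if element is not None and a.element != element:
                continue
            if name is not None and a.name != name:
                continue
            if molecule_id is not None and a.molecule_id != molecule_id:
                continue
            out.append(i)
        return np.asarray(out, dtype=int)

    def index_of(self, name: str) -> int:
        """Index of the unique atom with this name."""
        idx = self.indices(name=name)
        if len(idx) != 1:
            raise SelectionError(f"name {name!r} matches {len(idx)} atoms, need exactly 1")
        return int(idx[0])

    def molecule_ids(self) -> list[int]:
        """Distinct molecule ids in first-appearance order."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.molecule_id, None)
        return list(seen)


@dataclass
class Frame:
    """Time-stamped coordinate set matching a topology's atom order."""

    time: float  # ps
    coordinates: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise GeometryError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise GeometryError("frame contains non-finite coordinates")


@dataclass
class Trajectory:
    """Topology plus an ordered list of frames with strictly increasing times."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        for k, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != self.topology.n_atoms:
                raise TopologyError(
                    f"frame {k} has {fr.coordinates.shape[0]} atoms, "
                    f"topology has {self.topology.n_atoms}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise GeometryError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames], dtype=float)

    @property
    def stride(self) -> float:
        """Median spacing between consecutive frame times (ps)."""
        t = self.times
        if len(t) < 2:
            return 0.0
        return float(np.median(np.diff(t)))

    def coordinate_stack(self) -> np.ndarray:
        """All coordinates as one (n_frames, n_atoms, 3) array."""
        return np.stack([fr.coordinates for fr in self.frames])


@dataclass
class Molecule:
    """A rigid group of atoms with coordinates, used by the sphere builder."""

    atoms: list[AtomRecord]
    coordinates: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.atoms) == 0:
            raise TopologyError("molecule must contain at least one atom")
        if self.coordinates.shape != (len(self.atoms), 3):
            raise TopologyError("molecule coordinates do not match atom count")

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted mean of the atomic positions."""
        return self.coordinates.mean(axis=0)

    def translated(self, shift: np.ndarray) -> "Molecule":
        return Molecule(self.atoms, self.coordinates + np.asarray(shift, dtype=float))

    def with_molecule_id(self, molecule_id: int) -> "Molecule":
        return Molecule(
            [replace(a, molecule_id=molecule_id) for a in self.atoms],
            self.coordinates.copy(),
        )


@dataclass
class UnitCell:
    """Solvent repeating cell: origin, three lattice vectors, contents.

    The lattice vectors are generally non-orthogonal; the only
    requirement is a nonzero cell volume.
    """

    origin: np.ndarray  # (3,) Å
    lattice_vectors: np.ndarray  # (3, 3) Å, rows are the cell vectors
    topology: Topology
    coordinates: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.lattice_vectors = np.asarray(self.lattice_vectors, dtype=float).reshape(3, 3)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if abs(self.volume) < 1e-9:
            raise GeometryError("unit cell has (near-)zero volume")
        if self.coordinates.shape != (self.topology.n_atoms, 3):
            raise TopologyError("cell coordinates do not match topology atom count")

    @property
    def volume(self) -> float:
        """Signed cell volume in Å³."""
        return float(np.linalg.det(self.lattice_vectors))

    def molecules(self) -> list[Molecule]:
        """Split the cell contents into whole molecules by molecule_id."""
        out = []
        for mid in self.topology.molecule_ids():
            idx = self.topology.indices(molecule_id=mid)
            out.append(Molecule([self.topology.atoms[i] for i in idx],
                                self.coordinates[idx]))
        return out


def make_lone_pair_sites(
    o_pos: np.ndarray,
    n_pos: np.ndarray,
    c_positions: Sequence[np.ndarray],
    *,
    distance: float = 0.3,
    half_angle_deg: float = 45.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Place two lone-pair virtual sites on a nitroxide oxygen.

    The sites sit at ``distance`` Å from O, in the plane that bisects
    the C–N–C framework (i.e. perpendicular to the C···C direction),
    symmetric about the N→O axis at ``half_angle_deg`` on either side.

    Parameters
    ----------
    o_pos, n_pos:
        Oxygen and nitrogen positions (Å).
    c_positions:
        The two ring-carbon positions bonded to N, defining the local frame.
    """
    o_pos = np.asarray(o_pos, dtype=float)
    n_pos = np.asarray(n_pos, dtype=float)
    axis = o_pos - n_pos
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise GeometryError("N and O coincide; cannot orient lone pairs")
    axis = axis / norm
    c1, c2 = (np.asarray(c, dtype=float) for c in c_positions)
    cc = c2 - c1
    # in-plane direction: component of the C->C vector orthogonal to N-O,
    # falling back to an arbitrary perpendicular for degenerate input
    perp = cc - np.dot(cc, axis) * axis
    if np.linalg.norm(perp) < 1e-8:
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, axis)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        perp = trial - np.dot(trial, axis) * axis
    # lone pairs live in the plane bisecting C-N-C: spanned by the N-O
    # axis and the normal to the C..C direction within that plane
    normal = np.cross(axis, perp)
    normal /= np.linalg.norm(normal)
    half = np.deg2rad(half_angle_deg)
    lp1 = o_pos + distance * (np.cos(half) * axis + np.sin(half) * normal)
    lp2 = o_pos + distance * (np.cos(half) * axis - np.sin(half) * normal)
    return lp1, lp2
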
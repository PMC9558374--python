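"""Synthetic fixtures with planted ground truth.

Every analysis stage of the workflow is testable without external data
through three seeded generators:

* :func:`gen_trajectory` — rigid nitroxide-like solute at the origin,
  solvent molecules placed frame by frame according to hydrogen-bond
  *regimes* (0, 1 or 2 planted donors at sampled distance/angle around
  the oxygen lone pairs, the rest uniform bulk), with the regime label
  of every frame returned as ground truth;
* :func:`gen_qm_reference` — physically consistent random reference
  eigenstate data (ascending energies with a visible-band first gap,
  symmetric transition charges obeying the diagonal sum rule, random
  transition dipoles);
* :func:`gen_solvent_cell` — non-overlapping random packing of a rigid
  solvent molecule at a target mass density.

All generators are pure functions of their seed. Geometry only: no
force-field energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ATOMIC_MASSES,
    AtomRecord,
    CybospecError,
    Frame,
    GeometryError,
    Molecule,
    Topology,
    Trajectory,
    UnitCell,
    make_lone_pair_sites,
)
from .pmm import QMReference

__all__ = [
    "Regime",
    "RegimeSpec",
    "nitroxide_fragment",
    "water_template",
    "methanol_template",
    "gen_trajectory",
    "gen_qm_reference",
    "gen_solvent_cell",
]

AVOGADRO = 6.02214076e23

_OH_BOND = 0.96  # Å, hydroxyl bond length used by the solvent templates


@dataclass(frozen=True)
class Regime:
    """One planted solvation regime.

    hb_count — number of simultaneously hydrogen-bonded donors (0–2);
    r_mean/r_sd — donor-H···O distance distribution (Å);
    angle_sd — angular jitter of the donor geometry (degrees, sd of a
    half-normal);
    dwell — fraction of the trajectory spent in this regime.
    """

    hb_count: int
    dwell: float
    r_mean: float = 1.85
    r_sd: float = 0.02
    angle_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.hb_count not in (0, 1, 2):
            raise CybospecError("hb_count must be 0, 1 or 2")
        if self.dwell <= 0:
            raise CybospecError("dwell fraction must be positive")


@dataclass(frozen=True)
class RegimeSpec:
    """Planted-regime trajectory recipe."""

    regimes: tuple[Regime, ...]
    n_frames: int = 100
    seed: int = 0
    sphere_radius: float = 12.0
    n_bulk: int = 12
    dt_ps: float = 1.0
    bulk_min_radius: float = 4.5

    def __post_init__(self) -> None:
        if len(self.regimes) < 1:
            raise CybospecError("need at least one regime")
        total = sum(r.dwell for r in self.regimes)
        if abs(total - 1.0) > 1e-6:
            raise CybospecError(f"dwell fractions must sum to 1, got {total}")


def nitroxide_fragment() -> Molecule:
    """Minimal rigid nitroxide-like solute: C–N(–C)–O plus two lone-pair
    virtual sites on the oxygen; charges sum to zero."""
    n_pos = np.zeros(3)
    o_pos = np.array([0.0, 0.0, 1.28])
    c1 = np.array([1.24, 0.0, -0.62])
    c2 = np.array([-1.24, 0.0, -0.62])
    lp1, lp2 = make_lone_pair_sites(o_pos, n_pos, (c1, c2))
    atoms = [
        AtomRecord("C1", "C", 0, "solute", 0.10, 1.70),
        AtomRecord("N", "N", 0, "solute", 0.15, 1.55),
        AtomRecord("C2", "C", 0, "solute", 0.10, 1.70),
        AtomRecord("O", "O", 0, "solute", -0.11, 1.52),
        AtomRecord("LP1", "X", 0, "virtual_site", -0.12, 0.0),
        AtomRecord("LP2", "X", 0, "virtual_site", -0.12, 0.0),
    ]
    coords = np.vstack([c1, n_pos, c2, o_pos, lp1, lp2])
    return Molecule(atoms, coords)


def water_template() -> Molecule:
    """3-site rigid water-like molecule; first atom O, then the two H.
    TIP3P-like geometry and charges (sum 0)."""
    atoms = [
        AtomRecord("OW", "O", 0, "solvent", -0.834, 1.52),
        AtomRecord("HW1", "H", 0, "solvent", 0.417, 1.20),
        AtomRecord("HW2", "H", 0, "solvent", 0.417, 1.20),
    ]
    ang = np.deg2rad(104.52)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [_OH_BOND, 0.0, 0.0],
            [_OH_BOND * np.cos(ang), _OH_BOND * np.sin(ang), 0.0],
        ]
    )
    return Molecule(atoms, coords)


def methanol_template() -> Molecule:
    """6-site rigid methanol-like molecule; hydroxyl O first, then its
    H, then the methyl group; charges sum to zero."""
    atoms = [
        AtomRecord("OH", "O", 0, "solvent", -0.65, 1.52),
        AtomRecord("HO", "H", 0, "solvent", 0.42, 1.20),
        AtomRecord("CM", "C", 0, "solvent", 0.14, 1.70),
        AtomRecord("HM1", "H", 0, "solvent", 0.03, 1.20),
        AtomRecord("HM2", "H", 0, "solvent", 0.03, 1.20),
        AtomRecord("HM3", "H", 0, "solvent", 0.03, 1.20),
    ]
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [_OH_BOND, 0.0, 0.0],
            [-0.70, 1.24, 0.0],
            [-1.76, 1.10, 0.2],
            [-0.55, 1.80, -0.9],
            [-0.30, 1.80, 0.85],
        ]
    )
    return Molecule(atoms, coords)


def molar_mass(mol: Molecule) -> float:
    return sum(ATOMIC_MASSES.get(a.element, 0.0) for a in mol.atoms)


# ------------------------------------------------------------ geometry

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _place_donor(
    template: Molecule,
    acceptor_pos: np.ndarray,
    direction: np.ndarray,
    R: float,
    theta_deg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place a donor molecule so its hydroxyl realises exactly (R, ϑ).

    R is the H···acceptor distance and ϑ the angle at the donor O
    between its H and the acceptor. The donor O sits along
    ``direction`` from the acceptor; the molecule is randomly rolled
    about its O–H axis.
    """
    u = direction / np.linalg.norm(direction)
    theta = np.deg2rad(theta_deg)
    # donor O distance L solving the (R, theta, r_OH) triangle
    disc = R * R - (_OH_BOND * np.sin(theta)) ** 2
    if disc <= 0:
        raise GeometryError("infeasible donor geometry (R too short for the angle)")
    L = _OH_BOND * np.cos(theta) + np.sqrt(disc)
    o_pos = acceptor_pos + L * u
    w = (acceptor_pos - o_pos) / L  # O_s -> acceptor direction
    # perpendicular for the angular deviation, random azimuth
    perp = np.cross(w, rng.normal(size=3))
    while np.linalg.norm(perp) < 1e-8:
        perp = np.cross(w, rng.normal(size=3))
    perp /= np.linalg.norm(perp)
    h_dir = np.cos(theta) * w + np.sin(theta) * perp
    h_pos = o_pos + _OH_BOND * h_dir

    # map the template: O at index 0, hydroxyl H at index 1
    t = template.coordinates - template.coordinates[0]
    rot1 = _rotation_between(t[1], h_dir)
    coords = (rot1 @ t.T).T
    roll = _axis_angle(h_dir, float(rng.uniform(0, 2 * np.pi)))
    coords = (roll @ coords.T).T + o_pos
    return coords


def _place_bulk(
    template: Molecule,
    occupied: list[np.ndarray],
    rng: np.random.Generator,
    r_lo: float,
    r_hi: float,
    min_dist: float = 2.0,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Uniform random placement in the shell [r_lo, r_hi], rejecting
    positions within ``min_dist`` Å of anything already placed."""
    t = template.coordinates - template.centroid
    for _ in range(max_attempts):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = (rng.uniform(r_lo**3, r_hi**3)) ** (1.0 / 3.0)
        center = r * direction
        coords = (_random_rotation(rng) @ t.T).T + center
        ok = True
        for other in occupied:
            d = np.linalg.norm(coords[:, None, :] - other[None, :, :], axis=2)
            if d.min() < min_dist:
                ok = False
                break
        if ok:
            return coords
    raise GeometryError(f"bulk placement failed after {max_attempts} attempts")


def gen_trajectory(
    solute_template: Molecule | None,
    solvent_template: Molecule | None,
    spec: RegimeSpec,
) -> tuple[Trajectory, np.ndarray]:
    """Planted-regime trajectory with per-frame ground-truth labels.

    The solute sits rigidly at the origin. Frames are split into
    contiguous blocks proportional to the regime dwell fractions; in
    each frame the active regime's donors are placed at sampled (R, ϑ)
    along the oxygen lone-pair directions and the remaining solvent
    molecules are placed uniformly in the bulk shell. The solvent
    molecule count is constant across frames (donors of inactive
    regimes become bulk), so all frames share one topology.

    Returns (trajectory, labels) with ``labels[k]`` the regime index of
    frame k.
    """
    solute = solute_template or nitroxide_fragment()
    solvent = solvent_template or water_template()
    rng = np.random.default_rng(spec.seed)

    max_hb = max(r.hb_count for r in spec.regimes)
    n_solvent = spec.n_bulk + max_hb

    atoms = [a for a in solute.atoms]
    for m in range(n_solvent):
        for a in solvent.atoms:
            atoms.append(
                AtomRecord(f"{a.name}_{m + 1}", a.element, m + 1, "solvent",
                           a.charge, a.vdw_radius)
            )
    topology = Topology(atoms)

    # regime boundaries: contiguous blocks proportional to dwell
    bounds = np.cumsum([r.dwell for r in spec.regimes])
    edges = np.minimum((bounds * spec.n_frames).round().astype(int), spec.n_frames)
    labels = np.zeros(spec.n_frames, dtype=int)
    start = 0
    for i, e in enumerate(edges):
        labels[start:e] = i
        start = e

    o_idx = next(i for i, a in enumerate(solute.atoms) if a.name == "O")
    lp_idx = [i for i, a in enumerate(solute.atoms) if a.role == "virtual_site"]
    o_pos = solute.coordinates[o_idx]
    lp_dirs = [
        (solute.coordinates[i] - o_pos) / np.linalg.norm(solute.coordinates[i] - o_pos)
        for i in lp_idx
    ]

    frames: list[Frame] = []
    for k in range(spec.n_frames):
        regime = spec.regimes[labels[k]]
        occupied = [solute.coordinates]
        placed: list[np.ndarray] = []
        for d in range(regime.hb_count):
            R = -1.0
            while R <= 0.5:
                R = rng.normal(regime.r_mean, regime.r_sd)
            theta = abs(rng.normal(0.0, regime.angle_sd))
            coords = _place_donor(solvent, o_pos, lp_dirs[d % len(lp_dirs)],
                                  R, theta, rng)
            placed.append(coords)
            occupied.append(coords)
        while len(placed) < n_solvent:
            coords = _place_bulk(solvent, occupied, rng,
                                 spec.bulk_min_radius, spec.sphere_radius)
            placed.append(coords)
            occupied.append(coords)
        frames.append(
            Frame(time=k * spec.dt_ps,
                  coordinates=np.vstack([solute.coordinates, *placed]))
        )
    return Trajectory(topology=topology, frames=frames), labels


def gen_qm_reference(
    n_states: int = 11,
    n_atoms: int = 6,
    coupling_scale: float = 0.05,
    seed: int = 0,
    total_charge: float = 0.0,
    first_gap: float = 0.10,
) -> QMReference:
    """Random but physically consistent PMM reference data.

    Energies ascend with a first excitation near ``first_gap`` hartree
    (a visible band) and slowly widening gaps; transition charges are
    symmetric with the diagonal sum rule enforced exactly; transition
    dipoles from the ground state are random unit-scale vectors.
    """
    if n_states < 2:
        raise CybospecError("need at least 2 states")
    rng = np.random.default_rng(seed)
    gaps = first_gap * (1.0 + 0.3 * np.arange(n_states - 1)) \
        * (1.0 + 0.05 * rng.uniform(-1, 1, n_states - 1))
    energies = np.concatenate([[0.0], np.cumsum(gaps)])

    q = rng.normal(0.0, coupling_scale, size=(n_states, n_states, n_atoms))
    q = 0.5 * (q + q.transpose(1, 0, 2))
    for i in range(n_states):
        q[i, i] += (total_charge - q[i, i].sum()) / n_atoms

    mu = np.zeros((n_states, n_states, 3))
    for j in range(1, n_states):
        vec = rng.normal(0.0, 0.5, size=3)
        mu[0, j] = vec
        mu[j, 0] = vec

    vref = rng.normal(0.0, 0.01, size=n_atoms)
    return QMReference(
        energies=energies,
        transition_charges=q,
        transition_dipoles=mu,
        reference_potentials=vref,
        total_charge=total_charge,
    )


def gen_solvent_cell(
    molecule_template: Molecule,
    density: float,
    cell_edge: float,
    seed: int = 0,
    min_dist: float = 2.0,
    max_attempts: int = 2000,
) -> UnitCell:
    """Random non-overlapping packing of a rigid molecule in a cube.

    ``density`` in g/cm³; the molecule count is round(ρ_N · V) with
    ρ_N the implied number density. Raises a generation error when the
    rejection packing cannot reach that count.
    """
    if density < 0:
        raise CybospecError("density must be non-negative")
    mass = molar_mass(molecule_template)
    rho_n = density * AVOGADRO / mass / 1.0e24  # Å⁻³
    count = int(round(rho_n * cell_edge**3))
    rng = np.random.default_rng(seed)
    t = molecule_template.coordinates - molecule_template.centroid

    placed_coords: list[np.ndarray] = []
    atoms: list[AtomRecord] = []
    for m in range(count):
        ok = False
        for _ in range(max_attempts):
            center = rng.uniform(0.0, cell_edge, size=3)
            coords = (_random_rotation(rng) @ t.T).T + center
            ok = True
            for other in placed_coords:
                d = np.linalg.norm(coords[:, None, :] - other[None, :, :], axis=2)
                if d.min() < min_dist:
                    ok = False
                    break
            if ok:
                break
        if not ok:
            raise GeometryError(
                f"packing failed at molecule {m + 1}/{count} "
                f"(density {density} g/cm³ too high for min_dist {min_dist} Å)"
            )
        placed_coords.append(coords)
        for a in molecule_template.atoms:
            atoms.append(AtomRecord(f"{a.name}_{m}", a.element, m, "solvent",
                                    a.charge, a.vdw_radius))

    coords_all = np.vstack(placed_coords) if placed_coords else np.empty((0, 3))
    if not atoms:
        # an empty cell still needs a valid (empty) topology
        return UnitCell(
            origin=np.zeros(3),
            lattice_vectors=np.eye(3) * cell_edge,
            topology=Topology([]),
            coordinates=np.empty((0, 3)),
        )
    return UnitCell(
        origin=np.zeros(3),
        lattice_vectors=np.eye(3) * cell_edge,
        topology=Topology(atoms),
        coordinates=coords_all,
    )
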
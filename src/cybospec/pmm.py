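"""Perturbed Matrix Method: solvent-perturbed excitation energies.

The solute's electronic problem is solved once (externally, by TD-DFT)
for a reference solvent configuration, yielding the first n eigenstates
(default 11: ground + 10 excited), their energies E_i, the atomic
transition charges q_a^{ij}, and the transition dipoles μ_{0j}. For any
other solvent configuration, the perturbed Hamiltonian in that basis is

    H̃_ij = E_i δ_ij + Σ_a q_a^{ij} (V(r_a) − V_ref(r_a)),

where V(r_a) is the solvent electrostatic potential at solute atom a.
Diagonalising H̃ gives perturbed excitation energies; rotating the
dipole matrix into the perturbed eigenbasis gives oscillator strengths.
Everything is in atomic units internally (hartree, bohr, e).

This is a first-order atom-site expansion: the perturbation couples
states only through the transition charges times potential differences.
Higher multipole corrections can be added in
:func:`build_perturbed_hamiltonian` without touching the rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import CybospecError, GeometryError
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "QMReference",
    "PerturbedResult",
    "site_potentials",
    "build_perturbed_hamiltonian",
    "diagonalize_pmm",
    "read_qm_reference",
    "write_qm_reference",
]


@dataclass
class QMReference:
    """Reference electronic-structure data defining the PMM basis.

    energies — per-state energies in hartree, ascending;
    transition_charges — q[i, j, a] in e, symmetric in (i, j);
    transition_dipoles — μ[i, j] vectors in a.u. (entries not supplied
    by the reference computation are zero);
    reference_potentials — V_ref at each solute atom (hartree/e);
    total_charge — Σ_a q[i, i, a] for every state (diagonal sum rule).
    """

    energies: np.ndarray
    transition_charges: np.ndarray
    transition_dipoles: np.ndarray
    reference_potentials: np.ndarray
    total_charge: float = 0.0

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.transition_charges = np.asarray(self.transition_charges, dtype=float)
        self.transition_dipoles = np.asarray(self.transition_dipoles, dtype=float)
        self.reference_potentials = np.asarray(self.reference_potentials, dtype=float)
        n = self.n_states
        if self.transition_charges.shape[:2] != (n, n):
            raise CybospecError("transition charge tensor must be (n_states, n_states, n_atoms)")
        if self.transition_dipoles.shape != (n, n, 3):
            raise CybospecError("dipole tensor must be (n_states, n_states, 3)")
        if self.reference_potentials.shape != (self.n_atoms,):
            raise CybospecError("reference potentials must have one entry per solute atom")
        if np.any(np.diff(self.energies) < -1e-12):
            raise CybospecError("reference energies must be ascending")
        if not np.allclose(self.transition_charges,
                           self.transition_charges.transpose(1, 0, 2), atol=1e-8):
            raise CybospecError("transition charges must be symmetric in the state pair")
        diag_sums = self.transition_charges[np.arange(n), np.arange(n)].sum(axis=1)
        if not np.allclose(diag_sums, self.total_charge, atol=1e-6):
            raise CybospecError(
                "diagonal transition charges must sum to the total molecular charge"
            )

    @property
    def n_states(self) -> int:
        return len(self.energies)

    @property
    def n_atoms(self) -> int:
        return self.transition_charges.shape[2]


@dataclass
class PerturbedResult:
    hamiltonian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    excitation_energies: np.ndarray   # hartree, E_k − E_0, k ≥ 1
    rotated_dipoles: np.ndarray       # μ̃[0, k] vectors, a.u.
    oscillator_strengths: np.ndarray  # f_k, dimensionless


def site_potentials(charge_coordinates, charges, solute_coordinates,
                    min_distance: float = 0.1) -> np.ndarray:
    """Coulomb potential (hartree/e) of point charges at solute sites.

    V(r_a) = Σ_s q_s / |r_a − r_s| in atomic units; input coordinates
    are Å and converted to bohr once. A charge within ``min_distance``
    Å of a solute site raises a singularity error naming the pair.
    """
    pos_s = np.asarray(charge_coordinates, dtype=float).reshape(-1, 3)
    q = np.asarray(charges, dtype=float).ravel()
    pos_a = np.asarray(solute_coordinates, dtype=float).reshape(-1, 3)
    if len(q) != len(pos_s):
        raise CybospecError("charge array does not match charge coordinates")
    if len(pos_s) == 0:
        return np.zeros(len(pos_a))
    diff = pos_a[:, None, :] - pos_s[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    if dist.min() <= min_distance:
        a, s = np.unravel_index(np.argmin(dist), dist.shape)
        raise GeometryError(
            f"charge site {s} within {min_distance} Å of solute site {a} "
            f"(d = {dist[a, s]:.4f} Å)"
        )
    return (q[None, :] / (dist * BOHR_PER_ANGSTROM)).sum(axis=1)


def build_perturbed_hamiltonian(ref: QMReference, current_potentials) -> np.ndarray:
    """H̃ = diag(E) + Σ_a q[:, :, a] ΔV_a with ΔV = V_current − V_ref."""
    V = np.asarray(current_potentials, dtype=float).ravel()
    if V.shape != ref.reference_potentials.shape:
        raise CybospecError(
            f"potential vector has {V.shape[0]} entries, reference has "
            f"{ref.reference_potentials.shape[0]} solute atoms"
        )
    dV = V - ref.reference_potentials
    H = np.diag(ref.energies) + np.einsum("ija,a->ij", ref.transition_charges, dV)
    return 0.5 * (H + H.T)  # exact symmetrisation against roundoff


def diagonalize_pmm(H: np.ndarray, ref: QMReference) -> PerturbedResult:
    """Diagonalise the perturbed Hamiltonian and rotate the dipoles.

    Excitation energies are differences of sorted eigenvalues; the
    perturbed transition dipoles are μ̃[0, k] = Σ_ij c_i⁰ c_j^k μ[i, j]
    and the oscillator strengths f_k = (2/3) ΔE_k |μ̃[0, k]|² (a.u.).
    """
    H = np.asarray(H, dtype=float)
    if not np.allclose(H, H.T, atol=1e-10):
        raise CybospecError("perturbed Hamiltonian must be symmetric")
    evals, evecs = np.linalg.eigh(H)
    dE = evals[1:] - evals[0]
    c0 = evecs[:, 0]
    rotated = np.einsum("i,ijx,jk->kx", c0, ref.transition_dipoles, evecs[:, 1:])
    f = (2.0 / 3.0) * dE * np.einsum("kx,kx->k", rotated, rotated)
    return PerturbedResult(
        hamiltonian=H,
        eigenvalues=evals,
        eigenvectors=evecs,
        excitation_energies=dE,
        rotated_dipoles=rotated,
        oscillator_strengths=f,
    )


# ---------------------------------------------------------------- I/O

def write_qm_reference(ref: QMReference, path) -> None:
    """Structured-text serialisation of a :class:`QMReference`.

    Key-value header (n_states, n_atoms, total_charge) followed by
    ENERGIES, TRANSITION_CHARGES (``i j a q``, upper triangle),
    DIPOLES (``i j x y z``, nonzero entries with i ≤ j) and
    REF_POTENTIALS blocks.
    """
    n, na = ref.n_states, ref.n_atoms
    with open(path, "w") as fh:
        fh.write(f"n_states {n}\nn_atoms {na}\ntotal_charge {ref.total_charge:.10f}\n")
        fh.write("ENERGIES\n")
        for e in ref.energies:
            fh.write(f"{e:.12f}\n")
        fh.write("TRANSITION_CHARGES\n")
        for i in range(n):
            for j in range(i, n):
                for a in range(na):
                    q = ref.transition_charges[i, j, a]
                    if q != 0.0:
                        fh.write(f"{i} {j} {a} {q:.12f}\n")
        fh.write("DIPOLES\n")
        for i in range(n):
            for j in range(i, n):
                mu = ref.transition_dipoles[i, j]
                if np.any(mu != 0.0):
                    fh.write(f"{i} {j} {mu[0]:.12f} {mu[1]:.12f} {mu[2]:.12f}\n")
        fh.write("REF_POTENTIALS\n")
        for v in ref.reference_potentials:
            fh.write(f"{v:.12f}\n")


def read_qm_reference(path) -> QMReference:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header: dict[str, float] = {}
    pos = 0
    while pos < len(lines) and lines[pos] != "ENERGIES":
        key, val = lines[pos].split()
        header[key] = float(val)
        pos += 1
    n = int(header["n_states"])
    na = int(header["n_atoms"])
    total_charge = header.get("total_charge", 0.0)

    def block(name: str, start: int) -> tuple[list[str], int]:
        if lines[start] != name:
            raise CybospecError(f"expected {name} block at line {start}")
        out = []
        i = start + 1
        while i < len(lines) and not lines[i].isupper():
            out.append(lines[i])
            i += 1
        return out, i

    e_lines, pos = block("ENERGIES", pos)
    energies = np.array([float(v) for v in e_lines])
    q_lines, pos = block("TRANSITION_CHARGES", pos)
    q = np.zeros((n, n, na))
    for ln in q_lines:
        i, j, a, val = ln.split()
        q[int(i), int(j), int(a)] = float(val)
        q[int(j), int(i), int(a)] = float(val)
    d_lines, pos = block("DIPOLES", pos)
    mu = np.zeros((n, n, 3))
    for ln in d_lines:
        i, j, x, y, z = ln.split()
        vec = [float(x), float(y), float(z)]
        mu[int(i), int(j)] = vec
        mu[int(j), int(i)] = vec
    v_lines, pos = block("REF_POTENTIALS", pos)
    vref = np.array([float(v) for v in v_lines])
    return QMReference(
        energies=energies,
        transition_charges=q,
        transition_dipoles=mu,
        reference_potentials=vref,
        total_charge=total_charge,
    )
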
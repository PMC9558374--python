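"""Representative-frame selection and collective frames.

A total frame budget is split among clusters proportionally to their
sizes (largest-remainder apportionment). Within each cluster, a GRASP
metaheuristic — multi-start greedy randomized construction with a
restricted candidate list, followed by swap local search — picks the
subset of frames whose mean feature vector best matches the cluster
mean. The selected frames are merged into a
*collective frame*: all their solvent atoms as point charges scaled by
1/N, whose electrostatic potential at any solute site is exactly the
average of the per-frame potentials.
"""

from __future__ import annotations

import itertools

from dataclasses import dataclass

import numpy as np

from .core import CybospecError, Frame, Topology, TopologyError

__all__ = [
    "GraspSelection",
    "CollectiveFrame",
    "allocate_frames",
    "grasp_select",
    "build_collective_frame",
]


@dataclass
class GraspSelection:
    per_cluster_counts: list[int]
    per_cluster_frames: list[np.ndarray]
    objective_values: list[float]
    seed: int
    alpha: float


@dataclass
class CollectiveFrame:
    """Rigid solute + union of solvent point charges from N frames.

    Every source solvent charge is scaled by exactly 1/N, so the
    Coulomb potential of the collective frame at any point equals the
    arithmetic mean of the per-frame potentials (linearity).
    """

    solute_coordinates: np.ndarray
    solute_charges: np.ndarray
    solvent_coordinates: np.ndarray
    solvent_charges: np.ndarray
    n_source_frames: int


def allocate_frames(cluster_sizes, budget: int) -> list[int]:
    """Largest-remainder (Hamilton) apportionment of the frame budget.

    Each cluster receives floor(budget·size/total) frames; leftover
    frames go to the largest fractional remainders (ties: larger
    cluster first, then lower index). Every cluster is guaranteed at
    least one frame, which requires budget ≥ number of clusters.
    """
    sizes = [int(s) for s in cluster_sizes]
    if any(s <= 0 for s in sizes):
        raise CybospecError("cluster sizes must be positive")
    n = len(sizes)
    if budget < n:
        raise CybospecError(f"budget {budget} below the number of clusters {n}")
    total = sum(sizes)
    quotas = [budget * s / total for s in sizes]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = budget - sum(counts)
    order = sorted(range(n), key=lambda i: (-(quotas[i] - counts[i]), -sizes[i], i))
    for i in order[:remainder]:
        counts[i] += 1
    # guarantee >= 1: take from the currently largest allocation
    for i in range(n):
        while counts[i] == 0:
            j = int(np.argmax(counts))
            counts[j] -= 1
            counts[i] += 1
    return counts


def _objective(sum_sel: np.ndarray, n_sel: int, target: np.ndarray) -> float:
    diff = sum_sel / n_sel - target
    return float(diff @ diff)


def grasp_select(
    cluster_frames: np.ndarray,
    n: int,
    alpha: float = 0.3,
    n_restarts: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """GRASP subset selection minimising the mean-feature mismatch.

    Objective: J(S) = ‖mean_{f∈S} φ(f) − mean_cluster φ‖² over subsets
    of size ``n`` of the cluster's feature vectors φ. Each restart runs
    a greedy randomized construction — at every step the candidate is
    drawn uniformly from the restricted candidate list of the
    ⌈alpha·(#remaining candidates)⌉ frames with the best marginal
    objective — followed by swap local search (single exchanges, plus a
    bounded 2-exchange pass once single swaps are exhausted, since some
    optima are not reachable one swap at a time). The best restart
    wins. ``alpha = 0`` collapses the RCL to pure greedy.

    Returns (selected indices into ``cluster_frames``, J).
    """
    X = np.asarray(cluster_frames, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    m = X.shape[0]
    if not 1 <= n <= m:
        raise CybospecError(f"cannot select {n} frames from a cluster of {m}")
    if not 0.0 <= alpha <= 1.0:
        raise CybospecError(f"alpha must be in [0, 1], got {alpha}")
    target = X.mean(axis=0)
    root = np.random.default_rng(seed)
    streams = root.spawn(max(1, n_restarts))

    best_sel: np.ndarray | None = None
    best_J = np.inf
    for rng in streams[: max(1, n_restarts)]:
        # construction
        selected: list[int] = []
        sum_sel = np.zeros(X.shape[1])
        remaining = list(range(m))
        while len(selected) < n:
            trial = (sum_sel[None, :] + X[remaining]) / (len(selected) + 1) - target
            J_cand = np.einsum("ij,ij->i", trial, trial)
            order = np.argsort(J_cand, kind="stable")
            rcl = max(1, int(np.ceil(alpha * len(remaining))))
            pick_pos = order[int(rng.integers(rcl))] if rcl > 1 else order[0]
            pick = remaining.pop(int(pick_pos))
            selected.append(pick)
            sum_sel += X[pick]
        J = _objective(sum_sel, n, target)

        # swap local search: apply the first improving exchange found,
        # rescanning until the subset is swap-optimal
        improved = True
        while improved:
            improved = False
            sel_set = set(selected)
            best_move = None
            J_move = J
            for si in range(len(selected)):
                out_i = selected[si]
                base = sum_sel - X[out_i]
                for j in range(m):
                    if j in sel_set:
                        continue
                    J_new = _objective(base + X[j], n, target)
                    if J_new < J_move - 1e-15:
                        J_move = J_new
                        best_move = (si, j, base + X[j])
            if best_move is not None:
                si, j, new_sum = best_move
                selected[si] = j
                sum_sel = new_sum
                J = J_move
                improved = True
                continue
            # single-swap optimum reached: try one bounded 2-exchange
            # pass (some optima are unreachable by single swaps)
            outside = [j for j in range(m) if j not in sel_set]
            n_pairs = (len(selected) * (len(selected) - 1) // 2) \
                * (len(outside) * (len(outside) - 1) // 2)
            if n_pairs == 0 or n_pairs > 200_000:
                continue
            for si, sj in itertools.combinations(range(len(selected)), 2):
                base = sum_sel - X[selected[si]] - X[selected[sj]]
                for oi, oj in itertools.combinations(outside, 2):
                    J_new = _objective(base + X[oi] + X[oj], n, target)
                    if J_new < J - 1e-15:
                        selected[si], selected[sj] = oi, oj
                        sum_sel = base + X[oi] + X[oj]
                        J = J_new
                        improved = True
                        break
                if improved:
                    break
        if J < best_J:
            best_J = J
            best_sel = np.array(sorted(selected), dtype=int)
    assert best_sel is not None
    return best_sel, best_J


def build_collective_frame(
    frames: list[Frame],
    topology: Topology,
    solute_reference: Frame,
) -> CollectiveFrame:
    """Merge the solvent of N frames into one 1/N-charge-scaled frame.

    The rigid solute (including its virtual sites) is taken once from
    the reference frame; the solvent atoms of every selected frame are
    concatenated with their charges divided by N.
    """
    if len(frames) == 0:
        raise CybospecError("need at least one frame")
    n_atoms = topology.n_atoms
    for k, fr in enumerate(frames):
        if fr.coordinates.shape[0] != n_atoms:
            raise TopologyError(f"frame {k} does not match the topology")
    if solute_reference.coordinates.shape[0] != n_atoms:
        raise TopologyError("solute reference frame does not match the topology")

    # the solute (plus its virtual sites) is whatever shares the first
    # atom's molecule id; classify by molecule, not by role, so that
    # solvent-attached virtual sites stay with their molecules
    solute_mol = topology.atoms[0].molecule_id
    solute_idx = [i for i, a in enumerate(topology.atoms) if a.molecule_id == solute_mol]
    solvent_idx = [i for i in range(n_atoms) if i not in set(solute_idx)]

    charges = topology.charges
    N = len(frames)
    solv_coords = np.vstack([fr.coordinates[solvent_idx] for fr in frames]) \
        if solvent_idx else np.empty((0, 3))
    solv_charges = np.concatenate([charges[solvent_idx] / N for _ in frames]) \
        if solvent_idx else np.empty(0)
    return CollectiveFrame(
        solute_coordinates=solute_reference.coordinates[solute_idx].copy(),
        solute_charges=charges[solute_idx].copy(),
        solvent_coordinates=solv_coords,
        solvent_charges=solv_charges,
        n_source_frames=N,
    )
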
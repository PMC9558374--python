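"""Solute–solvent structural analysis in finite spherical boxes.

Radial distribution functions, coordination numbers, and a continuous
hydrogen-bond perception score. Because the simulation sphere is
non-periodic, the RDF normalisation estimates the partner density from
a concentric sub-sphere (rather than a periodic-cell density), which
avoids the depletion bias near the rigid wall.

The hydrogen-bond score F_HB maps a donor geometry — the donor-H to
acceptor-O distance R and the angle ϑ at the donor oxygen between its
H and the acceptor — onto [0, 1]: 1 for an ideal short, linear bond,
decaying smoothly to 0 as the geometry degrades. Defaults follow the
empirical parameterisation R₀ = 1.85 Å, σ_R = 0.20 (fraction of R₀),
ϑ₀ = 0°, σ_ϑ = 10°, with scores below 1e-4 clamped to exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import (
    AnalysisError,
    CybospecError,
    SelectionError,
    Trajectory,
)

__all__ = [
    "RDFResult",
    "HBParams",
    "HBRecord",
    "compute_rdf",
    "coordination_number",
    "find_first_extremum",
    "f_hb",
    "hb_scan",
    "subsample",
]


@dataclass
class RDFResult:
    """Binned radial distribution function g(r).

    bin_centers in Å; g dimensionless; rho_B the partner number density
    (Å⁻³) used for normalisation; n_pairs_per_frame the raw mean pair
    count per bin.
    """

    bin_centers: np.ndarray
    g: np.ndarray
    rho_B: float
    n_pairs_per_frame: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass(frozen=True)
class HBParams:
    """Continuous hydrogen-bond score parameters.

    R0 (Å) and theta0 (deg) locate the ideal geometry; sigma_R
    (dimensionless, fraction of R0) and sigma_theta (deg) set the decay
    scales; scores below zero_floor are returned as exactly 0.
    """

    R0: float = 1.85
    sigma_R: float = 0.20
    theta0: float = 0.0
    sigma_theta: float = 10.0
    zero_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.sigma_R <= 0 or self.sigma_theta <= 0:
            raise CybospecError("sigma_R and sigma_theta must be positive")
        if self.zero_floor < 0:
            raise CybospecError("zero_floor must be >= 0")


@dataclass(frozen=True)
class HBRecord:
    """One donor geometry in one frame: distance R (Å), angle theta
    (deg), and its hydrogen-bond score."""

    frame_index: int
    solvent_molecule_id: int
    R: float
    theta: float
    f_hb: float


def compute_rdf(
    traj: Trajectory,
    sel_A: np.ndarray,
    sel_B: np.ndarray,
    r_min: float = 0.0,
    r_max: float = 10.0,
    n_bins: int = 200,
    r_norm: float | None = None,
    center: np.ndarray | None = None,
) -> RDFResult:
    """Frame-averaged radial distribution function between two selections.

    g(r) = ⟨pair histogram⟩ / (N_A ρ_B 4π r² Δr), with ρ_B estimated
    from the B sites inside the concentric normalisation sphere of
    radius ``r_norm`` about ``center`` (default: origin). ``r_norm``
    defaults to ``r_max``.
    """
    sel_A = np.asarray(sel_A, dtype=int)
    sel_B = np.asarray(sel_B, dtype=int)
    if len(sel_A) == 0 or len(sel_B) == 0:
        raise SelectionError("RDF selections must be non-empty")
    if r_max <= r_min:
        raise CybospecError(f"r_max ({r_max}) must exceed r_min ({r_min})")
    if r_norm is None:
        r_norm = r_max
    if center is None:
        center = np.zeros(3)
    center = np.asarray(center, dtype=float).reshape(3)

    edges = np.linspace(r_min, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    n_B_inside = 0.0
    for fr in traj.frames:
        d = cdist(fr.coordinates[sel_A], fr.coordinates[sel_B]).ravel()
        hist += np.histogram(d, bins=edges)[0]
        rB = np.linalg.norm(fr.coordinates[sel_B] - center, axis=1)
        n_B_inside += np.count_nonzero(rB <= r_norm)
    n_frames = traj.n_frames
    hist /= n_frames
    rho_B = (n_B_inside / n_frames) / (4.0 / 3.0 * np.pi * r_norm**3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers**2 * np.diff(edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(rho_B > 0, hist / (len(sel_A) * rho_B * shell), 0.0)
    return RDFResult(bin_centers=centers, g=g, rho_B=rho_B, n_pairs_per_frame=hist)


def coordination_number(rdf: RDFResult, r_cut: float) -> float:
    """Running coordination number n(r_cut) = 4π ρ_B ∫₀^{r_cut} g r² dr.

    Trapezoid rule on the binned grid, integrating only up to r_cut.
    """
    r = rdf.bin_centers
    if r_cut < r[0] or r_cut > r[-1]:
        raise CybospecError(f"r_cut {r_cut} outside the RDF grid [{r[0]}, {r[-1]}]")
    mask = r <= r_cut
    rr = np.append(r[mask], r_cut)
    gg = np.append(rdf.g[mask], np.interp(r_cut, r, rdf.g))
    return float(4.0 * np.pi * rdf.rho_B * np.trapezoid(gg * rr**2, rr))


def find_first_extremum(rdf: RDFResult, kind: str = "peak", smooth_window: int = 5) -> float:
    """Location of the first local maximum of g (or the first minimum
    after it), on a moving-average-smoothed curve.

    Raises :class:`AnalysisError` when no such extremum exists (e.g.
    monotone g) instead of silently returning an endpoint.
    """
    if kind not in ("peak", "minimum_after_peak"):
        raise CybospecError(f"unknown extremum kind {kind!r}")
    g = rdf.g
    if len(g) < 5:
        raise AnalysisError("need at least 5 bins to locate an extremum")
    w = max(1, int(smooth_window))
    kernel = np.ones(w) / w
    # edge padding keeps the smoothed curve flat at the boundaries instead
    # of dipping toward zero (which would fake a peak on monotone input)
    pad = w // 2
    gs = np.convolve(np.pad(g, pad, mode="edge"), kernel, mode="valid")
    gs = gs[: len(g)]
    peak = None
    for i in range(1, len(gs) - 1):
        if gs[i] > gs[i - 1] and gs[i] >= gs[i + 1] and gs[i] > 0:
            peak = i
            break
    if peak is None:
        raise AnalysisError("no first peak found in g(r)")
    if kind == "peak":
        return float(rdf.bin_centers[peak])
    for i in range(peak + 1, len(gs) - 1):
        if gs[i] < gs[i - 1] and gs[i] <= gs[i + 1]:
            return float(rdf.bin_centers[i])
    raise AnalysisError("no minimum after the first peak found in g(r)")


def _radial_score(R: np.ndarray, params: HBParams) -> np.ndarray:
    """Flat-top radial factor: 1 up to R0, Gaussian decay beyond, with
    decay scale sigma_R * R0 (sigma_R is a fraction of R0)."""
    scale = params.sigma_R * params.R0
    excess = np.maximum(np.asarray(R, dtype=float) - params.R0, 0.0)
    return np.exp(-(excess**2) / (2.0 * scale**2))


def _angular_score(theta: np.ndarray, params: HBParams) -> np.ndarray:
    dev = np.asarray(theta, dtype=float) - params.theta0
    return np.exp(-(dev**2) / (2.0 * params.sigma_theta**2))


def f_hb(R, theta, params: HBParams = HBParams()) -> np.ndarray | float:
    """Continuous hydrogen-bond score in [0, 1].

    Separable product of a radial factor (1 for R ≤ R0, Gaussian decay
    beyond) and a Gaussian angular factor centred at theta0. Values
    below ``params.zero_floor`` are returned as exactly 0. Scalar in,
    scalar out.
    """
    R_arr = np.asarray(R, dtype=float)
    if np.any(R_arr <= 0):
        raise CybospecError("R must be positive")
    score = _radial_score(R_arr, params) * _angular_score(theta, params)
    score = np.where(score < params.zero_floor, 0.0, score)
    if np.isscalar(R) and np.isscalar(theta):
        return float(score)
    return score


@dataclass
class HBScanResult:
    records: list[HBRecord]
    frame_sums: np.ndarray          # per-frame summed F_HB
    histogram: np.ndarray           # counts of frame_sums
    histogram_edges: np.ndarray
    mean: float                     # trajectory mean ⟨F_HB⟩ of frame sums


def hb_scan(
    traj: Trajectory,
    donor_pairs: Sequence[tuple[int, int]],
    acceptor_site: int,
    params: HBParams = HBParams(),
    n_hist_bins: int = 30,
    hist_range: tuple[float, float] = (0.0, 3.0),
) -> HBScanResult:
    """Scan a trajectory for hydrogen bonds to one acceptor site.

    ``donor_pairs`` lists (hydrogen_index, donor_heavy_index) atom-index
    pairs — typically each solvent hydroxyl H with its parent O. Per
    frame and per donor the geometry (R = H···acceptor distance, ϑ =
    angle at the donor heavy atom between its H and the acceptor) is
    scored with :func:`f_hb`; nonzero scores are recorded. The per-frame
    score sum, its histogram, and the trajectory mean of the sums are
    returned.
    """
    if len(donor_pairs) == 0:
        raise SelectionError("no donor pairs supplied")
    top = traj.topology
    records: list[HBRecord] = []
    sums = np.zeros(traj.n_frames)
    h_idx = np.array([p[0] for p in donor_pairs], dtype=int)
    d_idx = np.array([p[1] for p in donor_pairs], dtype=int)
    mol_ids = np.array([top.atoms[i].molecule_id for i in h_idx], dtype=int)
    for k, fr in enumerate(traj.frames):
        acc = fr.coordinates[acceptor_site]
        h_pos = fr.coordinates[h_idx]
        d_pos = fr.coordinates[d_idx]
        R = np.linalg.norm(h_pos - acc, axis=1)
        v_h = h_pos - d_pos
        v_a = acc - d_pos
        cosang = np.einsum("ij,ij->i", v_h, v_a) / (
            np.linalg.norm(v_h, axis=1) * np.linalg.norm(v_a, axis=1)
        )
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        scores = f_hb(R, theta, params)
        sums[k] = scores.sum()
        for j in np.flatnonzero(scores > 0):
            records.append(
                HBRecord(
                    frame_index=k,
                    solvent_molecule_id=int(mol_ids[j]),
                    R=float(R[j]),
                    theta=float(theta[j]),
                    f_hb=float(scores[j]),
                )
            )
    hist, edges = np.histogram(sums, bins=n_hist_bins, range=hist_range)
    return HBScanResult(
        records=records,
        frame_sums=sums,
        histogram=hist,
        histogram_edges=edges,
        mean=float(sums.mean()) if len(sums) else 0.0,
    )


def subsample(traj: Trajectory, stride: float) -> Trajectory:
    """Thin a trajectory to one frame per ``stride`` ps.

    Keeps the frames nearest to the target times t₀ + k·stride (one per
    target, matched greedily in time order), decorrelating consecutive
    samples for clustering. ``stride`` must be at least the native
    frame spacing.
    """
    native = traj.stride
    if native > 0 and stride < native - 1e-9:
        raise CybospecError(
            f"stride {stride} ps is below the native frame spacing {native} ps"
        )
    times = traj.times
    t0, t1 = times[0], times[-1]
    n_targets = int(np.floor((t1 - t0) / stride + 1e-9)) + 1
    targets = t0 + stride * np.arange(n_targets)
    picked = []
    for tt in targets:
        i = int(np.argmin(np.abs(times - tt)))
        if not picked or i != picked[-1]:
            picked.append(i)
    return Trajectory(topology=traj.topology, frames=[traj.frames[i] for i in picked])
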
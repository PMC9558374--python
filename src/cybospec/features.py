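"""Interaction feature space for trajectory clustering.

Per frame, the two solvent atoms nearest the nitroxide group (A₁, A₂)
are identified and six distances are emitted: N–A₁, N–A₂, O–A₁, O–A₂,
LP1–A₁, LP2–A₂, where LP1/LP2 are the lone-pair virtual sites on the
oxygen. The matrix is then centred and reduced by PCA, keeping the
smallest number of components reaching a cumulative explained-variance
target (default 90%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .core import CybospecError, SelectionError, Trajectory

__all__ = ["FeatureMatrix", "PCAModel", "extract_features", "pca_fit_transform"]

FEATURE_LABELS = ("N-A1", "N-A2", "O-A1", "O-A2", "LP1-A1", "LP2-A2")


class FeatureError(CybospecError):
    """A feature row could not be built; the message names the frame."""


@dataclass
class FeatureMatrix:
    """frames × features distance matrix (Å) with provenance."""

    values: np.ndarray
    feature_labels: tuple[str, ...]
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)):
            raise FeatureError("feature matrix contains non-finite entries")


@dataclass
class PCAModel:
    """Fitted centring + orthonormal components + variance bookkeeping."""

    means: np.ndarray
    components: np.ndarray            # (m, n_features)
    explained_variance_ratio: np.ndarray  # all ratios, full decomposition
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) @ self.components.T


def extract_features(
    traj: Trajectory,
    sites: dict[str, int],
    candidate_atoms: np.ndarray,
    per_site_neighbors: bool = False,
) -> FeatureMatrix:
    """Six solute–solvent distances per frame.

    ``sites`` maps the labels ``N``, ``O``, ``LP1``, ``LP2`` to atom
    indices; ``candidate_atoms`` are the solvent atom indices eligible
    as A₁/A₂ (typically the polar atoms). By default A₁/A₂ are the two
    candidates nearest the N–O bond midpoint, shared by all six
    features; with ``per_site_neighbors`` each feature's first site
    picks its own nearest pair. Distance ties break on the lower atom
    index (np.argsort stable order).
    """
    for key in ("N", "O", "LP1", "LP2"):
        if key not in sites:
            raise SelectionError(f"site {key!r} missing from the sites mapping")
    candidate_atoms = np.asarray(candidate_atoms, dtype=int)
    if len(candidate_atoms) < 2:
        raise SelectionError("need at least 2 candidate solvent atoms")
    iN, iO, iL1, iL2 = (sites[k] for k in ("N", "O", "LP1", "LP2"))
    rows = []
    for k, fr in enumerate(traj.frames):
        c = fr.coordinates
        cand = c[candidate_atoms]
        if len(cand) < 2:
            raise FeatureError(f"frame {k}: fewer than 2 candidate atoms")
        if per_site_neighbors:
            row = []
            for site, which in ((iN, 0), (iN, 1), (iO, 0), (iO, 1), (iL1, 0), (iL2, 1)):
                d = np.linalg.norm(cand - c[site], axis=1)
                order = np.argsort(d, kind="stable")
                row.append(d[order[which]])
        else:
            mid = 0.5 * (c[iN] + c[iO])
            d_mid = np.linalg.norm(cand - mid, axis=1)
            order = np.argsort(d_mid, kind="stable")
            a1, a2 = cand[order[0]], cand[order[1]]
            row = [
                np.linalg.norm(c[iN] - a1),
                np.linalg.norm(c[iN] - a2),
                np.linalg.norm(c[iO] - a1),
                np.linalg.norm(c[iO] - a2),
                np.linalg.norm(c[iL1] - a1),
                np.linalg.norm(c[iL2] - a2),
            ]
        rows.append(row)
    return FeatureMatrix(
        values=np.asarray(rows, dtype=float),
        feature_labels=FEATURE_LABELS,
        frame_indices=np.arange(traj.n_frames),
    )


def pca_fit_transform(
    X: FeatureMatrix | np.ndarray,
    variance_target: float = 0.90,
) -> tuple[PCAModel, np.ndarray]:
    """Centre (no scaling — every feature is an Å distance) and project
    onto the smallest number of principal components whose cumulative
    explained variance reaches ``variance_target``.

    A zero-variance matrix yields a 0-component model with a warning.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if values.shape[0] < 2:
        raise CybospecError("PCA needs at least 2 frames")
    if values.shape[1] < 1:
        raise CybospecError("PCA needs at least 1 feature")
    total_var = np.var(values, axis=0).sum()
    if total_var < 1e-15:
        warnings.warn("zero-variance feature matrix: PCA returns 0 components")
        model = PCAModel(
            means=values.mean(axis=0),
            components=np.empty((0, values.shape[1])),
            explained_variance_ratio=np.empty(0),
            n_components=0,
        )
        return model, np.empty((values.shape[0], 0))
    pca = PCA(n_components=None)
    full = pca.fit_transform(values)
    ratios = pca.explained_variance_ratio_
    m = int(np.searchsorted(np.cumsum(ratios), variance_target - 1e-12) + 1)
    m = min(m, len(ratios))
    model = PCAModel(
        means=pca.mean_,
        components=pca.components_[:m],
        explained_variance_ratio=ratios,
        n_components=m,
    )
    return model, full[:, :m]
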
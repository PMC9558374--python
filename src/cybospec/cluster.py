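"""Partition Around Medoids clustering with 3-of-4 model selection.

Frames are partitioned with the classic PAM algorithm (greedy BUILD
followed by best-improvement SWAP) in the reduced feature space. The
number of clusters k is chosen by letting four internal validation
criteria vote: Silhouette (SI), Dunn index (DI), and Calinski–Harabasz
(pSF) each vote for their argmax over the k range, while the Within
Sum of Squares (WSS) votes for its elbow (largest discrete second
forward difference). A k endorsed by at least three of the four wins;
otherwise the smallest k among those with the most votes is returned
with a low-confidence flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from .core import CybospecError

__all__ = [
    "ClusteringResult",
    "KSelection",
    "pam",
    "validation_scores",
    "select_k",
    "cluster_scan",
]


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray
    medoid_indices: np.ndarray
    scores: dict[int, dict[str, float]] = field(default_factory=dict)


@dataclass
class KSelection:
    k: int
    votes: dict[str, int]
    vote_counts: dict[int, int]
    low_confidence: bool


def _assign(dist_to_medoids: np.ndarray) -> tuple[np.ndarray, float]:
    labels = np.argmin(dist_to_medoids, axis=1)
    cost = float(dist_to_medoids[np.arange(len(labels)), labels].sum())
    return labels, cost


def _build(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy BUILD initialisation: first medoid minimises total
    distance, each next maximises the cost reduction; exact ties are
    broken randomly."""
    medoids: list[int] = []
    totals = D.sum(axis=1)
    best = np.flatnonzero(totals == totals.min())
    medoids.append(int(rng.choice(best)))
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        cand = np.flatnonzero(gains == gains.max())
        pick = int(rng.choice(cand))
        medoids.append(pick)
        nearest = np.minimum(nearest, D[pick])
    return np.array(medoids, dtype=int)


def _swap(D: np.ndarray, medoid_arr: np.ndarray) -> tuple[np.ndarray, float]:
    """Best-improvement SWAP until no (medoid, non-medoid) exchange
    lowers the total cost; cost is non-increasing throughout."""
    n = D.shape[0]
    medoid_arr = medoid_arr.copy()
    _, cost = _assign(D[:, medoid_arr])
    improved = True
    while improved:
        improved = False
        best_delta = -1e-12
        best_swap = None
        non_medoids = np.setdiff1d(np.arange(n), medoid_arr)
        for mi in range(len(medoid_arr)):
            for h in non_medoids:
                trial = medoid_arr.copy()
                trial[mi] = h
                _, c = _assign(D[:, trial])
                delta = c - cost
                if delta < best_delta:
                    best_delta = delta
                    best_swap = (mi, h, c)
        if best_swap is not None:
            mi, h, c = best_swap
            medoid_arr[mi] = h
            cost = c
            improved = True
    return medoid_arr, cost


def pam(X: np.ndarray, k: int, seed: int = 0,
        n_restarts: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """PAM k-medoids: greedy BUILD + best-improvement SWAP, multi-start.

    Euclidean dissimilarity. SWAP is run once from the greedy BUILD
    initialisation and then from ``n_restarts − 1`` seeded random
    initialisations; the lowest-cost local optimum wins. The restarts
    guard against the (rare, small-instance) local optima of
    single-swap descent; the result is deterministic given the seed.

    Returns (labels, medoid_indices).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= k <= n:
        raise CybospecError(f"k = {k} outside [1, {n}]")
    rng = np.random.default_rng(seed)
    D = squareform(pdist(X))

    best_cost = np.inf
    medoid_arr = None
    for r in range(max(1, n_restarts)):
        init = _build(D, k, rng) if r == 0 else rng.choice(n, size=k, replace=False)
        cand, cost = _swap(D, np.asarray(init, dtype=int))
        if cost < best_cost - 1e-12:
            best_cost = cost
            medoid_arr = cand
    labels, _ = _assign(D[:, medoid_arr])
    # canonical order: medoids sorted by index, labels renumbered
    order = np.argsort(medoid_arr)
    medoid_arr = medoid_arr[order]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels], dtype=int)
    return labels, medoid_arr


def validation_scores(X: np.ndarray, labels: np.ndarray,
                      medoids: np.ndarray | None = None) -> dict[str, float]:
    """Internal validation criteria for one clustering.

    SI — mean silhouette, with singleton clusters scored 0;
    DI — min inter-cluster point separation / max intra-cluster diameter;
    pSF — Calinski–Harabasz between/within dispersion ratio;
    WSS — total squared distance to the cluster means.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels, dtype=int)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise CybospecError("validation scores need at least 2 clusters")

    si = float(np.mean(silhouette_samples(X, labels)))
    psf = float(calinski_harabasz_score(X, labels))

    D = squareform(pdist(X))
    max_diam = 0.0
    for c in ids:
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            max_diam = max(max_diam, float(D[np.ix_(idx, idx)].max()))
    min_sep = np.inf
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ia, ib = np.flatnonzero(labels == a), np.flatnonzero(labels == b)
            min_sep = min(min_sep, float(D[np.ix_(ia, ib)].min()))
    di = float(min_sep / max_diam) if max_diam > 0 else float("inf")

    wss = 0.0
    for c in ids:
        pts = X[labels == c]
        wss += float(((pts - pts.mean(axis=0)) ** 2).sum())

    return {"SI": si, "DI": di, "pSF": psf, "WSS": wss}


def select_k(scores: dict[int, dict[str, float]],
             k_range: tuple[int, int] | None = None) -> KSelection:
    """Choose k by the 3-of-4 vote among SI, DI, pSF and the WSS elbow.

    SI, DI and pSF vote for their argmax over the scanned k values; WSS
    votes for the interior k maximising the discrete second forward
    difference WSS(k−1) − 2·WSS(k) + WSS(k+1) (the sharpest slope
    break). With no ≥3-vote winner, the smallest k among the modal vote
    count is returned and ``low_confidence`` is set.
    """
    if not scores:
        raise CybospecError("empty score table")
    ks = sorted(scores)
    if k_range is not None:
        ks = [k for k in ks if k_range[0] <= k <= k_range[1]]
        if not ks:
            raise CybospecError("no scored k inside k_range")

    votes: dict[str, int] = {}
    for crit in ("SI", "DI", "pSF"):
        vals = [scores[k][crit] for k in ks]
        votes[crit] = ks[int(np.argmax(vals))]
    wss = np.array([scores[k]["WSS"] for k in ks])
    if len(ks) >= 3:
        curv = wss[:-2] - 2 * wss[1:-1] + wss[2:]
        votes["WSS"] = ks[1 + int(np.argmax(curv))]
    else:
        votes["WSS"] = ks[0]

    counts: dict[int, int] = {}
    for v in votes.values():
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    winners = sorted(k for k, c in counts.items() if c == top)
    return KSelection(
        k=winners[0],
        votes=votes,
        vote_counts=counts,
        low_confidence=top < 3,
    )


def cluster_scan(X: np.ndarray, k_min: int = 2, k_max: int = 20,
                 seed: int = 0) -> ClusteringResult:
    """Run PAM for every k in [k_min, k_max], score each, pick k by vote,
    and return the winning clustering with the full score table."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k_max = min(k_max, n - 1)
    results = {}
    scores: dict[int, dict[str, float]] = {}
    for k in range(k_min, k_max + 1):
        labels, medoids = pam(X, k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        results[k] = (labels, medoids)
        scores[k] = validation_scores(X, labels, medoids)
    sel = select_k(scores)
    labels, medoids = results[sel.k]
    return ClusteringResult(k=sel.k, labels=labels, medoid_indices=medoids, scores=scores)
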
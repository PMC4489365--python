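"""Representative-structure selection by centroid clustering of an ensemble.

Frames are compared by post-superposition heavy-atom RMSD and clustered
with a deterministic greedy centroid scheme; the cluster radius is tuned so
that around 20 clusters emerge, and the centroids of the ten largest
clusters become the representative structures, weighted by cluster size.
The fraction of frames covered by those clusters is reported, not enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import Conformation, ConformationEnsemble, kabsch_rmsd


@dataclass
class ClusterAssignment:
    """Frame-to-cluster labels; cluster ids are the centroid frame indices."""

    labels: np.ndarray            # frame -> cluster id
    centroid_frames: dict         # cluster id -> frame index (identical here)
    sizes: dict                   # cluster id -> member count
    radius: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


@dataclass
class RepresentativeSet:
    """Centroids of the largest clusters, ordered by descending weight."""

    structures: list[Conformation]
    weights: np.ndarray
    frame_indices: list[int]
    coverage: float               # fraction of all frames in the kept clusters
    truncated: bool               # True when fewer clusters than requested


def heavy_atom_selection(conformation: Conformation) -> np.ndarray:
    return np.array(
        [i for i, a in enumerate(conformation.atoms) if a.element != "H"], np.int64
    )


def pairwise_rmsd_matrix(
    ensemble: ConformationEnsemble, selection: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric matrix of pairwise post-superposition RMSDs (Å).

    ``selection`` defaults to all heavy atoms.  Every pair is superposed
    independently before the RMSD is evaluated.
    """
    n = len(ensemble)
    if n < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    sel = heavy_atom_selection(ensemble.template) if selection is None else np.asarray(selection, np.int64)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    coords = ensemble.coords[:, sel, :]
    centred = coords - coords.mean(axis=1, keepdims=True)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_rmsd(centred[i], centred[j])
            out[i, j] = out[j, i] = r
    return out


def centroid_cluster(matrix: np.ndarray, radius: float) -> ClusterAssignment:
    """Greedy centroid clustering of a precomputed RMSD matrix.

    Repeatedly promote the unassigned frame with the most unassigned
    neighbours within ``radius`` to a centroid (ties: lowest frame index)
    and assign its neighbourhood to it.  Deterministic for a given matrix.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = matrix.shape[0]
    labels = np.full(n, -1, np.int64)
    within = matrix <= radius
    while np.any(labels < 0):
        unassigned = labels < 0
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = unassigned & within[centroid]
        labels[members] = centroid
    ids = sorted(set(labels.tolist()))
    sizes = {c: int(np.sum(labels == c)) for c in ids}
    return ClusterAssignment(
        labels=labels,
        centroid_frames={c: c for c in ids},
        sizes=sizes,
        radius=float(radius),
    )


def tune_radius(
    matrix: np.ndarray,
    target_clusters: int = 20,
    tolerance: int = 3,
    max_iter: int = 40,
) -> float:
    """Bisect the cluster radius until the cluster count is near the target.

    Returns the radius whose count lands closest to ``target_clusters``
    (smallest radius on ties).  Stops early once within ``tolerance``.
    """
    n = matrix.shape[0]
    if target_clusters < 1:
        raise ValueError("target must be >= 1")
    if target_clusters > n:
        raise ValueError(f"target {target_clusters} exceeds the frame count {n}")
    off = matrix[~np.eye(n, dtype=bool)]
    positive = off[off > 0]
    lo = 0.9 * float(positive.min()) if positive.size else 1e-6
    hi = 1.01 * float(matrix.max()) + 1e-6

    best = None  # (count distance, radius, count)
    def evaluate(r):
        nonlocal best
        c = centroid_cluster(matrix, r).n_clusters
        key = (abs(c - target_clusters), r)
        if best is None or key < best[:2]:
            best = (abs(c - target_clusters), r, c)
        return c

    c_lo = evaluate(lo)
    c_hi = evaluate(hi)
    for _ in range(max_iter):
        if best[0] <= tolerance:
            break
        mid = 0.5 * (lo + hi)
        c_mid = evaluate(mid)
        # cluster count decreases with radius
        if c_mid > target_clusters:
            lo, c_lo = mid, c_mid
        elif c_mid < target_clusters:
            hi, c_hi = mid, c_mid
        else:
            break
    return float(best[1])


def select_representatives(
    assignment: ClusterAssignment,
    ensemble: ConformationEnsemble,
    k: int = 10,
) -> RepresentativeSet:
    """Centroids of the ``k`` largest clusters with cluster-size weights.

    Weights are the cluster sizes renormalised over the kept clusters; the
    coverage (kept frames / all frames) is reported alongside.  If fewer
    clusters exist than requested, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(assignment.sizes.items(), key=lambda kv: (-kv[1], kv[0]))
    truncated = len(ranked) < k
    if truncated:
        warnings.warn(
            f"only {len(ranked)} clusters available; requested {k} representatives"
        )
    kept = ranked[:k]
    total_kept = sum(s for _, s in kept)
    n_frames = int(assignment.labels.shape[0])
    structures = [ensemble[assignment.centroid_frames[c]] for c, _ in kept]
    weights = np.array([s / total_kept for _, s in kept])
    return RepresentativeSet(
        structures=structures,
        weights=weights,
        frame_indices=[assignment.centroid_frames[c] for c, _ in kept],
        coverage=total_kept / n_frames,
        truncated=truncated,
    )
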
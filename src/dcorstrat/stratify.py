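"""Embedding, clustering and group gene-set extraction from D_dCor.

The dCor similarity matrix is converted to the dissimilarity 1 - D_dCor,
embedded with classical (Torgerson) multidimensional scaling for
visualization, and partitioned with replicated squared-Euclidean K-means.
Silhouette profiles guide the choice of K; per-cluster SMG unions and
cluster-specific gene sets summarize what distinguishes the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .dcor import DistanceCorrelationMatrix
from .variant_io import SMGProfile

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    """1 - D_dCor with an exactly-zero diagonal."""

    values: np.ndarray
    patient_ids: list[str]


@dataclass
class MDSEmbedding:
    """Classical MDS coordinates, one row per patient, axes sorted by
    descending eigenvalue; only positive-eigenvalue axes are kept."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    retained_dims: int
    patient_ids: list[str]


@dataclass
class ClusterAssignment:
    """Best-of-replicates K-means labels (1..K) plus run metadata."""

    patient_ids: list[str]
    labels: np.ndarray  # int array, values in 1..K
    K: int
    within_ss: float
    seed: int
    replicates: int
    silhouette: np.ndarray | None = None

    @property
    def labels_map(self) -> dict[str, int]:
        return dict(zip(self.patient_ids, (int(x) for x in self.labels)))

    def members(self, cluster: int) -> list[str]:
        return [p for p, l in zip(self.patient_ids, self.labels) if l == cluster]


@dataclass
class GroupGeneSets:
    """Per-cluster SMG unions and the genes specific to each cluster."""

    unions: dict[int, frozenset[str]]
    specific: dict[int, frozenset[str]]
    shared: frozenset[str] = field(default_factory=frozenset)


def to_dissimilarity(D: DistanceCorrelationMatrix, atol: float = 1e-8) -> DissimilarityMatrix:
    """Element-wise 1 - dCor, with the diagonal forced to exactly zero."""
    V = np.asarray(D.values, dtype=float)
    if (V < -atol).any() or (V > 1.0 + atol).any():
        raise ValueError("dCor entries outside [0, 1] beyond tolerance")
    S = 1.0 - np.clip(V, 0.0, 1.0)
    np.fill_diagonal(S, 0.0)
    return DissimilarityMatrix(values=S, patient_ids=list(D.patient_ids))


def classical_mds(S, k: int = 3, patient_ids: list[str] | None = None) -> MDSEmbedding:
    """Torgerson scaling of a dissimilarity matrix.

    Double-centers -1/2 * S∘S, eigendecomposes, and returns coordinates
    eigvec * sqrt(eigval) for the top-k positive-eigenvalue axes. If the
    dissimilarity admits fewer than k positive axes, fewer columns are
    returned (logged). Column signs are fixed so the largest-magnitude
    loading of each axis is positive, making output deterministic.
    """
    if isinstance(S, DissimilarityMatrix):
        patient_ids = patient_ids or S.patient_ids
        M = S.values
    else:
        M = np.asarray(S, dtype=float)
    n = M.shape[0]
    if M.ndim != 2 or M.shape[1] != n:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if patient_ids is None:
        patient_ids = [str(i) for i in range(n)]

    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (M * M) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1.0, float(np.abs(eigval).max())) * n * np.finfo(float).eps
    n_pos = int(np.sum(eigval > tol))
    keep = min(k, n_pos)
    if keep < k:
        logger.info("classical_mds: only %d positive axes available (requested %d)", n_pos, k)
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    for j in range(keep):  # deterministic sign convention
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    if keep == 0:
        coords = np.zeros((n, 1))
        keep = 1
    return MDSEmbedding(
        coordinates=coords,
        eigenvalues=eigval,
        retained_dims=keep,
        patient_ids=list(patient_ids),
    )


def kmeans_cluster(
    X,
    K: int,
    replicates: int = 50,
    seed: int = 0,
    patient_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Squared-Euclidean K-means (Lloyd), best of ``replicates`` random
    initializations by within-cluster sum of squares; deterministic given
    ``seed``. ``X`` may be a DissimilarityMatrix (rows as feature vectors,
    the default reading of clustering "the same dissimilarity matrix") or an
    MDSEmbedding / plain array.
    """
    if isinstance(X, DissimilarityMatrix):
        patient_ids = patient_ids or X.patient_ids
        F = X.values
    elif isinstance(X, MDSEmbedding):
        patient_ids = patient_ids or X.patient_ids
        F = X.coordinates
    else:
        F = np.asarray(X, dtype=float)
    n = F.shape[0]
    if patient_ids is None:
        patient_ids = [str(i) for i in range(n)]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds number of patients ({n})")
    km = KMeans(
        n_clusters=K,
        n_init=replicates,
        init="random",
        algorithm="lloyd",
        random_state=seed,
    ).fit(F)
    return ClusterAssignment(
        patient_ids=list(patient_ids),
        labels=km.labels_.astype(int) + 1,
        K=K,
        within_ss=float(km.inertia_),
        seed=seed,
        replicates=replicates,
    )


def silhouette_profile(X, assignment: ClusterAssignment) -> tuple[np.ndarray, float]:
    """Per-patient silhouette s = (b - a) / max(a, b) with Euclidean distance
    on the same feature rows used for clustering; singleton clusters get 0.

    Returns (per-patient values, mean). Attaches the values to ``assignment``.
    """
    if isinstance(X, DissimilarityMatrix):
        F = X.values
    elif isinstance(X, MDSEmbedding):
        F = X.coordinates
    else:
        F = np.asarray(X, dtype=float)
    if len(np.unique(assignment.labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    s = silhouette_samples(F, assignment.labels, metric="euclidean")
    assignment.silhouette = s
    return s, float(s.mean())


def silhouette_by_k(
    X,
    k_range=range(2, 9),
    replicates: int = 50,
    seed: int = 0,
) -> dict[int, float]:
    """Mean silhouette for each candidate K — the report used to choose K
    (the run itself proceeds with a user-chosen K)."""
    out: dict[int, float] = {}
    for K in k_range:
        assign = kmeans_cluster(X, K, replicates=replicates, seed=seed)
        _, mean_s = silhouette_profile(X, assign)
        out[K] = mean_s
    return out


def group_specific_genes(
    assignment: ClusterAssignment,
    profiles: dict[str, SMGProfile],
) -> GroupGeneSets:
    """Per-cluster SMG unions; a gene is cluster-specific when it appears in
    that cluster's union and no other's, and shared when it appears in two or
    more unions."""
    unions: dict[int, set[str]] = {k: set() for k in sorted(set(int(l) for l in assignment.labels))}
    for pid, label in zip(assignment.patient_ids, assignment.labels):
        prof = profiles.get(pid)
        if prof is not None:
            unions[int(label)].update(prof.genes)
    specific: dict[int, frozenset[str]] = {}
    for k, u in unions.items():
        others: set[str] = set()
        for k2, u2 in unions.items():
            if k2 != k:
                others |= u2
        specific[k] = frozenset(u - others)
    all_specific = frozenset().union(*specific.values()) if specific else frozenset()
    all_genes = frozenset().union(*unions.values()) if unions else frozenset()
    return GroupGeneSets(
        unions={k: frozenset(u) for k, u in unions.items()},
        specific=specific,
        shared=all_genes - all_specific,
    )
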
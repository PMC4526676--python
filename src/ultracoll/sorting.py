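"""Spike sorting: 3-PC projection, mixture clustering, isolation distance.

Snippets are projected onto the first three principal components of the
snippet set, clustered with a Gaussian-mixture EM fit (model order chosen
by BIC), and each cluster is quality-gated by its isolation distance: the
squared Mahalanobis distance — under the cluster's own mean and covariance
— of the n-th closest non-member snippet, where n is the cluster size.
Only clusters with isolation distance strictly greater than 20 are
accepted as single units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.mixture import GaussianMixture

from .preprocess import SnippetSet
from .signal_io import ClusteringError, InsufficientDataError

log = logging.getLogger(__name__)

ISOLATION_THRESHOLD = 20.0
UNASSIGNED = -1


@dataclass
class ClusterResult:
    """Output of the sorting stage for one channel's snippets."""

    labels: np.ndarray  # per-snippet cluster id; -1 = unassigned
    features: np.ndarray  # [n_snippets x 3] PC scores
    isolation_distance: dict[int, float | None] = field(default_factory=dict)
    accepted: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        assert self.features.shape[1] == 3


def project_pca(snippets: SnippetSet | np.ndarray, return_components: bool = False):
    """Project snippets onto the first 3 principal components.

    Scores are mean-centered projections onto the top-3 eigenvectors of the
    snippet covariance.  Each eigenvector's sign is fixed so its
    largest-magnitude coefficient is positive, making the projection
    deterministic.
    """
    X = snippets.snippets if isinstance(snippets, SnippetSet) else np.asarray(snippets)
    if X.shape[0] < 4:
        raise InsufficientDataError(f"need >= 4 snippets for PCA, got {X.shape[0]}")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:3]
    V = evecs[:, order]
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    scores = Xc @ V
    if return_components:
        return scores, V
    return scores


def cluster_features(
    features: np.ndarray,
    max_clusters: int = 8,
    seed: int = 0,
    min_responsibility: float = 0.5,
) -> np.ndarray:
    """Cluster PC scores with Gaussian-mixture EM, model order by BIC.

    Labels are maximum-responsibility assignments; snippets whose maximum
    responsibility is below ``min_responsibility`` are labeled -1
    (unassigned) and later count as cluster non-members.
    """
    X = np.asarray(features, dtype=float)
    best = None
    best_bic = np.inf
    for k in range(1, max_clusters + 1):
        if X.shape[0] < 2 * k:
            break
        try:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=3,
                reg_covar=1e-9,
                random_state=seed,
            ).fit(X)
        except (ValueError, linalg.LinAlgError):  # pragma: no cover - rare EM failure
            continue
        bic = gm.bic(X)
        if bic < best_bic:
            best, best_bic = gm, bic
    if best is None:
        raise ClusteringError("EM failed for every candidate model order")
    resp = best.predict_proba(X)
    labels = np.argmax(resp, axis=1)
    labels[resp.max(axis=1) < min_responsibility] = UNASSIGNED
    return labels


def isolation_distance(
    features: np.ndarray, labels: np.ndarray, cluster_id: int
) -> float | None:
    """Isolation distance of one cluster.

    Squared Mahalanobis distance, under the cluster's own mean and
    covariance, of the n-th closest non-member point (n = cluster size).
    Returns ``None`` (undefined) when there are fewer non-members than
    members.  A singular cluster covariance is regularized by adding
    ``1e-9 * trace/3`` to the diagonal, with a logged warning.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    members = X[labels == cluster_id]
    others = X[labels != cluster_id]
    n = members.shape[0]
    if n < 4:
        raise InsufficientDataError(f"cluster {cluster_id} has only {n} members")
    if others.shape[0] < n:
        return None
    mu = members.mean(axis=0)
    cov = np.cov(members, rowvar=False)
    try:
        chol = linalg.cho_factor(cov)
    except linalg.LinAlgError:
        log.warning("singular covariance for cluster %s; regularizing", cluster_id)
        cov = cov + np.eye(cov.shape[0]) * (1e-9 * np.trace(cov) / cov.shape[0])
        chol = linalg.cho_factor(cov)
    diff = others - mu
    d2 = np.einsum("ij,ij->i", diff, linalg.cho_solve(chol, diff.T).T)
    d2.sort()
    return float(d2[n - 1])


def accept_units(
    isolation: dict[int, float | None], threshold: float = ISOLATION_THRESHOLD
) -> set[int]:
    """Accept clusters whose isolation distance is defined and strictly
    greater than the threshold."""
    return {c for c, d in isolation.items() if d is not None and d > threshold}


def sort_snippets(
    snippets: SnippetSet | np.ndarray,
    max_clusters: int = 8,
    seed: int = 0,
    threshold: float = ISOLATION_THRESHOLD,
) -> ClusterResult:
    """Full sorting chain: PCA projection, clustering, isolation gating."""
    features = project_pca(snippets)
    labels = cluster_features(features, max_clusters=max_clusters, seed=seed)
    iso: dict[int, float | None] = {}
    for c in sorted(set(labels) - {UNASSIGNED}):
        members = labels == c
        if members.sum() < 4:
            iso[c] = None
            continue
        iso[c] = isolation_distance(features, labels, c)
    return ClusterResult(
        labels=labels,
        features=features,
        isolation_distance=iso,
        accepted=accept_units(iso, threshold),
    )
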
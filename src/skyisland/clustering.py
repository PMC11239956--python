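"""DAPC-style genetic clustering.

Discriminant analysis of principal components: genotypes are reduced by
PCA (missing calls imputed by per-locus means), candidate cluster numbers
are scored by k-means with a BIC of the form n·ln(WSS/n) + k·ln(n), and a
linear discriminant analysis of the retained PCs yields membership
probabilities (softmax of negative squared distances to cluster centroids
in discriminant space).  The a-score contrasts observed reassignment rates
with those obtained under permuted labels, penalizing overfitting as the
number of retained PCs grows.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import GenotypeMatrix

__all__ = ["ClusterModel", "genotype_pca", "kmeans_bic_scan", "dapc_fit", "dapc_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    """Fitted DAPC model: assignments, memberships, model-selection trace."""

    n_pcs_retained: int
    k: int
    bic_by_k: dict[int, float]
    cluster_assignments: np.ndarray
    membership_probabilities: np.ndarray
    a_score: float | None = None


def genotype_pca(
    g: GenotypeMatrix | np.ndarray, n_axes: int, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of the genotype matrix.

    Missing entries are imputed by the per-locus mean before centering.
    Returns (scores, explained variance fractions).  Axis signs follow the
    convention that each axis' largest-magnitude loading is positive.
    ``n_axes`` beyond the matrix rank is truncated with a warning.
    """
    X = g.genotypes if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two individuals")
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(np.isnan(X), col_mean, X)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_axes > rank:
        logger.warning("requested %d axes but rank is %d; truncating", n_axes, rank)
        n_axes = rank
    # sign convention: largest-|loading| positive per axis
    for j in range(n_axes):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U[:, :n_axes] * s[:n_axes]
    var = s**2
    explained = var[:n_axes] / var.sum() if var.sum() > 0 else np.zeros(n_axes)
    return scores, explained


def kmeans_bic_scan(
    scores: np.ndarray,
    k_min: int = 1,
    k_max: int = 8,
    seed: int | None = None,
    n_restarts: int = 10,
) -> tuple[dict[int, float], int]:
    """K-means over a range of k scored by BIC = n·ln(WSS/n) + k·ln(n).

    ``best_k`` is the argmin of the BIC; ties resolve to the smaller k.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of individuals")
    rng = np.random.default_rng(seed)
    bic_by_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(
            n_clusters=k, n_init=n_restarts,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(scores)
        wss = km.inertia_
        bic_by_k[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
    best_k = min(bic_by_k, key=lambda k: (round(bic_by_k[k], 12), k))
    return bic_by_k, best_k


def _reassignment_rate(
    scores: np.ndarray, labels: np.ndarray, n_pcs: int
) -> float:
    """Fraction of individuals a refit DA assigns back to their own cluster."""
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores[:, :n_pcs], labels)
    return float((lda.predict(scores[:, :n_pcs]) == labels).mean())


def a_score(
    scores: np.ndarray,
    labels: np.ndarray,
    n_pcs: int,
    n_permutations: int = 10,
    seed: int | None = None,
) -> float:
    """Observed reassignment rate minus its permuted-label expectation."""
    rng = np.random.default_rng(seed)
    observed = _reassignment_rate(scores, labels, n_pcs)
    permuted = np.mean(
        [
            _reassignment_rate(scores, rng.permutation(labels), n_pcs)
            for _ in range(n_permutations)
        ]
    )
    return float(observed - permuted)


def dapc_fit(
    scores: np.ndarray,
    assignments: np.ndarray,
    n_pcs: int,
    bic_by_k: dict[int, float] | None = None,
    compute_a_score: bool = False,
    seed: int | None = None,
) -> ClusterModel:
    """Linear discriminant analysis of retained PCs.

    Membership probabilities are the softmax of negative squared distances
    to cluster centroids in the (whitened) discriminant space; rows sum
    to 1.  Single-member clusters fall back on the pooled covariance that
    LDA already uses.
    """
    scores = np.asarray(scores, dtype=float)
    assignments = np.asarray(assignments)
    if n_pcs > scores.shape[1]:
        raise ValueError("n_pcs exceeds available axes")
    labels = np.unique(assignments)
    if labels.size < 2:
        raise ValueError("discriminant analysis needs at least two clusters")
    X = scores[:, :n_pcs]
    lda = LinearDiscriminantAnalysis()
    disc = lda.fit_transform(X, assignments)
    centroids = np.vstack([disc[assignments == lab].mean(axis=0) for lab in labels])
    d2 = ((disc[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    logits = -0.5 * d2
    logits -= logits.max(axis=1, keepdims=True)
    member = np.exp(logits)
    member /= member.sum(axis=1, keepdims=True)

    score = None
    if compute_a_score:
        score = a_score(scores, assignments, n_pcs, seed=seed)

    return ClusterModel(
        n_pcs_retained=n_pcs,
        k=labels.size,
        bic_by_k=bic_by_k or {},
        cluster_assignments=assignments,
        membership_probabilities=member,
        a_score=score,
    )


def dapc_pipeline(
    g: GenotypeMatrix,
    n_axes: int | None = None,
    k_min: int = 1,
    k_max: int = 8,
    n_pcs: int | None = None,
    seed: int | None = None,
    force_k: int | None = None,
) -> ClusterModel:
    """Full DAPC: PCA → BIC scan → k-means assignment → discriminant fit.

    ``force_k`` overrides the BIC-selected cluster number (used to inspect
    secondary structure at k values near the optimum).  When the selected
    or forced k is 1 the model carries the trivial single-cluster
    assignment and no discriminant step is run.  ``n_axes`` defaults to
    the customary N/3 rule of thumb: retaining many more PCs than that
    dilutes the cluster signal with noise axes and overfits the
    discriminant step.
    """
    if n_axes is None:
        n_axes = max(2, g.n_individuals // 3)
    n_axes = min(n_axes, g.n_individuals - 1, g.n_loci)
    scores, _ = genotype_pca(g, n_axes)
    bic_by_k, best_k = kmeans_bic_scan(
        scores, k_min=k_min, k_max=min(k_max, g.n_individuals - 1), seed=seed
    )
    k = force_k if force_k is not None else best_k
    rng = np.random.default_rng(seed)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31 - 1)))
    assignments = km.fit_predict(scores)
    if k == 1:
        return ClusterModel(
            n_pcs_retained=scores.shape[1],
            k=1,
            bic_by_k=bic_by_k,
            cluster_assignments=assignments,
            membership_probabilities=np.ones((g.n_individuals, 1)),
        )
    n_keep = n_pcs if n_pcs is not None else max(2, min(scores.shape[1], 10))
    n_keep = min(n_keep, scores.shape[1])
    return dapc_fit(scores, assignments, n_keep, bic_by_k=bic_by_k, seed=seed)
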
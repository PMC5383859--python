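"""Multivariate population structure: PCA, PERMANOVA, and DAPC.

PCA operates on the column-centered (unscaled) composite-genotype matrix by
singular-value decomposition — ordination of the genotype covariance
structure.  PERMANOVA tests group separation on the first two ordination
axes using Euclidean distances, a pseudo-F statistic and free label
permutations.  DAPC first searches for the most likely number of clusters
by k-means over PCA scores with a BIC criterion, then computes individual
assignment probabilities by linear discriminant analysis on the retained
principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data_io import GenotypeMatrix, ValidationError


@dataclass
class OrdinationResult:
    scores: np.ndarray          # N x K
    pct_variance: np.ndarray    # K, non-increasing, sums to 100
    loadings: np.ndarray        # L x K


@dataclass
class PermanovaResult:
    r2: float
    f: float
    p: float
    df_between: int
    df_within: int
    n_perm: int

    def to_record(self) -> dict:
        return {
            "R2": self.r2, "F": self.f, "p": self.p,
            "df_between": self.df_between, "df_within": self.df_within,
            "n_perm": self.n_perm,
        }


@dataclass
class DapcResult:
    bic_by_k: dict[int, float] = field(default_factory=dict)
    best_k: int = 1
    cluster_labels: np.ndarray | None = None
    assignments: np.ndarray | None = None  # N x best_k, rows sum to 1


def pca_genotypes(gm_or_matrix) -> OrdinationResult:
    """PCA of composite genotypes: center columns, SVD, percent variance
    from squared singular values."""
    if isinstance(gm_or_matrix, GenotypeMatrix):
        x = gm_or_matrix.composite
    else:
        x = np.asarray(gm_or_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need >= 2 individuals and >= 2 loci")
    if np.isnan(x).any():
        raise ValidationError("composite matrix has missing values")
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        # constant matrix: no variance on any axis
        k = min(x.shape)
        return OrdinationResult(
            scores=np.zeros((x.shape[0], k)),
            pct_variance=np.zeros(k),
            loadings=vt.T,
        )
    pct = 100.0 * s**2 / total
    return OrdinationResult(scores=u * s, pct_variance=pct, loadings=vt.T)


def _ss_within(d2: np.ndarray, label_matrix: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Within-group sum of squared distances / group size, summed over
    groups, for a batch of labelings.

    ``label_matrix`` is (B, N) integer labels; returns length-B array.
    """
    b = label_matrix.shape[0]
    out = np.zeros(b)
    for g in range(sizes.size):
        mask = (label_matrix == g).astype(float)       # B x N
        out += np.einsum("bi,ij,bj->b", mask, d2, mask) / (2.0 * sizes[g])
    return out


def permanova(
    points: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA on Euclidean distances of ordination scores.

    SS_total = sum of squared pairwise distances / N; SS_within sums the
    per-group quantity over groups; pseudo-F = (SS_between/(a-1)) /
    (SS_within/(N-a)); p includes the observed statistic in the null set.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = points.shape[0]
    uniq, enc = np.unique(labels, return_inverse=True)
    a = uniq.size
    sizes = np.bincount(enc)
    if a < 2:
        raise ValidationError("need >= 2 groups")
    if (sizes < 2).any():
        raise ValidationError("every group needs >= 2 members")
    diff = points[:, None, :] - points[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_w_obs = _ss_within(d2, enc[None, :], sizes)[0]
    ss_b_obs = ss_total - ss_w_obs
    df_b, df_w = a - 1, n - a
    f_obs = (ss_b_obs / df_b) / (ss_w_obs / df_w)
    r2 = ss_b_obs / ss_total

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(enc) for _ in range(n_perm)])
    ss_w = _ss_within(d2, perms, sizes)
    f_perm = ((ss_total - ss_w) / df_b) / (ss_w / df_w)
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_perm)
    return PermanovaResult(
        r2=float(r2), f=float(f_obs), p=float(p),
        df_between=df_b, df_within=df_w, n_perm=n_perm,
    )


def kmeans_bic(wss: float, n: int, k: int) -> float:
    """BIC for a k-means solution: N ln(WSS/N) + k ln(N)."""
    return n * np.log(wss / n) + k * np.log(n)


def dapc_find_clusters(
    scores: np.ndarray,
    n_pcs: int,
    k_max: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> DapcResult:
    """k-means cluster search over retained PCs, model choice by BIC."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n_pcs > scores.shape[1]:
        raise ValidationError(f"n_pcs {n_pcs} exceeds available axes {scores.shape[1]}")
    if k_max >= n:
        raise ValidationError("k_max must be smaller than the number of individuals")
    x = scores[:, :n_pcs]
    result = DapcResult()
    best_labels = None
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((x - x.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k, n_init=n_restarts, max_iter=300,
                random_state=seed,
            ).fit(x)
            wss = float(km.inertia_)
            labels = km.labels_
        result.bic_by_k[k] = kmeans_bic(max(wss, 1e-300), n, k)
        if result.bic_by_k[k] == min(result.bic_by_k.values()):
            result.best_k = k
            best_labels = labels
    result.cluster_labels = best_labels
    return result


def dapc_assign(
    scores: np.ndarray,
    cluster_labels: np.ndarray,
    n_pcs: int,
    n_da: int | None = None,
) -> DapcResult:
    """Assignment probabilities from LDA on the retained PCs.

    The discriminant-space Gaussian model gives each individual a
    probability of membership in each cluster; rows sum to 1.  Singular
    within-cluster covariance is handled by the SVD solver's implicit
    regularization (rank truncation).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(cluster_labels)
    k = np.unique(labels).size
    if k < 2:
        raise ValidationError("need >= 2 clusters for discriminant analysis")
    x = scores[:, :n_pcs]
    if n_da is None:
        n_da = min(k - 1, x.shape[1])
    if n_da > k - 1:
        raise ValidationError("n_da cannot exceed clusters - 1")
    lda = LinearDiscriminantAnalysis(n_components=n_da, solver="svd")
    lda.fit(x, labels)
    proba = lda.predict_proba(x)
    result = DapcResult(best_k=k, cluster_labels=labels, assignments=proba)
    return result
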
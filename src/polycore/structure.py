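"""Ordination and group assignment: PCA, K selection, k-means labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .geno_io import DosageMatrix, ValidationError


@dataclass
class PcaResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    percent_variance: np.ndarray
    n_components: int
    degenerate: bool = False  # zero total variance: scores all 0, pct undefined


@dataclass
class GroupAssignment:
    k: int
    labels: np.ndarray  # ints 0..k-1
    index_scores: dict[str, dict[int, float]] = field(default_factory=dict)
    low_confidence: bool = False


def pca(matrix: DosageMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the dosage matrix via SVD.

    Missing calls are marker-mean imputed; columns are centered but not
    variance-scaled (dosages share a scale).  Percent variance is relative
    to the total variance of the imputed, centered matrix.
    """
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs at least two samples")
    x = matrix.calls.astype(float)
    miss = matrix.missing_mask()
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean[np.isnan(col_mean)] = 0.0  # all-missing marker: impute 0, centers to 0
    inds = np.where(miss)
    x[inds] = col_mean[inds[1]]
    x -= x.mean(axis=0)

    n_components = min(n_components, matrix.n_samples, matrix.n_markers)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total_var = float((s**2).sum())
    if total_var == 0.0:
        return PcaResult(
            sample_ids=list(matrix.sample_ids),
            scores=np.zeros((matrix.n_samples, n_components)),
            percent_variance=np.full(n_components, np.nan),
            n_components=n_components,
            degenerate=True,
        )
    scores = u[:, :n_components] * s[:n_components]
    pct = 100.0 * (s[:n_components] ** 2) / total_var
    return PcaResult(
        sample_ids=list(matrix.sample_ids),
        scores=scores,
        percent_variance=pct,
        n_components=n_components,
    )


def kmeans_assign(scores: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """k-means labels on ordination scores; best of ``n_init`` restarts."""
    scores = np.asarray(scores, dtype=float)
    if k < 1:
        raise ValidationError("K must be >= 1")
    if k > scores.shape[0]:
        raise ValidationError("K exceeds number of samples")
    if k == 1:
        return np.zeros(scores.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(scores)


def choose_k(
    scores: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    n_components: int = 3,
) -> GroupAssignment:
    """Choose the number of groups by clustering indices on PCA scores.

    For each candidate K in [k_min, k_max], k-means (fixed seed, 10 restarts)
    is run on the first ``n_components`` score columns; the silhouette and
    Calinski-Harabasz indices each vote for their best K.  Majority vote
    decides; a tie goes to the smaller K and flags the result as
    low-confidence.
    """
    scores = np.asarray(scores, dtype=float)[:, :n_components]
    n = scores.shape[0]
    if k_max >= n:
        raise ValidationError(f"k_max ({k_max}) must be < n_samples ({n})")
    if k_min < 2:
        raise ValidationError("k_min must be >= 2")

    sil: dict[int, float] = {}
    ch: dict[int, float] = {}
    labels_at: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        lab = kmeans_assign(scores, k, seed=seed)
        labels_at[k] = lab
        if len(set(lab.tolist())) < 2:
            sil[k] = -1.0
            ch[k] = 0.0
            continue
        sil[k] = float(silhouette_score(scores, lab))
        ch[k] = float(calinski_harabasz_score(scores, lab))

    def best(index: dict[int, float]) -> int:
        top = max(index.values())
        return min(k for k, v in index.items() if v == top)

    votes = [best(sil), best(ch)]
    if votes[0] == votes[1]:
        k_best, low_conf = votes[0], False
    else:
        k_best, low_conf = min(votes), True
    return GroupAssignment(
        k=k_best,
        labels=labels_at[k_best],
        index_scores={"silhouette": sil, "calinski_harabasz": ch},
        low_confidence=low_conf,
    )
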
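"""Enterotype discovery: PAM over Bray-Curtis, Calinski-Harabasz model choice.

The workflow mirrors the classic enterotyping recipe: cluster samples with
partitioning-around-medoids (PAM) on a genus-level Bray-Curtis matrix for a
range of k, score each k with the Calinski-Harabasz pseudo-F computed in
principal-coordinate space, and keep the k with the highest score (ties go
to the smaller k).  :class:`EnterotypeModel` / :class:`EnterotypeResults`
wrap the scan statsmodels-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn import metrics as _skl_metrics

from .diversity import bray_curtis, pcoa_positive_coordinates
from .io import AsvTable

#: Sentinel reported when within-cluster dispersion is exactly zero.
CH_INF_SENTINEL = 1e12


#: exhaustively search medoid sets when C(n, k) is at most this
_EXACT_SEARCH_LIMIT = 20000


def pam_cluster(dm: DistanceMatrix, k: int, seed: int = 0) -> tuple[np.ndarray, list]:
    """k-medoids: exact search when cheap, classic BUILD + SWAP otherwise.

    When the number of candidate medoid sets C(n, k) is small the global
    optimum is found by enumeration (BUILD+SWAP can stall in a swap-local
    optimum); larger problems use the deterministic BUILD + SWAP heuristic
    (BUILD greedily picks medoids that most reduce total
    distance-to-nearest-medoid; SWAP applies best-improvement swaps until no
    swap lowers the cost).  Exact cost ties are broken by the lowest
    candidate index, so ``seed`` only matters when floating-point costs tie
    exactly.
    """
    import math

    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")

    if math.comb(n, k) <= _EXACT_SEARCH_LIMIT:
        import itertools

        best_cost, best_set = np.inf, None
        for combo in itertools.combinations(range(n), k):
            cost = D[list(combo)].min(axis=0).sum()
            if cost < best_cost - 1e-12:
                best_cost, best_set = cost, combo
        medoids = list(best_set)
        med = np.array(medoids)
        labels = np.argmin(D[med], axis=0)
        for ci, m in enumerate(medoids):
            labels[m] = ci
        return labels, [dm.ids[m] for m in medoids]

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dist_to_nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.minimum(dist_to_nearest[None, :], D).sum(axis=1)
        gains[medoids] = np.inf
        cand = int(np.argmin(gains))
        medoids.append(cand)
        dist_to_nearest = np.minimum(dist_to_nearest, D[cand])

    # SWAP (best improvement)
    medoids = sorted(medoids)
    while True:
        med = np.array(medoids)
        cost = D[med].min(axis=0).sum()
        best = (0.0, None)
        non_med = [h for h in range(n) if h not in medoids]
        for mi, m in enumerate(medoids):
            others = np.delete(med, mi)
            base = D[others].min(axis=0) if len(others) else np.full(n, np.inf)
            for h in non_med:
                new_cost = np.minimum(base, D[h]).sum()
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = sorted(medoids)

    med = np.array(medoids)
    labels = np.argmin(D[med], axis=0)
    # medoids must belong to their own cluster even under distance ties
    for ci, m in enumerate(medoids):
        labels[m] = ci
    medoid_ids = [dm.ids[m] for m in medoids]
    return labels, medoid_ids


def pam_total_cost(dm: DistanceMatrix, medoid_ids) -> float:
    """Total distance from each sample to its nearest medoid."""
    idx = [list(dm.ids).index(m) for m in medoid_ids]
    return float(np.asarray(dm.data)[idx].min(axis=0).sum())


def calinski_harabasz(dm: DistanceMatrix, labels) -> float:
    """Calinski-Harabasz pseudo-F on the PCoA embedding of ``dm``.

    Computed over all positive-eigenvalue principal coordinates, the standard
    enterotype-tutorial practice.  A zero within-cluster dispersion returns a
    large finite sentinel instead of infinity.
    """
    labels = np.asarray(labels)
    n = len(dm.ids)
    k = len(np.unique(labels))
    if k < 2 or k >= n:
        raise ValueError("calinski_harabasz requires 2 <= k < n")
    coords = pcoa_positive_coordinates(dm)
    # within-cluster dispersion
    w = 0.0
    for g in np.unique(labels):
        sub = coords[labels == g]
        w += ((sub - sub.mean(axis=0)) ** 2).sum()
    if w <= 1e-30:
        return CH_INF_SENTINEL
    return float(_skl_metrics.calinski_harabasz_score(coords, labels))


def distance_pseudo_f(dm: DistanceMatrix, labels) -> float:
    """Distance-only pseudo-F (PERMANOVA-style) sensitivity alternative."""
    labels = np.asarray(labels)
    D2 = np.asarray(dm.data) ** 2
    n = len(labels)
    k = len(np.unique(labels))
    sst = D2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ssw += D2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssb = sst - ssw
    if ssw <= 1e-30:
        return CH_INF_SENTINEL
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def silhouette_mean(dm: DistanceMatrix, labels) -> float:
    """Mean silhouette width on the precomputed distances (singletons score 0)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least two clusters")
    return float(
        _skl_metrics.silhouette_samples(np.asarray(dm.data), labels,
                                        metric="precomputed").mean()
    )


@dataclass
class EnterotypeResults:
    """Fitted enterotype partition plus the model-selection profile."""

    k_best: int
    labels: pd.Series                      # sample id -> cluster id (0..k_best-1)
    medoids: list
    ch_profile: dict[int, float]           # k -> Calinski-Harabasz
    silhouette_profile: dict[int, float]   # k -> mean silhouette
    labels_by_k: dict[int, pd.Series] = field(default_factory=dict)

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def summary(self) -> str:
        lines = [
            "Enterotype model selection (PAM + Calinski-Harabasz)",
            "=" * 52,
            f"{'k':>3} {'CH':>12} {'silhouette':>11}",
        ]
        for k in sorted(self.ch_profile):
            mark = " <- best" if k == self.k_best else ""
            lines.append(f"{k:>3} {self.ch_profile[k]:>12.3f} "
                         f"{self.silhouette_profile[k]:>11.3f}{mark}")
        sizes = ", ".join(f"{c}:{s}" for c, s in self.cluster_sizes.items())
        lines.append(f"best k = {self.k_best}; cluster sizes {{{sizes}}}")
        lines.append(f"medoids: {', '.join(map(str, self.medoids))}")
        return "\n".join(lines)


class EnterotypeModel:
    """PAM/CH enterotype scan over a Bray-Curtis (or any) distance matrix.

    Parameters
    ----------
    dm : skbio.DistanceMatrix
        Pairwise sample dissimilarities (typically genus-level Bray-Curtis).
    """

    def __init__(self, dm: DistanceMatrix):
        self.dm = dm

    @classmethod
    def from_table(cls, table: AsvTable) -> "EnterotypeModel":
        return cls(bray_curtis(table))

    def fit(self, k_min: int = 2, k_max: int = 6, seed: int = 0,
            criterion: str = "ch_pcoa") -> EnterotypeResults:
        """Scan k in [k_min, k_max]; keep the k with the highest criterion.

        ``criterion`` is ``'ch_pcoa'`` (default) or ``'pseudo_f'`` (distance
        only).  CH ties break toward the smaller k.
        """
        n = len(self.dm.ids)
        if not 2 <= k_min <= k_max < n:
            raise ValueError("need 2 <= k_min <= k_max < n_samples")
        score = {"ch_pcoa": calinski_harabasz, "pseudo_f": distance_pseudo_f}[criterion]
        ch, sil, labs, meds = {}, {}, {}, {}
        for k in range(k_min, k_max + 1):
            labels, medoids = pam_cluster(self.dm, k, seed=seed)
            ch[k] = score(self.dm, labels)
            sil[k] = silhouette_mean(self.dm, labels)
            labs[k] = pd.Series(labels, index=list(self.dm.ids), name="cluster")
            meds[k] = medoids
        k_best = min(ch, key=lambda k: (-ch[k], k))
        return EnterotypeResults(
            k_best=k_best,
            labels=labs[k_best],
            medoids=meds[k_best],
            ch_profile=ch,
            silhouette_profile=sil,
            labels_by_k=labs,
        )


def select_k(dm: DistanceMatrix, k_min: int = 2, k_max: int = 6,
             seed: int = 0) -> EnterotypeResults:
    """Functional shorthand for ``EnterotypeModel(dm).fit(k_min, k_max, seed)``."""
    return EnterotypeModel(dm).fit(k_min=k_min, k_max=k_max, seed=seed)
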
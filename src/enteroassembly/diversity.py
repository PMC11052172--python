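"""Alpha diversity, Bray-Curtis, ordination, and group contrasts.

Shannon is reported in nats by default (``base=2`` available), "Simpson"
means the Gini-Simpson index 1 - sum(p^2) (inverse Simpson behind a flag),
matching common amplicon-pipeline conventions.  ANOSIM and the Mantel test
(see :mod:`enteroassembly.nullmodels`) are implemented with explicit seeded
permutation engines so reruns are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats import ordination as _skbio_ordination
from statsmodels.stats.multitest import multipletests

from .io import AsvTable


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame          # samples x axes
    eigenvalues: np.ndarray            # descending; may include negatives
    proportion_explained: np.ndarray   # over positive eigenvalues only


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    group_sizes: tuple
    adjusted_p: float | None = None
    name: str | None = None


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats unless ``base`` given)."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or (x < 0).any():
        raise ValueError("counts must be a non-negative vector")
    total = x.sum()
    if total <= 0:
        raise ValueError("zero total abundance")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def simpson(counts, inverse: bool = False) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (or inverse Simpson 1/sum p_i^2)."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or (x < 0).any():
        raise ValueError("counts must be a non-negative vector")
    total = x.sum()
    if total <= 0:
        raise ValueError("zero total abundance")
    p = x / total
    s = float((p**2).sum())
    return 1.0 / s if inverse else 1.0 - s


def alpha_diversity_table(table: AsvTable) -> pd.DataFrame:
    """Per-sample Shannon (nats) and Gini-Simpson indices."""
    rows = {
        s: {"shannon": shannon(table.counts.loc[s]), "simpson": simpson(table.counts.loc[s])}
        for s in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    x = table.values().astype(float)
    if (x.sum(axis=1) == 0).any():
        bad = [s for s, t in zip(table.sample_ids, x.sum(axis=1)) if t == 0]
        raise ValueError(f"all-zero samples: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinate analysis) of a distance matrix.

    Eigenvalues are returned in descending order including any negative ones
    (non-Euclidean distances); proportion explained is computed over the
    positive eigenvalues only.
    """
    import warnings as _warnings
    with _warnings.catch_warnings():
        # full-spectrum eigh and negative eigenvalues are expected for
        # non-Euclidean dissimilarities like Bray-Curtis
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_ordination.pcoa(dm, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    order = np.argsort(eig)[::-1]
    eig = eig[order]
    coords = res.samples.to_numpy()[:, order]
    pos = eig[eig > 1e-12]
    prop = np.where(eig > 1e-12, eig / pos.sum(), 0.0) if len(pos) else np.zeros_like(eig)
    k = len(eig) if n_axes is None else min(n_axes, len(eig))
    coords = pd.DataFrame(
        coords[:, :k], index=list(dm.ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coords, eig[:k], prop[:k])


def pcoa_positive_coordinates(dm: DistanceMatrix) -> np.ndarray:
    """Sample coordinates over all positive-eigenvalue axes (Euclidean embedding)."""
    res = pcoa(dm)
    keep = res.eigenvalues > 1e-12
    return res.coordinates.to_numpy()[:, keep]


def anosim(dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0) -> GroupTestResult:
    """Analysis of similarities: R = (rb - rw) / (M/2) with a label-permutation p.

    ``rb``/``rw`` are the mean ranks of between- and within-group distances,
    M = n(n-1)/2.  p = (1 + #{perm R >= obs R}) / (1 + n_perm), so p is never
    exactly 0.
    """
    labels = np.asarray(pd.Series(labels).loc[list(dm.ids)] if isinstance(labels, pd.Series)
                        else labels)
    n = len(dm.ids)
    if len(labels) != n:
        raise ValueError("labels length does not match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        raise ValueError(f"singleton group(s): {groups[counts < 2].tolist()}")
    condensed = squareform(dm.data, checks=False)
    ranks = stats.rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    denom = len(condensed) / 2.0

    def r_stat(lab):
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += r_stat(labels[rng.permutation(n)]) >= obs
    p = (1 + hits) / (1 + n_perm)
    return GroupTestResult(float(obs), float(p), tuple(counts), name="ANOSIM R")


def rank_sum_test(x, y) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exhaustive permutation enumeration when both samples have n <= 8 (exact
    even under ties); tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    if len(x) <= 8 and len(y) <= 8:
        if np.ptp(np.concatenate([x, y])) == 0:
            return GroupTestResult(float(len(x) * len(y) / 2), 1.0, (len(x), len(y)))
        res = stats.permutation_test(
            (x, y),
            lambda a, b, axis=-1: stats.mannwhitneyu(a, b, axis=axis,
                                                     method="asymptotic").statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
            vectorized=True,
        )
        return GroupTestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                               (len(x), len(y)))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupTestResult(float(res.statistic), float(res.pvalue), (len(x), len(y)))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def compare_taxa(table_rel: AsvTable, labels, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Per-taxon two-group rank-sum contrasts with BH correction.

    ``table_rel`` should be a relative-abundance table already aggregated at
    the desired taxonomic level (the BH family is that level's taxa).
    Returns a DataFrame with statistic, p, q, the enriched group, and a
    significance flag at ``fdr_alpha``.
    """
    lab = pd.Series(labels)
    lab = lab.loc[table_rel.sample_ids] if set(table_rel.sample_ids) <= set(lab.index) else lab
    groups = pd.unique(lab)
    if len(groups) != 2:
        raise ValueError("compare_taxa requires exactly two groups")
    g1 = table_rel.counts.loc[np.asarray(lab) == groups[0]]
    g2 = table_rel.counts.loc[np.asarray(lab) == groups[1]]
    records = []
    for taxon in table_rel.taxon_ids:
        a, b = g1[taxon].to_numpy(), g2[taxon].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = len(a) * len(b) / 2, 1.0
        else:
            r = rank_sum_test(a, b)
            stat, p = r.statistic, r.p_value
        records.append({
            "taxon": taxon,
            "statistic": stat,
            "p_value": p,
            "mean_" + str(groups[0]): a.mean(),
            "mean_" + str(groups[1]): b.mean(),
            "enriched_in": str(groups[0]) if a.mean() >= b.mean() else str(groups[1]),
        })
    out = pd.DataFrame.from_records(records).set_index("taxon")
    out["q_value"] = benjamini_hochberg(out["p_value"])
    out["significant"] = out["q_value"] < fdr_alpha
    return out
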
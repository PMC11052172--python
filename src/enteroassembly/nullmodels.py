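"""Phylogenetic and taxonomic null models of community assembly.

Implements the Stegen-style partitioning framework:

* beta mean nearest taxon distance (βMNTD), abundance-weighted;
* beta nearest taxon index (βNTI): z-score of observed βMNTD against a
  tip-label-shuffled null distribution;
* Raup-Crick index on Bray-Curtis (RC_bray): observed dissimilarity ranked
  within a null that preserves each sample's richness and total abundance
  while drawing species by metacommunity occupancy and individuals by
  metacommunity relative abundance, rescaled to [-1, 1];
* the five-process partition per sample pair: βNTI > +2 variable selection,
  βNTI < -2 homogeneous selection, otherwise RC > +0.95 dispersal
  limitation, RC < -0.95 homogenizing dispersal, else drift;
* seeded Mantel tests of assembly matrices against host/environment
  distance matrices.

Matrices with signed entries (βNTI, RC) are returned as labeled symmetric
:class:`pandas.DataFrame` objects with a zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .diversity import GroupTestResult
from .io import AsvTable, patristic_distance_matrix

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


def _relative(table: AsvTable) -> np.ndarray:
    x = table.values().astype(float)
    totals = x.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("all-zero samples present")
    return x / totals


def _taxon_distance(table: AsvTable, tree) -> np.ndarray:
    """Patristic distances among the table's taxa, in table column order."""
    if isinstance(tree, pd.DataFrame):
        return tree.loc[table.taxon_ids, table.taxon_ids].to_numpy()
    if isinstance(tree, dendropy.Tree):
        return patristic_distance_matrix(tree, table.taxon_ids).to_numpy()
    return np.asarray(tree, dtype=float)


def _betamntd_from_parts(rel: np.ndarray, D: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """βMNTD matrix given a taxon->tree-position mapping ``perm``."""
    n, _ = rel.shape
    supports = [np.flatnonzero(rel[k] > 0) for k in range(n)]
    # minvec[k][i] = distance from taxon i to its nearest taxon present in k
    minvecs = [D[perm][:, perm[supp]].min(axis=1) for supp in supports]
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            v = 0.5 * (rel[j] @ minvecs[k] + rel[k] @ minvecs[j])
            out[j, k] = out[k, j] = v
    return out


def beta_mntd(table_rel: AsvTable, tree) -> pd.DataFrame:
    """Abundance-weighted beta mean nearest taxon distance between samples.

    βMNTD(j,k) = 0.5 * [ sum_i f_ij * min_{i' in k} d(i,i')
                       + sum_i f_ik * min_{i' in j} d(i,i') ]
    with f relative abundances and d patristic distance.  ``tree`` may be a
    dendropy tree, a labeled patristic-distance DataFrame, or a raw matrix
    in table column order.
    """
    rel = _relative(table_rel)
    D = _taxon_distance(table_rel, tree)
    ids = table_rel.sample_ids
    obs = _betamntd_from_parts(rel, D, np.arange(D.shape[0]))
    return pd.DataFrame(obs, index=ids, columns=ids)


def beta_nti(table_rel: AsvTable, tree, n_rand: int = 999, seed: int = 0,
             return_observed: bool = False):
    """Beta nearest taxon index: z-score of βMNTD against a tip-shuffle null.

    The null permutes taxon identities across the tree tips (one global
    permutation of the whole table's taxon pool per randomization) and
    recomputes βMNTD.  βNTI(j,k) = (obs - mean_null) / sd_null.  Pairs with a
    degenerate null (sd 0) are recorded as 0.
    """
    rel = _relative(table_rel)
    D = _taxon_distance(table_rel, tree)
    ids = table_rel.sample_ids
    n = len(ids)
    t = D.shape[0]
    obs = _betamntd_from_parts(rel, D, np.arange(t))
    rng = np.random.default_rng(seed)
    null_sum = np.zeros((n, n))
    null_sq = np.zeros((n, n))
    for _ in range(n_rand):
        nb = _betamntd_from_parts(rel, D, rng.permutation(t))
        null_sum += nb
        null_sq += nb**2
    mean = null_sum / n_rand
    var = np.maximum(null_sq / n_rand - mean**2, 0.0)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 1e-12, (obs - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    np.fill_diagonal(z, 0.0)
    bnti = pd.DataFrame(z, index=ids, columns=ids)
    if return_observed:
        return bnti, pd.DataFrame(obs, index=ids, columns=ids)
    return bnti


def _null_community(rng, richness: int, total: int, occ_w: np.ndarray,
                    ab_w: np.ndarray) -> np.ndarray:
    """One null assemblage preserving richness and total abundance."""
    t = len(occ_w)
    with np.errstate(divide="ignore"):
        keys = np.log(occ_w) + rng.gumbel(size=t)  # weighted draw w/o replacement
    chosen = np.argpartition(-keys, richness - 1)[:richness]
    out = np.zeros(t, dtype=np.int64)
    out[chosen] = 1  # guarantee presence of every chosen species
    if total > richness:
        w = ab_w[chosen]
        w = w / w.sum() if w.sum() > 0 else np.full(richness, 1.0 / richness)
        out[chosen] += rng.multinomial(total - richness, w)
    return out


def raup_crick_bray(table: AsvTable, n_rand: int = 999, seed: int = 0) -> pd.DataFrame:
    """Raup-Crick index on Bray-Curtis, rescaled to [-1, 1].

    Per randomization each sample is reassembled from the metacommunity
    (species identity weighted by occupancy, individuals by pooled relative
    abundance) holding its observed richness and total count fixed; null
    Bray-Curtis dissimilarities are computed, and

        RC = ( #null < obs + 0.5 * #null == obs ) / n_rand, rescaled by
        (RC - 0.5) * 2.

    RC near +1: communities are more dissimilar than expected by chance; RC
    near -1: more similar.
    """
    from scipy.spatial.distance import pdist, squareform

    x = table.values().astype(np.int64)
    n, t = x.shape
    richness = (x > 0).sum(axis=1)
    if (richness == 0).any():
        bad = [s for s, r in zip(table.sample_ids, richness) if r == 0]
        raise ValueError(f"samples with zero richness: {bad}")
    totals = x.sum(axis=1)
    occ_w = (x > 0).mean(axis=0).astype(float)
    ab_w = x.sum(axis=0).astype(float)
    ab_w = ab_w / ab_w.sum()
    obs = squareform(pdist(x.astype(float), metric="braycurtis"))
    rng = np.random.default_rng(seed)
    less = np.zeros((n, n))
    equal = np.zeros((n, n))
    for _ in range(n_rand):
        null = np.array([
            _null_community(rng, int(richness[i]), int(totals[i]), occ_w, ab_w)
            for i in range(n)
        ], dtype=float)
        nbc = squareform(pdist(null, metric="braycurtis"))
        less += nbc < obs
        equal += np.isclose(nbc, obs)
    rc = ((less + 0.5 * equal) / n_rand - 0.5) * 2.0
    np.fill_diagonal(rc, 0.0)
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class AssemblyPartition:
    """Five-process summary over sample pairs."""

    fractions: dict[str, float]
    counts: dict[str, int]
    n_pairs: int
    group: str | None = None

    def summary(self) -> str:
        head = f"Assembly process partition{f' ({self.group})' if self.group else ''}"
        lines = [head, "=" * len(head)]
        for proc in PROCESSES:
            lines.append(f"{proc:<24} {100 * self.fractions[proc]:6.2f}%  "
                         f"({self.counts[proc]} pairs)")
        lines.append(f"{'total pairs':<24} {self.n_pairs}")
        return "\n".join(lines)


def classify_pair(bnti: float, rc: float) -> str:
    """Process label for one sample pair (Stegen convention)."""
    if bnti > 2:
        return "variable_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "drift"


def partition_processes(beta_nti_dm: pd.DataFrame, rc_dm: pd.DataFrame,
                        group: str | None = None,
                        beta_mntd_dm: pd.DataFrame | None = None,
                        ) -> tuple[pd.DataFrame, AssemblyPartition]:
    """Label every sample pair with its inferred assembly process.

    Returns the long-format pair table (sample_a, sample_b, beta_nti, rc,
    process, plus beta_mntd when given) and the five-fraction summary.
    """
    if list(beta_nti_dm.index) != list(rc_dm.index):
        raise ValueError("βNTI and RC matrices must share sample labels")
    ids = list(beta_nti_dm.index)
    rows = []
    for j in range(len(ids)):
        for k in range(j + 1, len(ids)):
            b = float(beta_nti_dm.iat[j, k])
            r = float(rc_dm.iat[j, k])
            row = {"sample_a": ids[j], "sample_b": ids[k], "beta_nti": b,
                   "rc_bray": r, "process": classify_pair(b, r)}
            if beta_mntd_dm is not None:
                row["beta_mntd"] = float(beta_mntd_dm.iat[j, k])
            rows.append(row)
    pairs = pd.DataFrame(rows)
    counts = {proc: int((pairs["process"] == proc).sum()) for proc in PROCESSES}
    n_pairs = len(pairs)
    fractions = {proc: counts[proc] / n_pairs for proc in PROCESSES}
    return pairs, AssemblyPartition(fractions, counts, n_pairs, group)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    return mat[iu, ju]


def _as_matrix(dm) -> tuple[np.ndarray, list]:
    if isinstance(dm, pd.DataFrame):
        return dm.to_numpy(dtype=float), list(dm.index)
    if hasattr(dm, "data") and hasattr(dm, "ids"):  # skbio DistanceMatrix
        return np.asarray(dm.data, dtype=float), list(dm.ids)
    arr = np.asarray(dm, dtype=float)
    return arr, list(range(arr.shape[0]))


def mantel(dm_a, dm_b, method: str = "pearson", n_perm: int = 999,
           seed: int = 0) -> GroupTestResult:
    """Mantel test between two labeled distance matrices.

    r correlates the upper-triangle entries; significance comes from jointly
    permuting rows and columns of the second matrix, two-sided on |r|:
    p = (1 + #{perm |r| >= |obs r|}) / (1 + n_perm).  Square the returned
    statistic for the r² scale some tools report.
    """
    a, ids_a = _as_matrix(dm_a)
    b, ids_b = _as_matrix(dm_b)
    if ids_a != ids_b:
        raise ValueError("distance matrices must share labels and order")
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    va = _upper(a)
    if method == "spearman":
        va = stats.rankdata(va)
    va = va - va.mean()
    denom_a = np.sqrt((va**2).sum())
    iu, ju = np.triu_indices(n, k=1)

    def corr_with(bmat_vec):
        vb = bmat_vec - bmat_vec.mean()
        den = denom_a * np.sqrt((vb**2).sum())
        return float(va @ vb / den) if den > 0 else 0.0

    vb_obs = b[iu, ju]
    if method == "spearman":
        vb_obs = stats.rankdata(vb_obs)
    obs = corr_with(vb_obs)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    vb_perm = b[perms[:, iu], perms[:, ju]]  # (n_perm, n_pairs)
    if method == "spearman":
        vb_perm = stats.rankdata(vb_perm, axis=1)
    vb_perm = vb_perm - vb_perm.mean(axis=1, keepdims=True)
    den = denom_a * np.sqrt((vb_perm**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = np.where(den > 0, vb_perm @ va / den, 0.0)
    p = (1 + int((np.abs(r_perm) >= abs(obs)).sum())) / (1 + n_perm)
    return GroupTestResult(obs, float(p), (n, n), name="mantel r")


def env_distance(metadata: pd.DataFrame, column: str) -> pd.DataFrame:
    """Pairwise absolute differences of a numeric metadata column."""
    if column not in metadata.columns:
        raise KeyError(f"no column {column!r} in metadata")
    v = metadata[column]
    missing = v[v.isna()].index.tolist()
    if missing:
        raise ValueError(f"missing {column!r} for samples: {missing}")
    arr = v.to_numpy(dtype=float)
    d = np.abs(arr[:, None] - arr[None, :])
    return pd.DataFrame(d, index=metadata.index, columns=metadata.index)


@dataclass
class AssemblyResults:
    """βMNTD/βNTI/RC matrices, per-pair processes, and the five fractions."""

    beta_mntd: pd.DataFrame
    beta_nti: pd.DataFrame
    rc_bray: pd.DataFrame
    pairs: pd.DataFrame
    partition: AssemblyPartition
    n_randomizations: int
    seed: int

    def summary(self) -> str:
        lines = [self.partition.summary(), ""]
        vals = _upper(self.beta_nti.to_numpy())
        lines.append(f"βNTI: mean {vals.mean():+.3f}, sd {vals.std():.3f}, "
                     f"|βNTI|>2 in {100 * (np.abs(vals) > 2).mean():.1f}% of pairs")
        vals = _upper(self.rc_bray.to_numpy())
        lines.append(f"RC_bray: mean {vals.mean():+.3f}, |RC|>0.95 in "
                     f"{100 * (np.abs(vals) > 0.95).mean():.1f}% of pairs")
        return "\n".join(lines)


class CommunityAssemblyModel:
    """Null-model assembly analysis of one sample group.

    Parameters
    ----------
    table : AsvTable
        Count table for the group (counts are needed by Raup-Crick; relative
        abundances for βMNTD are derived internally).
    tree : dendropy.Tree or patristic-distance DataFrame
        Phylogeny covering the table's taxa.

    Notes
    -----
    The table's full taxon set defines the metacommunity pool for the βNTI
    tip shuffle and the Raup-Crick draws.  When analysing one group of a
    larger study, keep the study-wide taxon columns (zeros included) so the
    null pool is the regional pool, the standard Stegen-style choice.
    """

    def __init__(self, table: AsvTable, tree, group: str | None = None):
        self.table = table
        self.tree = tree
        self.group = group

    def fit(self, n_rand: int = 999, seed: int = 0,
            rc_n_rand: int | None = None) -> AssemblyResults:
        bnti, bmntd = beta_nti(self.table, self.tree, n_rand=n_rand, seed=seed,
                               return_observed=True)
        rc = raup_crick_bray(self.table, n_rand=rc_n_rand or n_rand, seed=seed + 1)
        pairs, part = partition_processes(bnti, rc, group=self.group,
                                          beta_mntd_dm=bmntd)
        return AssemblyResults(bmntd, bnti, rc, pairs, part, n_rand, seed)
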
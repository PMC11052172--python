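"""Synthetic communities with known ground truth.

Generators emulate the statistical structure each downstream analysis
assumes, so the whole pipeline can be exercised end to end without any
sequencing data:

* ``simulate_enterotype_mixture`` — Dirichlet-multinomial mixture with one
  dominance-structured cluster (a *Lactobacillus*-like community, low
  evenness) and one diverse cluster (a *Muribaculaceae*-like community),
  the two-enterotype pattern seen in wild rodent guts.
* ``simulate_neutral`` — Sloan-neutral sampling: a skewed metacommunity and
  per-sample Dirichlet(Nm * p) compositions, giving each taxon the
  Beta(Nm*p_i, Nm*(1-p_i)) local relative-abundance marginal the neutral
  community model fits.
* ``simulate_selected`` — habitat filtering on a phylogeny: Brownian traits
  on a Yule tree and Gaussian environmental filtering, producing
  phylogenetically clustered (or divergent) communities detectable by the
  beta nearest taxon index.
* ``simulate_metadata`` — site structure with altitudes and host body
  measurements (length, weight, BMI).

All generators are pure functions of their arguments plus an integer seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import AsvTable, UNASSIGNED_GENUS

__all__ = [
    "GroundTruth",
    "simulate_tree",
    "brownian_traits",
    "simulate_enterotype_mixture",
    "simulate_neutral",
    "simulate_selected",
    "simulate_metadata",
    "simulate_taxonomy",
]


@dataclass
class GroundTruth:
    """Generator-specific truth, aligned with the generated sample/taxon ids."""

    labels: pd.Series | None = None            # enterotype mixture: true cluster per sample
    cluster_means: pd.DataFrame | None = None  # enterotype mixture: mean compositions
    Nm: float | None = None                    # neutral: true Nm
    metacommunity_p: pd.Series | None = None   # neutral: true metacommunity proportions
    traits: pd.Series | None = None            # selected: per-taxon trait values
    env: pd.Series | None = None               # selected: per-sample environment value
    extras: dict = field(default_factory=dict)


def _taxon_ids(n: int) -> list[str]:
    return [f"t{i + 1:04d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"s{i + 1:04d}" for i in range(n)]


def _geometric_series(n_taxa: int, decades: float) -> np.ndarray:
    """Normalized geometric abundance series spanning ``decades`` orders of
    magnitude from the most to the least abundant taxon — the skewed
    metacommunity shape the Sloan fit expects."""
    if n_taxa < 1:
        raise ValueError("n_taxa must be positive")
    ranks = np.arange(n_taxa)
    p = 10.0 ** (-decades * ranks / max(n_taxa - 1, 1))
    return p / p.sum()


def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) tree with unit birth rate and ``n_taxa`` leaves.

    Leaves are relabeled t0001... in a deterministic traversal order, so the
    newick string is a pure function of (n_taxa, seed).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    # assign ids in random order so label rank carries no topological signal
    labels = [f"t{i + 1:04d}" for i in range(n_taxa)]
    rng.shuffle(labels)
    for label, leaf in zip(labels, tree.leaf_node_iter()):
        leaf.taxon = ns.new_taxon(label)
    tree.update_taxon_namespace()
    return tree


def brownian_traits(tree: dendropy.Tree, sigma: float, seed: int) -> pd.Series:
    """Evolve a continuous trait by Brownian motion along the tree.

    Each branch adds a Normal(0, sigma^2 * branch_length) increment; the root
    starts at 0.  Returns tip values indexed by leaf label.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        parent = values[id(node.parent_node)]
        values[id(node)] = parent + rng.normal(0.0, sigma * np.sqrt(bl)) if bl > 0 else parent
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out).sort_index()


def simulate_enterotype_mixture(
    n_samples: int,
    n_taxa: int,
    depth: int,
    n_clusters: int = 2,
    concentration: float = 50.0,
    effect_size: float = 3.0,
    seed: int = 0,
) -> tuple[AsvTable, GroundTruth]:
    """Dirichlet-multinomial mixture over cluster-specific mean compositions.

    A shared skewed baseline composition is perturbed per cluster: cluster 1
    up-weights a tiny block of top-ranked taxa (dominance, low evenness — a
    *Lactobacillus*-like type) while later clusters up-weight broad blocks of
    mid-ranked taxa (diversity — a *Muribaculaceae*-like type).
    ``effect_size`` is the log-fold boost of a cluster's block; 0 makes all
    clusters identical.  ``concentration`` scales the Dirichlet and controls
    the sample-to-sample overdispersion real 16S tables show.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    base = _geometric_series(n_taxa, decades=3.0)

    # disjoint taxon blocks from the top of the baseline ranking: the first
    # cluster gets a near-singleton block (dominance), the rest broad blocks
    blocks: list[np.ndarray] = []
    start = 0
    for c in range(n_clusters):
        size = max(1, n_taxa // 200) if c == 0 else max(5, n_taxa // 10)
        blocks.append(np.arange(start, min(start + size, n_taxa)))
        start += size
    means = np.empty((n_clusters, n_taxa))
    for c, block in enumerate(blocks):
        m = base.copy()
        m[block] *= np.exp(effect_size)
        means[c] = m / m.sum()

    labels = np.repeat(np.arange(n_clusters), -(-n_samples // n_clusters))[:n_samples]
    rng.shuffle(labels)
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for i in range(n_samples):
        alpha = concentration * means[labels[i]]
        comp = rng.gamma(alpha)
        comp = comp / comp.sum()
        counts[i] = rng.multinomial(depth, comp)

    sids, tids = _sample_ids(n_samples), _taxon_ids(n_taxa)
    table = AsvTable(pd.DataFrame(counts, index=sids, columns=tids))
    truth = GroundTruth(
        labels=pd.Series(labels, index=sids, name="cluster"),
        cluster_means=pd.DataFrame(means, columns=tids),
    )
    return table, truth


def simulate_neutral(
    n_samples: int,
    n_taxa: int,
    depth: int,
    Nm: float,
    seed: int = 0,
    decades: float = 4.0,
) -> tuple[AsvTable, GroundTruth]:
    """Sloan-neutral communities: Dirichlet(Nm * p) compositions, multinomial reads.

    ``p`` is a normalized geometric series spanning ``decades`` orders of
    magnitude.  Under this scheme taxon i's local relative abundance has the
    Beta(Nm*p_i, Nm*(1-p_i)) marginal assumed by the neutral community model,
    so occupancy-abundance structure is neutral by construction and Nm is a
    recoverable ground truth.
    """
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    rng = np.random.default_rng(seed)
    p = _geometric_series(n_taxa, decades)
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for i in range(n_samples):
        comp = rng.gamma(Nm * p)
        total = comp.sum()
        if total == 0:  # pathological only for absurdly small Nm
            comp[rng.integers(n_taxa)] = 1.0
            total = 1.0
        counts[i] = rng.multinomial(depth, comp / total)
    sids, tids = _sample_ids(n_samples), _taxon_ids(n_taxa)
    table = AsvTable(pd.DataFrame(counts, index=sids, columns=tids))
    truth = GroundTruth(Nm=float(Nm), metacommunity_p=pd.Series(p, index=tids, name="p"))
    return table, truth


def simulate_selected(
    tree: dendropy.Tree,
    n_samples: int,
    depth: int,
    env_values,
    trait_sigma: float = 1.0,
    selection_strength: float = 0.0,
    seed: int = 0,
    base_decades: float = 2.0,
    concentration: float | None = None,
    traits: pd.Series | None = None,
) -> tuple[AsvTable, GroundTruth]:
    """Habitat filtering of phylogenetically conserved traits.

    A trait evolves by Brownian motion on ``tree``; sample ``s`` then weights
    taxon ``i`` by ``base_i * exp(-selection_strength * (trait_i - env_s)^2)``
    and draws reads multinomially.  With ``selection_strength=0`` this is a
    neutral draw from the base abundances.  A shared environment filters all
    samples into the same clades (phylogenetic clustering, negative beta-NTI
    pairs); divergent environments select divergent clades (positive pairs).

    ``concentration``, when given, draws each sample's composition from
    Dirichlet(concentration * weights) instead of using the weights directly,
    adding the drift-like presence turnover among the favored taxa that real
    filtered communities show (small values -> strong turnover).  ``traits``
    may be supplied (e.g. from :func:`brownian_traits`) to position the
    environment relative to the realized trait distribution; otherwise traits
    are evolved internally.
    """
    env = np.asarray(env_values, dtype=float)
    if env.ndim != 1 or len(env) != n_samples:
        raise ValueError("env_values must be a vector of length n_samples")
    rng = np.random.default_rng(seed)
    if traits is None:
        traits = brownian_traits(tree, trait_sigma, seed=int(rng.integers(2**31)))
    tids = list(traits.index)
    n_taxa = len(tids)
    # base abundances skewed but phylogeny-independent (random rank order)
    base = _geometric_series(n_taxa, base_decades)[rng.permutation(n_taxa)]
    t = traits.to_numpy()
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for s in range(n_samples):
        w = base * np.exp(-selection_strength * (t - env[s]) ** 2)
        total = w.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError("selection weights vanished; lower selection_strength")
        w = w / total
        if concentration is not None:
            comp = rng.gamma(concentration * w)
            if comp.sum() == 0:
                comp[np.argmax(w)] = 1.0
            w = comp / comp.sum()
        counts[s] = rng.multinomial(depth, w)
    sids = _sample_ids(n_samples)
    table = AsvTable(pd.DataFrame(counts, index=sids, columns=tids))
    truth = GroundTruth(traits=traits, env=pd.Series(env, index=sids, name="env"))
    return table, truth


def simulate_metadata(
    sample_ids,
    n_sites: int = 7,
    altitude_range: tuple[float, float] = (120.0, 838.0),
    bmi_mean: float = 3.3e-3,
    bmi_sd: float = 5e-4,
    seed: int = 0,
) -> pd.DataFrame:
    """Site assignments, altitudes, and host body measurements.

    Defaults mirror a small-rodent field survey: a handful of trapping sites
    whose elevations span roughly 120-840 m, body length ~95 mm, and BMI
    (weight / length^2, g/mm^2) around 3.3e-3.  Weight is derived from the
    drawn BMI and length so the three columns are exactly consistent.
    """
    sample_ids = list(sample_ids)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = altitude_range
    site_alt = rng.uniform(lo, hi, size=n_sites)
    site_of = rng.integers(0, n_sites, size=len(sample_ids))
    length = np.clip(rng.normal(95.0, 8.0, size=len(sample_ids)), 60.0, None)
    bmi = np.clip(rng.normal(bmi_mean, bmi_sd, size=len(sample_ids)), 1e-4, None)
    weight = bmi * length**2
    return pd.DataFrame(
        {
            "site": [f"S{j + 1}" for j in site_of],
            "altitude": site_alt[site_of],
            "body_length": length,
            "body_weight": weight,
            "bmi": bmi,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def simulate_taxonomy(taxon_ids, n_genera: int = 20, seed: int = 0,
                      unassigned_fraction: float = 0.02) -> pd.DataFrame:
    """Flat synthetic genus map for exercising genus aggregation."""
    taxon_ids = list(taxon_ids)
    rng = np.random.default_rng(seed)
    genera = np.array([f"g{j + 1:03d}" for j in rng.integers(0, n_genera, len(taxon_ids))],
                      dtype=object)
    mask = rng.random(len(taxon_ids)) < unassigned_fraction
    genera[mask] = UNASSIGNED_GENUS
    return pd.DataFrame({"genus": genera}, index=pd.Index(taxon_ids, name="taxon_id"))
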
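"""End-to-end orchestration: filter -> rarefy -> enterotype -> per-type analyses.

A :class:`PipelineConfig` (loadable from YAML) fully determines a run.  The
master seed deterministically derives a per-stage seed keyed by the stage
name, so adding a stage never perturbs earlier stages' random streams.  Each
stage writes its outputs (TSV/JSON with a ``#`` provenance header) before the
next stage starts; a :class:`RunRecord` collects wall times and file digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import networks as nw
from . import nullmodels as nm
from . import simulate as sim
from .enterotype import EnterotypeModel
from .io import (AsvTable, aggregate_by_genus, filter_low_abundance_asvs,
                 rarefy, read_metadata, read_taxonomy, read_tree, reconcile,
                 relative_abundance)
from .neutral import NeutralCommunityModel

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage-name-keyed child seed, stable across runs and stage additions."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    # inputs: either file paths...
    table_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    table_orientation: str = "samples"
    # ...or a simulation scenario
    scenario: str | None = None              # enterotype_mixture | neutral | selected
    n_samples: int = 94
    n_taxa: int = 300
    depth: int = 10000
    scenario_params: dict = field(default_factory=dict)
    # thresholds (canonical defaults)
    min_total: int = 5
    min_mean_rel: float = 1e-4
    rho_threshold: float = 0.6
    fdr_alpha: float = 0.05
    n_rand: int = 999
    n_perm: int = 999
    k_min: int = 2
    k_max: int = 6
    filter_before_rarefy: bool = True
    seed: int = 0
    output_dir: str = "enteroassembly_out"

    def validate(self) -> None:
        if self.k_min > self.k_max or self.k_min < 2:
            raise ValueError("need 2 <= k_min <= k_max")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0,1)")
        if self.rho_threshold < 0 or self.rho_threshold >= 1:
            raise ValueError("rho_threshold must be in [0,1)")
        if self.n_rand < 1 or self.n_perm < 1:
            raise ValueError("n_rand and n_perm must be positive")
        if self.min_total < 0 or self.min_mean_rel < 0:
            raise ValueError("thresholds must be non-negative")
        if self.scenario is None and self.table_path is None:
            raise ValueError("either a table_path or a simulation scenario is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunRecord:
    config: dict
    stage_seconds: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    stages_run: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _provenance(cfg: PipelineConfig, stage: str, seed: int | None = None) -> str:
    extra = f" seed={seed}" if seed is not None else ""
    return f"enteroassembly stage={stage} master_seed={cfg.seed}{extra}"


def _write_json(path: Path, obj, cfg: PipelineConfig, stage: str) -> None:
    payload = {"_provenance": _provenance(cfg, stage), **obj}
    path.write_text(json.dumps(payload, indent=2, default=float))


def _write_df(path: Path, df: pd.DataFrame, cfg: PipelineConfig, stage: str,
              seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_provenance(cfg, stage, seed)}\n")
        df.to_csv(fh, sep="\t")


def _load_inputs(cfg: PipelineConfig):
    """Read or simulate (table, taxonomy, tree, metadata, truth)."""
    if cfg.scenario is not None:
        seed = derive_seed(cfg.seed, "simulate")
        params = dict(cfg.scenario_params)
        tree = None
        if cfg.scenario == "enterotype_mixture":
            table, truth = sim.simulate_enterotype_mixture(
                cfg.n_samples, cfg.n_taxa, cfg.depth, seed=seed, **params)
        elif cfg.scenario == "neutral":
            table, truth = sim.simulate_neutral(
                cfg.n_samples, cfg.n_taxa, cfg.depth,
                Nm=params.pop("Nm", 2000.0), seed=seed, **params)
        elif cfg.scenario == "selected":
            tree = sim.simulate_tree(cfg.n_taxa, derive_seed(cfg.seed, "tree"))
            env = params.pop("env_values", None)
            if env is None:
                env = np.zeros(cfg.n_samples)
            table, truth = sim.simulate_selected(
                tree, cfg.n_samples, cfg.depth, env, seed=seed, **params)
        else:
            raise ValueError(f"unknown scenario {cfg.scenario!r}")
        if tree is None:
            tree = sim.simulate_tree(cfg.n_taxa, derive_seed(cfg.seed, "tree"))
        taxonomy = sim.simulate_taxonomy(table.taxon_ids,
                                         seed=derive_seed(cfg.seed, "taxonomy"))
        metadata = sim.simulate_metadata(table.sample_ids,
                                         seed=derive_seed(cfg.seed, "metadata"))
        return table, taxonomy, tree, metadata, truth
    table = AsvTable.read_tsv(cfg.table_path, orientation=cfg.table_orientation)
    taxonomy = read_taxonomy(cfg.taxonomy_path) if cfg.taxonomy_path else None
    tree = read_tree(cfg.tree_path) if cfg.tree_path else None
    metadata = read_metadata(cfg.metadata_path) if cfg.metadata_path else None
    return table, taxonomy, tree, metadata, None


def run_pipeline(cfg: PipelineConfig, labels: pd.Series | None = None) -> RunRecord:
    """Run the full analysis; outputs land under ``cfg.output_dir``.

    Unless ``labels`` is supplied, downstream per-group analyses (networks,
    neutral model, null models, Mantel) use the enterotypes discovered by the
    PAM/CH scan — enterotypes first, everything else per enterotype.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config=asdict(cfg))
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            record.stage_seconds[name] = round(time.time() - t0, 3)
            record.stages_run.append(name)
        return wrap

    state: dict = {}

    @stage("load")
    def _load():
        table, taxonomy, tree, metadata, truth = _load_inputs(cfg)
        state.update(table=table, taxonomy=taxonomy, tree=tree,
                     metadata=metadata, truth=truth)
        if truth is not None and truth.labels is not None:
            _write_df(out / "truth_labels.tsv", truth.labels.to_frame(), cfg, "load")

    @stage("preprocess")
    def _pre():
        table = state["table"]
        seed = derive_seed(cfg.seed, "rarefy")
        if cfg.filter_before_rarefy:
            table = filter_low_abundance_asvs(table, cfg.min_total)
            table = rarefy(table, seed=seed)
        else:
            table = rarefy(table, seed=seed)
            table = filter_low_abundance_asvs(table, cfg.min_total)
        state["asv_table"] = table.drop_empty_taxa()
        _write_df(out / "asv_table.tsv", state["asv_table"].counts, cfg,
                  "preprocess", seed)

    @stage("enterotype")
    def _entero():
        table = state["asv_table"]
        if state["taxonomy"] is not None:
            genus = aggregate_by_genus(table, state["taxonomy"])
        else:
            genus = table
        state["genus_table"] = genus
        dm = dv.bray_curtis(genus)
        state["bray_curtis"] = dm
        if labels is not None:
            state["labels"] = labels.loc[table.sample_ids]
            return
        res = EnterotypeModel(dm).fit(cfg.k_min, cfg.k_max,
                                      seed=derive_seed(cfg.seed, "pam"))
        state["enterotype"] = res
        state["labels"] = res.labels
        _write_df(out / "enterotype_labels.tsv", res.labels.to_frame(), cfg, "enterotype")
        profile = pd.DataFrame({"ch": res.ch_profile, "silhouette": res.silhouette_profile})
        profile.index.name = "k"
        _write_df(out / "enterotype_profile.tsv", profile, cfg, "enterotype")
        _write_json(out / "enterotype.json", {
            "k_best": res.k_best, "medoids": res.medoids,
            "cluster_sizes": res.cluster_sizes.to_dict(),
        }, cfg, "enterotype")

    @stage("diversity")
    def _div():
        genus = state["genus_table"]
        lab = state["labels"]
        alpha = dv.alpha_diversity_table(genus)
        alpha["enterotype"] = lab
        _write_df(out / "alpha_diversity.tsv", alpha, cfg, "diversity")
        dm = state["bray_curtis"]
        ano = dv.anosim(dm, lab, n_perm=cfg.n_perm,
                        seed=derive_seed(cfg.seed, "anosim"))
        ord_res = dv.pcoa(dm, n_axes=2)
        _write_df(out / "pcoa.tsv", ord_res.coordinates, cfg, "diversity")
        tests = {}
        if lab.nunique() == 2:
            g1, g2 = sorted(lab.unique())
            for metric in ("shannon", "simpson"):
                r = dv.rank_sum_test(alpha.loc[lab == g1, metric],
                                     alpha.loc[lab == g2, metric])
                tests[metric] = {"statistic": r.statistic, "p_value": r.p_value}
        _write_json(out / "diversity.json", {
            "anosim_r": ano.statistic, "anosim_p": ano.p_value,
            "alpha_tests": tests,
            "pcoa_proportion_explained": list(ord_res.proportion_explained[:2]),
        }, cfg, "diversity")
        state["anosim"] = ano

    def _per_group_tables():
        table = state["asv_table"]
        lab = state["labels"]
        for g in sorted(lab.unique()):
            yield str(g), table.subset_samples(lab[lab == g].index).drop_empty_taxa()

    @stage("networks")
    def _net():
        stats_all = {}
        for g, sub in _per_group_tables():
            rel = relative_abundance(sub)
            filt = nw.filter_for_network(rel, cfg.min_mean_rel)
            net = nw.spearman_edges(filt, cfg.rho_threshold, cfg.fdr_alpha)
            metrics = nw.network_metrics(net)
            stats_all[g] = {**metrics.as_dict(), "n_nodes": net.n_nodes,
                            "n_edges": net.n_edges}
            _write_df(out / f"network_edges_type{g}.tsv", net.edges, cfg, "networks")
        _write_json(out / "network_stats.json", stats_all, cfg, "networks")
        state["network_stats"] = stats_all

    @stage("ncm")
    def _ncm():
        fits = {}
        for g, sub in _per_group_tables():
            try:
                res = NeutralCommunityModel(sub).fit()
            except ValueError as exc:
                fits[g] = {"error": str(exc)}
                continue
            fits[g] = {"Nm": res.Nm, "m": res.m, "N": res.N, "R2": res.r_squared,
                       "fraction_within": res.fraction_within,
                       "fraction_above": res.fraction_above,
                       "fraction_below": res.fraction_below}
            _write_df(out / f"ncm_taxa_type{g}.tsv", res.taxa, cfg, "ncm")
            state.setdefault("ncm", {})[g] = res
        _write_json(out / "ncm.json", fits, cfg, "ncm")

    @stage("assembly")
    def _assembly():
        if state["tree"] is None:
            _write_json(out / "assembly.json", {"skipped": "no tree input"}, cfg,
                        "assembly")
            return
        results = {}
        table = state["asv_table"]
        lab = state["labels"]
        for g in map(str, sorted(lab.unique())):
            # keep study-wide taxon columns: the null pool is the regional pool
            sub = table.subset_samples(lab[lab.astype(str) == g].index)
            rec = reconcile(sub, state["tree"])
            model = nm.CommunityAssemblyModel(rec.table, rec.tree, group=g)
            res = model.fit(n_rand=cfg.n_rand,
                            seed=derive_seed(cfg.seed, f"assembly-{g}"))
            results[g] = {"fractions": res.partition.fractions,
                          "counts": res.partition.counts,
                          "n_pairs": res.partition.n_pairs}
            _write_df(out / f"assembly_pairs_type{g}.tsv", res.pairs, cfg, "assembly")
            state.setdefault("assembly", {})[g] = res
        _write_json(out / "assembly.json", results, cfg, "assembly")

    @stage("mantel")
    def _mantel():
        meta = state["metadata"]
        if meta is None or "assembly" not in state:
            _write_json(out / "mantel.json",
                        {"skipped": "needs metadata and assembly results"}, cfg, "mantel")
            return
        results = {}
        for g, res in state["assembly"].items():
            ids = list(res.beta_nti.index)
            sub_meta = meta.loc[ids]
            per_factor = {}
            for col in ("altitude", "body_length", "body_weight", "bmi"):
                if col not in sub_meta.columns:
                    continue
                env = nm.env_distance(sub_meta, col)
                r = nm.mantel(res.beta_nti, env, n_perm=cfg.n_perm,
                              seed=derive_seed(cfg.seed, f"mantel-{g}-{col}"))
                per_factor[col] = {"r": r.statistic, "r2": r.statistic**2,
                                   "p_value": r.p_value}
            results[g] = per_factor
        _write_json(out / "mantel.json", results, cfg, "mantel")

    for path in sorted(out.glob("*")):
        if path.is_file():
            record.digests[path.name] = _digest(path)
    record.to_json(out / "run_record.json")
    return record


def summarize_run(record: RunRecord, output_dir) -> str:
    """Plain-text report over a completed run's output directory."""
    out = Path(output_dir)
    if not out.exists() or not any(out.iterdir()):
        raise FileNotFoundError(f"no run outputs in {out}")

    def load(name):
        p = out / name
        if not p.exists():
            return None
        data = json.loads(p.read_text())
        data.pop("_provenance", None)
        return data

    lines = ["Enterotype & community-assembly run summary", "=" * 44]
    ent = load("enterotype.json")
    if ent:
        lines.append(f"Enterotypes: k_best={ent['k_best']}, "
                     f"sizes={ent['cluster_sizes']}, medoids={ent['medoids']}")
    else:
        lines.append("Enterotypes: (stage absent)")
    div = load("diversity.json")
    if div:
        lines.append(f"ANOSIM: R={div['anosim_r']:.3f}, p={div['anosim_p']:.4g}")
        for metric, t in div.get("alpha_tests", {}).items():
            lines.append(f"  {metric} rank-sum p={t['p_value']:.4g}")
    netstats = load("network_stats.json")
    if netstats:
        lines.append("Network topology (per enterotype):")
        header = ("diameter", "modularity", "clustering_coefficient",
                  "graph_density", "average_degree", "average_path_length")
        for g, s in netstats.items():
            vals = "  ".join(f"{k}={s[k]:.3f}" for k in header)
            lines.append(f"  type {g}: {vals}")
    ncm = load("ncm.json")
    if ncm:
        lines.append("Neutral community model (per enterotype):")
        for g, s in ncm.items():
            if "error" in s:
                lines.append(f"  type {g}: not fit ({s['error']})")
            else:
                lines.append(f"  type {g}: Nm={s['Nm']:.0f}, m={s['m']:.4f}, "
                             f"R2={s['R2']:.3f}, within-CI={100 * s['fraction_within']:.1f}%")
    asm = load("assembly.json")
    if asm is None or "skipped" in asm:
        lines.append("Assembly null models: skipped (no tree input)")
    else:
        lines.append("Assembly processes (per enterotype):")
        for g, s in asm.items():
            fr = s["fractions"]
            lines.append("  type {}: {}".format(
                g, ", ".join(f"{k}={100 * v:.1f}%" for k, v in fr.items())))
    man = load("mantel.json")
    if man and "skipped" not in man:
        lines.append("Mantel tests (βNTI vs factor distances):")
        for g, factors in man.items():
            for col, s in factors.items():
                lines.append(f"  type {g} ~ {col}: r={s['r']:.3f}, p={s['p_value']:.4g}")
    report = "\n".join(lines)
    (out / "summary.txt").write_text(report + "\n")
    return report
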
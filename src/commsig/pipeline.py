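"""End-to-end analysis pipeline with config, seed management and manifest.

Stage order: environmental clustering -> rarefied alpha diversity ->
beta diversity + ordination + group tests -> spatial patterns ->
nsNMF signatures -> taxon-subset re-analyses (trophic subsets and the
rare biosphere).  One master seed deterministically derives every stage
seed via a stable hash of the stage name, so disabling one stage never
shifts another's randomness.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import env as env_mod
from . import io as io_mod
from . import nmf as nmf_mod
from . import spatial as spatial_mod
from .containers import (
    AbundanceTable,
    SampleMetadata,
    TrophicMap,
    rare_biosphere,
    to_relative,
    trophic_subset,
)
from .phylo import patristic_distances

log = logging.getLogger("commsig")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run."""

    table_path: str = ""
    tree_path: str = ""
    metadata_path: str = ""
    trophic_map_path: str | None = None
    outdir: str = "commsig_out"
    # rarefaction / iteration settings
    alpha_depth: int = 25000
    alpha_iterations: int = 100
    consensus_depth: int = 20000
    consensus_iterations: int = 1000
    nri_nulls: int = 1000
    permanova_permutations: int = 999
    spatial_permutations: int = 999
    # NMF settings
    nmf_rank: int = 4
    nmf_runs: int = 200
    nmf_theta: float = 0.5
    # toggles
    run_env: bool = True
    run_alpha: bool = True
    run_beta: bool = True
    run_spatial: bool = True
    run_nmf: bool = True
    run_subsets: bool = True
    rare_threshold: float = 1e-4
    prune_tree: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha_depth, self.consensus_depth, self.alpha_iterations,
               self.consensus_iterations, self.nri_nulls, self.nmf_runs) < 1:
            raise ValueError("depths and iteration counts must be positive")
        if self.nmf_rank < 2:
            raise ValueError("NMF rank must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    stage_seeds: dict[str, int] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name mixed with
    the master seed, kept below 2**31."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _write_df(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)


def _beta_stage(
    table: AbundanceTable,
    tree: TreeNode,
    metadata: SampleMetadata,
    cfg: PipelineConfig,
    outdir: Path,
    prefix: str,
    manifest: RunManifest,
    consensus: bool = True,
) -> dict:
    seed = stage_seed(cfg.seed, f"beta:{prefix}")
    summary: dict = {}
    dms = {
        "bray_curtis": beta_mod.bray_curtis(table),
        "unweighted_unifrac": beta_mod.unifrac_unweighted(table, tree),
        "weighted_unifrac": beta_mod.unifrac_weighted(table, tree),
    }
    for name, dm in dms.items():
        p = outdir / f"{prefix}{name}.tsv"
        io_mod.write_distance_matrix(dm, p)
        manifest.outputs[f"{prefix}{name}"] = str(p)
    wuf = dms["weighted_unifrac"]
    ord_res = beta_mod.nmds(wuf, seed=seed)
    _write_df(ord_res.coordinates, outdir / f"{prefix}nmds.tsv", index_label="sample_id")
    manifest.outputs[f"{prefix}nmds"] = str(outdir / f"{prefix}nmds.tsv")
    summary["nmds_stress"] = ord_res.stress

    groups = metadata.groups
    per = beta_mod.permanova(wuf, groups, n_perm=cfg.permanova_permutations,
                             seed=stage_seed(cfg.seed, f"permanova:{prefix}"))
    summary["permanova"] = {"R2": per.r2, "F": per.pseudo_f, "p": per.p_value}
    try:
        f, p = beta_mod.permdisp(wuf, groups)
        summary["permdisp"] = {"F": f, "p": p}
    except ValueError as exc:
        summary["permdisp"] = {"error": str(exc)}

    dend = beta_mod.upgma(wuf)
    (outdir / f"{prefix}upgma.nwk").write_text(dend.to_newick())
    manifest.outputs[f"{prefix}upgma"] = str(outdir / f"{prefix}upgma.nwk")
    if consensus and table.has_integer_counts():
        depth = min(cfg.consensus_depth, int(table.sample_totals().min()))
        ct = beta_mod.consensus_upgma(
            table, tree, depth=depth, n_iter=cfg.consensus_iterations,
            seed=stage_seed(cfg.seed, f"consensus:{prefix}"),
        )
        (outdir / f"{prefix}upgma_consensus.nwk").write_text(ct.newick)
        manifest.outputs[f"{prefix}upgma_consensus"] = str(
            outdir / f"{prefix}upgma_consensus.nwk"
        )
    return summary


def _nri_stage(
    table: AbundanceTable, tree: TreeNode, metadata: SampleMetadata,
    cfg: PipelineConfig, prefix: str,
) -> pd.DataFrame:
    rel = to_relative(table)
    patristic = patristic_distances(tree, table.taxa_ids)
    rows = {}
    base = stage_seed(cfg.seed, f"nri:{prefix}")
    for j, sid in enumerate(rel.sample_ids):
        vec = rel.data[sid].to_numpy()
        if (vec > 0).sum() < 2:
            rows[sid] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = alpha_mod.nri(vec, patristic=patristic, n_null=cfg.nri_nulls,
                                seed=(base + j) % 2**31)
        rows[sid] = res.nri
    out = pd.DataFrame({"NRI": pd.Series(rows)})
    out["group"] = metadata.groups.reindex(out.index)
    return out


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute every enabled stage; returns (and writes) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg))
    table, tree, metadata = io_mod.load_dataset(
        cfg.table_path, cfg.tree_path, cfg.metadata_path, prune=cfg.prune_tree
    )
    trophic = (
        io_mod.read_trophic_map(cfg.trophic_map_path)
        if cfg.trophic_map_path
        else None
    )

    def run_stage(name: str, enabled: bool, fn) -> None:
        if not enabled:
            return
        t0 = time.perf_counter()
        seed = stage_seed(cfg.seed, name)
        manifest.stage_seeds[name] = seed
        try:
            fn()
        except Exception as exc:
            manifest.save(outdir / "manifest.json")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest.stage_seconds[name] = dt
        log.info("stage=%s elapsed=%.2fs seed=%d", name, dt, seed)

    # -- environmental clustering ------------------------------------
    def env_stage() -> None:
        z = env_mod.zscore(metadata)
        _write_df(z.values, outdir / "env_zscores.tsv", index_label="sample_id")
        dm = env_mod.euclidean_distance(z)
        io_mod.write_distance_matrix(dm, outdir / "env_distance.tsv")
        dend = env_mod.hclust_complete(dm)
        (outdir / "env_dendrogram.nwk").write_text(dend.to_newick())
        manifest.outputs["env_zscores"] = str(outdir / "env_zscores.tsv")
        manifest.outputs["env_distance"] = str(outdir / "env_distance.tsv")
        manifest.outputs["env_dendrogram"] = str(outdir / "env_dendrogram.nwk")

    run_stage("env", cfg.run_env, env_stage)

    # -- alpha diversity ----------------------------------------------
    def alpha_stage() -> None:
        depth = min(cfg.alpha_depth, int(table.sample_totals().min()))
        res = alpha_mod.rarefied_alpha(
            table, tree, depth=depth, n_iter=cfg.alpha_iterations,
            seed=stage_seed(cfg.seed, "alpha"),
        )
        _write_df(res.summary, outdir / "alpha.tsv", index_label="sample_id")
        manifest.outputs["alpha"] = str(outdir / "alpha.tsv")
        manifest.summary["alpha_depth"] = depth
        manifest.summary["mean_PD"] = float(res.summary["PD"].mean())
        manifest.summary["mean_SR"] = float(res.summary["SR"].mean())
        nri_df = _nri_stage(table, tree, metadata, cfg, "full")
        _write_df(nri_df, outdir / "nri.tsv", index_label="sample_id")
        manifest.outputs["nri"] = str(outdir / "nri.tsv")

    run_stage("alpha", cfg.run_alpha, alpha_stage)

    # -- beta diversity ------------------------------------------------
    def beta_stage() -> None:
        manifest.summary["beta"] = _beta_stage(
            table, tree, metadata, cfg, outdir, "", manifest
        )

    run_stage("beta", cfg.run_beta, beta_stage)

    # -- spatial -------------------------------------------------------
    def spatial_stage() -> None:
        geo = spatial_mod.geographic_distances(metadata)
        io_mod.write_distance_matrix(geo, outdir / "geographic_km.tsv")
        wuf = beta_mod.unifrac_weighted(table, tree)
        decay = spatial_mod.distance_decay(
            wuf, geo, n_perm=cfg.spatial_permutations,
            seed=stage_seed(cfg.seed, "decay"),
        )
        res = spatial_mod.mrm(
            wuf, geo, names=["geographic_km"], n_perm=cfg.spatial_permutations,
            seed=stage_seed(cfg.seed, "mrm"),
        )
        manifest.outputs["geographic_km"] = str(outdir / "geographic_km.tsv")
        manifest.summary["distance_decay"] = {
            "slope_per_km": decay.slope_per_km,
            "pseudo_r2": decay.pseudo_r2,
            "p": decay.p_value,
        }
        manifest.summary["mrm"] = {
            "R2": res.r2, "F": res.f_statistic, "p": res.f_p_value,
        }

    run_stage("spatial", cfg.run_spatial, spatial_stage)

    # -- NMF signatures -------------------------------------------------
    def nmf_stage() -> None:
        nz = table.data.loc[table.taxon_totals() > 0]
        V = AbundanceTable(nz)
        run = nmf_mod.nsnmf_best_of(
            V, cfg.nmf_rank, n_runs=cfg.nmf_runs, theta=cfg.nmf_theta,
            seed=stage_seed(cfg.seed, "nmf"),
        )
        model = run.best
        _write_df(model.W, outdir / "nmf_basis.tsv", index_label="taxon_id")
        _write_df(model.H, outdir / "nmf_coefficients.tsv", index_label="descriptor")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idx = nmf_mod.asv_index(V, model)
        _write_df(idx.to_frame(), outdir / "asv_index.tsv", index=False)
        sigs = nmf_mod.select_signatures(idx)
        _write_df(sigs.to_frame(), outdir / "signatures.tsv", index=False)
        manifest.outputs["nmf_basis"] = str(outdir / "nmf_basis.tsv")
        manifest.outputs["nmf_coefficients"] = str(outdir / "nmf_coefficients.tsv")
        manifest.outputs["asv_index"] = str(outdir / "asv_index.tsv")
        manifest.outputs["signatures"] = str(outdir / "signatures.tsv")
        manifest.summary["nmf"] = {
            "best_objective": model.objective,
            "run_agreement": run.agreement,
            "n_signatures": {k: len(v) for k, v in sigs.signatures.items()},
        }

    run_stage("nmf", cfg.run_nmf, nmf_stage)

    # -- subsets --------------------------------------------------------
    def subsets_stage() -> None:
        subsets: dict[str, AbundanceTable] = {}
        if trophic is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for label in ("chloroplast_containing", "heterotroph"):
                    subsets[label] = trophic_subset(table, trophic, label)
        subsets["rare"] = rare_biosphere(table, cfg.rare_threshold)
        for name, sub in subsets.items():
            occupied = sub.data.columns[sub.sample_totals() > 0]
            sub = sub.select_samples(occupied)
            sub = AbundanceTable(sub.data.loc[sub.taxon_totals() > 0])
            if sub.n_taxa < 3 or sub.n_samples < 3:
                manifest.summary[f"subset_{name}"] = {"skipped": "too few taxa/samples"}
                continue
            subtree = tree.shear(sub.taxa_ids)
            subtree.prune()
            meta_sub = metadata.subset(sub.sample_ids)
            stats = _beta_stage(sub, subtree, meta_sub, cfg, outdir,
                                f"{name}_", manifest, consensus=False)
            nri_df = _nri_stage(sub, subtree, meta_sub, cfg, name)
            _write_df(nri_df, outdir / f"{name}_nri.tsv", index_label="sample_id")
            manifest.outputs[f"{name}_nri"] = str(outdir / f"{name}_nri.tsv")
            stats["mean_nri_by_group"] = (
                nri_df.groupby("group")["NRI"].mean().to_dict()
            )
            manifest.summary[f"subset_{name}"] = stats

    run_stage("subsets", cfg.run_subsets, subsets_stage)

    manifest.save(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    return manifest
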
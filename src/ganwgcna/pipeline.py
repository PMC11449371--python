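"""End-to-end orchestration: ingest -> train -> simulate -> network ->
trait alignment -> serial/rescued DEG -> enrichment, with a manifest and
stage-level resumability.

Each stage writes its artifacts into a named subdirectory of the output
directory and records a summary in ``manifest.json``. A rerun skips stages
whose outputs already exist, so deleting one stage's directory re-executes
only that stage and the ones after it that depend on it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import data_io, gan, rdeg, temporal, trajectory, wgcna
from .data_io import ExpressionMatrix, TraitTable

log = logging.getLogger(__name__)

STAGES = ("ingest", "train", "simulate", "wgcna", "align", "rdeg", "enrich")


@dataclass
class PipelineConfig:
    expr_path: str | None = None
    meta_path: str | None = None
    traits_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "ganwgcna_out"
    normalize: str = "none"  # "log-cpm" or "none"
    augment_fold: int = 10
    seed: int = 0
    region: str | None = None
    gan: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    fc_threshold: float = rdeg.FC_THRESHOLD
    p_threshold: float = rdeg.P_THRESHOLD
    edge_threshold: float = temporal.EDGE_THRESHOLD
    pvalue_cutoff: float = 0.05
    cutoff_size: int = 50

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return PipelineConfig(**payload)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    X: ExpressionMatrix | None = None,
    traits: TraitTable | None = None,
    gene_sets: data_io.GeneSetCollection | None = None,
) -> dict:
    """Run every stage for one region and return the manifest.

    Inputs may be passed in memory (synthetic fixtures) or read from the
    paths in the config. Completed stages (their artifact directories
    already present) are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"seed": config.seed, "region": config.region, "stages": {}, "inputs": {}}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())

    def done(stage: str) -> bool:
        return (out / stage / ".complete").exists()

    def finish(stage: str, summary: dict) -> None:
        (out / stage).mkdir(parents=True, exist_ok=True)
        (out / stage / ".complete").touch()
        manifest["stages"][stage] = summary
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
        log.info("stage %s complete: %s", stage, summary)

    # ---- ingest ----------------------------------------------------------
    if X is None:
        if config.expr_path is None:
            raise ValueError("either pass X in memory or set expr_path")
        manifest["inputs"]["expr_sha"] = _hash_file(config.expr_path)
        if config.normalize == "log-cpm":
            counts = pd.read_csv(config.expr_path, sep="\t", index_col=0)
            meta = pd.read_csv(config.meta_path, sep="\t").set_index("sample_id")
            X = data_io.log_cpm(
                counts, meta["group"], meta.get("region")
            )
        else:
            X = data_io.read_expression(config.expr_path, meta_path=config.meta_path)
    if traits is None and config.traits_path:
        traits = data_io.read_traits(config.traits_path)
    if gene_sets is None and config.gmt_path:
        gene_sets = data_io.read_gene_sets(config.gmt_path)
    if config.region is not None and X.region is not None:
        keep = [s for s in X.sample_ids if X.region[s] == config.region]
        X = ExpressionMatrix(
            values=X.values[keep],
            sample_group=X.sample_group[keep],
            region=X.region[keep],
        )
    if not done("ingest"):
        X.require_two_groups()
        (out / "ingest").mkdir(parents=True, exist_ok=True)
        X.to_tsv(out / "ingest" / "expression.tsv")
        finish("ingest", {"n_genes": X.n_genes, "n_samples": X.n_samples})

    # ---- train -----------------------------------------------------------
    gan_cfg = gan.GanConfig(seed=config.seed, **config.gan)
    if not done("train"):
        X_aug = data_io.linear_augment(X, fold=config.augment_fold, seed=config.seed)
        result = gan.train(X_aug, gan_cfg)
        result.save(out / "train")
        finish(
            "train",
            {
                "n_checkpoints": len(result.checkpoints),
                "n_train_samples": X_aug.n_samples,
                "final_critic_loss": float(result.history.critic_loss.iloc[-1]),
            },
        )
    checkpoints = gan.TrainResult.load_checkpoints(out / "train")

    # ---- simulate --------------------------------------------------------
    sim_cfg = trajectory.SimulationConfig(seed=config.seed, **config.simulate)
    if not done("simulate"):
        stack = trajectory.average_profile(checkpoints, X, sim_cfg)
        stack.save(out / "simulate")
        finish(
            "simulate",
            {
                "n_repeats": stack.n_repeats,
                "n_timesteps": stack.n_timesteps,
                "n_candidates": sim_cfg.n_candidates,
                "k_nearest": sim_cfg.k,
                "min_achieved_r": float(stack.fake_log.achieved_r.min()),
            },
        )
    stack = trajectory.TrajectoryStack.load(out / "simulate")
    profile = stack.averaged_profile()

    # ---- wgcna -----------------------------------------------------------
    net_cfg = wgcna.NetworkConfig(**config.network)
    if not done("wgcna"):
        kept = wgcna.drop_constant_genes(profile, net_cfg.variance_tol)
        beta, fit_table = wgcna.pick_soft_threshold(kept, net_cfg)
        A = wgcna.adjacency(kept, beta, net_cfg.network_type)
        T = wgcna.tom(A)
        assignment = wgcna.detect_modules(T, kept.columns, net_cfg)
        # unassessed genes (constant over time) are module 0
        full = assignment.labels.reindex(profile.columns, fill_value=0)
        assignment = wgcna.ModuleAssignment(labels=full.astype(int))
        (out / "wgcna").mkdir(parents=True, exist_ok=True)
        assignment.to_tsv(out / "wgcna" / "modules.tsv")
        fit_table.to_csv(out / "wgcna" / "soft_threshold.tsv", sep="\t", index=False)
        prof_eig = wgcna.eigengene(profile[assignment.labels.index], assignment)
        prof_eig.eigengenes.to_csv(out / "wgcna" / "eigengenes_sim.tsv", sep="\t")
        finish(
            "wgcna",
            {"beta": beta, "n_modules": len(assignment.module_ids),
             "module_sizes": {int(k): int(v) for k, v in assignment.sizes().items()}},
        )
    assignment = wgcna.ModuleAssignment(
        labels=pd.read_csv(out / "wgcna" / "modules.tsv", sep="\t", index_col=0)["module"]
    )
    assignment.labels.index = assignment.labels.index.map(str)
    sim_eig = wgcna.eigengene(profile, assignment)

    # ---- align -----------------------------------------------------------
    if not done("align"):
        results = wgcna.module_trait_alignment(
            assignment, X, traits, sim_loadings=sim_eig.loadings, region=config.region
        )
        frame = wgcna.trait_results_frame(results)
        net = (
            temporal.module_network(sim_eig.eigengenes, config.edge_threshold)
            if len(assignment.module_ids) >= 2
            else None
        )
        (out / "align").mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "align" / "module_trait.tsv", sep="\t", index=False)
        if net is not None:
            groups = temporal.cluster_modules(net)
            net.nodes["group"] = net.nodes.module.map(groups)
            net.save(out / "align" / "nodes.tsv", out / "align" / "edges.tsv")
        finish(
            "align",
            {
                "n_passing": int(frame.passes.sum()),
                "n_positive": int((frame.passes & (frame.Corr > 0)).sum()),
                "n_negative": int((frame.passes & (frame.Corr < 0)).sum()),
            },
        )

    # ---- rdeg ------------------------------------------------------------
    if not done("rdeg"):
        serial = rdeg.serial_deg(
            stack.values, stack.gene_ids, config.fc_threshold, config.p_threshold
        )
        endpoint = rdeg.conventional_deg(X, config.fc_threshold, config.p_threshold)
        table = rdeg.rescue(serial, endpoint)
        (out / "rdeg").mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "rdeg" / "rdeg.tsv", sep="\t")
        finish(
            "rdeg",
            {
                "n_conventional": int(table.conventional_deg.sum()),
                "n_rdeg": int(table.rdeg.sum()),
                "n_rescued": int(table.rescued.sum()),
            },
        )

    # ---- enrich ----------------------------------------------------------
    if not done("enrich"):
        (out / "enrich").mkdir(parents=True, exist_ok=True)
        if gene_sets is not None:
            from . import enrichment as enr

            universe = set(X.gene_ids)
            results = {}
            for m in assignment.module_ids:
                res = enr.enrich_module(
                    assignment.genes_of(m), gene_sets, universe, config.cutoff_size
                )
                prim = enr.primary_term(
                    assignment.genes_of(m), gene_sets, universe,
                    config.pvalue_cutoff, config.cutoff_size,
                )
                if prim is not None:
                    for r in res:
                        r.is_primary = r.term_id == prim.term_id
                results[m] = res
            frame = enr.enrichment_frame(results)
            frame.to_csv(out / "enrich" / "enrichment.tsv", sep="\t", index=False)
            n_primary = int(frame.is_primary.sum())
        else:
            n_primary = 0
        finish("enrich", {"n_primary_terms": n_primary, "had_gene_sets": gene_sets is not None})

    manifest = json.loads(manifest_path.read_text())
    return manifest


def report(manifest: dict | str | Path) -> str:
    """Human-readable Markdown summary of a (possibly partial) pipeline run."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    stages = manifest.get("stages", {})
    region = manifest.get("region") or "all"
    lines = [f"# Pipeline report (region: {region})", ""]
    missing = [s for s in STAGES if s not in stages]
    if missing:
        lines.append(f"**Partial run** - missing stages: {', '.join(missing)}")
        lines.append("")
    for stage in STAGES:
        if stage not in stages:
            continue
        lines.append(f"## {stage}")
        for k, v in stages[stage].items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    align = stages.get("align")
    if align is not None:
        if align["n_passing"] == 0:
            lines.append("No modules passed the trait-correlation criteria.")
        else:
            lines.append(
                f"{align['n_passing']} module(s) passed the trait criteria "
                f"({align['n_positive']} positive / {align['n_negative']} negative)."
            )
    return "\n".join(lines)
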
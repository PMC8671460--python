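"""Configured end-to-end pipeline over the analysis stages.

``run_pipeline`` executes ingest -> calibration -> activity -> MOA landscape
-> clustering/embedding -> differential sensitivity -> biomarker discovery
-> enrichment on either a synthetic screen (with planted truth, for
self-checks) or user-supplied screen files, writing plain TSV/JSON outputs
plus a log into a run directory.  Every output carries the hash of the
configuration that produced it; deterministic stages are bit-identical
across reruns and stochastic stages are seeded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, biomarker, calibrate, cluster, diffsens, gsea, screenio, synth

__all__ = ["PipelineConfig", "run_pipeline", "REQUIRED_REPRODUCE_FILES"]

log = logging.getLogger("prismscreen")

#: Screen files the full-data reproduction recipe expects in ``data_dir``.
REQUIRED_REPRODUCE_FILES = (
    "primary_replicate_collapsed_logfold_change.csv",
    "primary-screen-cell-line-info.csv",
    "compound_annotations.csv",
    "CCLE_expression.csv",
)


@dataclass
class PipelineConfig:
    """All pipeline thresholds and settings, round-trippable through YAML."""

    synthetic: bool = True
    data_dir: str | None = None
    lineage: str | None = None
    cutoff: float = -1.0
    min_lines: int = 3
    alpha: float = 0.01
    perplexity: float = 30.0
    learning_rate: float = 100.0
    tsne_runs: int = 10
    tsne_max_iter: int = 500
    knn_k: int = 10
    knn_min_frac: float = 0.5
    deg_q_cutoff: float = 0.05
    gsea_n_perm: int = 1000
    gsea_mode: str | None = None
    gsea_fdr: float = 0.25
    seed: int = 0
    # synthetic-screen study conditions
    n_compounds: int = synth.DEFAULT_N_COMPOUNDS
    n_lines: int = synth.DEFAULT_N_LINES
    frac_active: float = synth.DEFAULT_FRAC_ACTIVE
    effect_mu: float = synth.DEFAULT_EFFECT_MU
    noise_sd: float = synth.DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.deg_q_cutoff < 1:
            raise ValueError("alpha and deg_q_cutoff must be in (0, 1)")
        if self.min_lines < 1 or self.tsne_runs < 1:
            raise ValueError("min_lines and tsne_runs must be >= 1")
        if not 0 < self.knn_min_frac <= 1:
            raise ValueError("knn_min_frac must be in (0, 1]")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_real_screen(config: PipelineConfig) -> screenio.DrugResponseMatrix:
    data_dir = Path(config.data_dir or ".")
    missing = [f for f in REQUIRED_REPRODUCE_FILES[:3] if not (data_dir / f).exists()]
    if missing:
        raise FileNotFoundError(
            "reproduce mode requires the pinned screen files in "
            f"{data_dir}: missing " + ", ".join(missing)
        )
    return screenio.read_logfc_matrix(
        data_dir / REQUIRED_REPRODUCE_FILES[0],
        data_dir / REQUIRED_REPRODUCE_FILES[1],
        data_dir / REQUIRED_REPRODUCE_FILES[2],
        lineage=config.lineage,
    )


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage under ``config`` and write outputs into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    chash = config.config_hash()
    try:
        log.info("config hash %s", chash)
        log.info("settings in force: %s", json.dumps(dataclasses.asdict(config), default=str))
        config.to_yaml(outdir / "config.yaml")

        truth = None
        if config.synthetic:
            drm, truth = synth.generate_screen(
                n_compounds=config.n_compounds,
                n_lines=config.n_lines,
                frac_active=config.frac_active,
                effect_mu=config.effect_mu,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
            truth.to_json(outdir / "truth.json")
        else:
            drm = _load_real_screen(config)
        log.info("screen matrix: %d compounds x %d lines", *drm.shape)

        # calibration: biomarker-conditioned drug (synthetic) or first compound
        cal_values, cal_labels = _calibration_series(drm, truth, config)
        if cal_values is not None:
            curve = calibrate.youden_scan(cal_values, cal_labels)
            curve.as_frame().to_csv(outdir / "calibration_curve.tsv", sep="\t", index=False)
            log.info("chosen threshold %.3f", curve.chosen_threshold)

        calls = activity.call_activity(drm, config.cutoff, config.min_lines)
        activity.calls_to_frame(calls).to_csv(outdir / "activity_calls.tsv", sep="\t")
        landscape = activity.moa_landscape(calls, drm.compound_info, min_active_per_moa=1)
        landscape.to_csv(outdir / "moa_landscape.tsv", sep="\t")
        n_active = sum(c.is_active for c in calls)
        log.info("%d active of %d compounds", n_active, len(calls))

        active_ids = [c.compound_id for c in calls if c.is_active]
        if len(active_ids) >= 10:
            dist = cluster.spearman_distance(drm.values.loc[active_ids], axis="compounds")
            dendro = cluster.hcluster(dist)
            (outdir / "compound_dendrogram.nwk").write_text(cluster.to_newick(dendro))
            perpl = min(config.perplexity, max(2.0, (len(active_ids) - 1) / 3))
            emb = cluster.tsne_runs(
                dist,
                perplexity=perpl,
                learning_rate=config.learning_rate,
                n_runs=config.tsne_runs,
                max_iter=config.tsne_max_iter,
            )
            for i, run in enumerate(emb.runs):
                run.to_csv(outdir / f"tsne_run{i + 1}.tsv", sep="\t")
            if drm.compound_info is not None and "moa" in drm.compound_info.columns:
                moa = drm.compound_info.loc[active_ids, "moa"]
                reference = {c: m for c, m in moa.items() if m not in (None, "unannotated")}
                queries = [c for c in active_ids if c not in reference]
                if reference and queries:
                    k = min(config.knn_k, len(reference))
                    assigns = cluster.consistent_proximity(
                        emb, queries, reference, k=k, min_frac=config.knn_min_frac
                    )
                    pd.DataFrame(
                        {
                            "query": [a.query_id for a in assigns],
                            "assigned_moa": [a.assigned_moa for a in assigns],
                            "supporting_runs": [a.supporting_runs for a in assigns],
                        }
                    ).to_csv(outdir / "moa_assignments.tsv", sep="\t", index=False)

        if config.synthetic:
            dm, selective, in_ids, out_ids = synth.generate_differential_screen(
                n_compounds=min(config.n_compounds, 500),
                n_selective=25,
                seed=config.seed + 1,
            )
            hits = diffsens.two_class_compare(dm, in_ids, out_ids, alpha=config.alpha)
            diffsens.hits_to_frame(hits).to_csv(outdir / "differential_hits.tsv", sep="\t")

            lines = drm.line_ids
            expr, etruth = synth.generate_expression(
                n_genes=2000, lines=lines, group_a=lines[:6], seed=config.seed + 2
            )
            degs = biomarker.moderated_t_test(expr, lines[:6], lines[6:12])
            biomarker.degs_to_frame(degs).to_csv(outdir / "deg.tsv", sep="\t")
            sets = dict(etruth.enriched_sets)
            sets.update(synth.random_gene_sets(list(expr.index), 10, 40, seed=config.seed + 3))
            results = gsea.permutation_significance(
                expr,
                lines[:6],
                lines[6:12],
                sets,
                n_perm=max(100, min(config.gsea_n_perm, 1000)),
                mode=config.gsea_mode,
                seed=config.seed + 4,
            )
            gsea.results_to_frame(results).to_csv(outdir / "gsea.tsv", sep="\t")

        manifest = {
            "config_hash": chash,
            "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "run.log"),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.info("pipeline complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


def _calibration_series(drm, truth, config):
    """Pick a (values, labels) pair for threshold calibration, if one exists."""
    if truth is not None and truth.biomarker_label.nunique() == 2 and truth.active_compounds:
        drug = sorted(truth.active_compounds)[0]
        return drm.values.loc[drug], truth.biomarker_label
    if drm.line_info is not None and "biomarker" in drm.line_info.columns:
        labels = drm.line_info["biomarker"].astype(int)
        if labels.nunique() == 2 and len(drm.values):
            return drm.values.iloc[0], labels
    return None, None
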
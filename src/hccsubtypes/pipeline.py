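"""End-to-end orchestration: simulate → preprocess → subtype → validate →
score → regulons → composition, with plain-file artifacts and a run manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import (CohortGrouping, DistanceSummary, composition_table,
                          distance_summary, group_cohort)
from .io import write_gmt, write_mtx_bundle, write_report
from .nmf import ConcordanceReport, NMFConfig, resample_concordance
from .preprocess import (PreprocessConfig, cluster_graph, normalize_log1p_cp10k,
                         pca, qc_filter, select_hvgs)
from .regulons import RegulonConfig, RegulonAUCScorer, make_pseudocells, rss
from .scoring import ScoringConfig, assign_subtype_by_score, mean_z_score, score_subtypes
from .simulate import SynthConfig, SyntheticTruth, generate_cohort, save_cohort
from .subtypes import (hcluster_merge, mean_profiles, rank_markers,
                       spearman_matrix, top_sd_genes)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "subtype", "nmf_validate", "score",
          "regulons", "composition")


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthConfig = SynthConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    nmf: NMFConfig = NMFConfig()
    scoring: ScoringConfig = ScoringConfig()
    regulon: RegulonConfig = RegulonConfig()
    seed: int = 0
    top_markers: int = 50
    score_method: str = "ssgsea"

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate a global seed into every stage's sub-seed."""
        return replace(
            self,
            seed=seed,
            synth=replace(self.synth, seed=seed),
            preprocess=replace(self.preprocess, seed=seed),
            nmf=replace(self.nmf, seed=seed),
            regulon=replace(self.regulon, seed=seed),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            synth=SynthConfig(**raw.get("synth", {})),
            preprocess=PreprocessConfig(**raw.get("preprocess", {})),
            nmf=NMFConfig(**raw.get("nmf", {})),
            scoring=ScoringConfig(**raw.get("scoring", {})),
            regulon=RegulonConfig(**raw.get("regulon", {})),
            seed=raw.get("seed", 0),
            top_markers=raw.get("top_markers", 50),
            score_method=raw.get("score_method", "ssgsea"),
        )
        if "seed" in raw:
            cfg = cfg.with_seed(raw["seed"])
        return cfg


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one run."""

    adata: "object"                  # QC-filtered counts (AnnData)
    truth: SyntheticTruth | None
    expr: pd.DataFrame               # log-normalized expression, cells x genes
    hvgs: list[str]
    subclusters: pd.Series
    cell_subtypes: pd.Series
    cluster_to_subtype: dict
    markers: dict[str, list[str]]
    concordance: ConcordanceReport
    scores: pd.DataFrame
    score_labels: pd.Series
    csc_score: pd.Series
    regulon_auc: pd.DataFrame
    regulon_rss: pd.DataFrame
    pseudocell_labels: pd.Series
    composition: pd.DataFrame
    grouping: CohortGrouping
    distances: DistanceSummary
    qc_report: dict
    manifest: dict


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 adata=None, truth: SyntheticTruth | None = None
                 ) -> PipelineResult:
    """Run every stage in order on synthetic (default) or user-supplied data.

    When ``out_dir`` is given, each stage writes its artifacts there and a
    ``manifest.json`` records stages, seeds and artifact paths; reruns with
    the same config reproduce all artifacts bit-identically (the manifest
    timestamp aside).
    """
    out = Path(out_dir) if out_dir is not None else None
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": _config_dict(cfg), "stages": []}

    def record(stage: str, artifacts: list[str]) -> None:
        manifest["stages"].append({"stage": stage, "artifacts": artifacts})

    try:
        # --- simulate ------------------------------------------------------
        if adata is None:
            adata, truth = generate_cohort(cfg.synth)
            arts = []
            if out is not None:
                save_cohort(out / "cohort", adata, truth)
                arts = [str(out / "cohort")]
            record("simulate", arts)
        else:
            record("simulate", ["(user data)"])

        # --- preprocess ----------------------------------------------------
        filtered, qc_report = qc_filter(adata, cfg.preprocess)
        normed = normalize_log1p_cp10k(filtered)
        n_hvgs = min(cfg.preprocess.n_hvgs, normed.n_vars)
        hvgs = select_hvgs(normed, n_hvgs)
        scores_pc = pca(normed, hvgs, cfg.preprocess.n_pcs,
                        cfg.preprocess.zscore_clip)
        subclusters = cluster_graph(scores_pc, cfg.preprocess.cluster_resolution,
                                    seed=cfg.preprocess.seed,
                                    n_neighbors=cfg.preprocess.snn_neighbors,
                                    prune=cfg.preprocess.snn_prune)
        expr = pd.DataFrame(np.asarray(normed.X.todense()),
                            index=normed.obs_names, columns=normed.var_names)
        arts = []
        if out is not None:
            write_mtx_bundle(filtered, out / "filtered")
            subclusters.rename("subcluster").to_csv(out / "subclusters.tsv", sep="\t")
            write_report(qc_report, out / "qc_report.json")
            arts = [str(out / p) for p in ("filtered", "subclusters.tsv",
                                           "qc_report.json")]
        record("preprocess", arts)

        # --- subtype discovery ----------------------------------------------
        profiles = mean_profiles(expr, subclusters)
        top_genes = top_sd_genes(profiles, n=min(50, expr.shape[1]))
        sim = spearman_matrix(profiles, top_genes)
        labeling = hcluster_merge(sim, profiles, k=3, cell_labels=subclusters)
        cell_subtypes = labeling.cell_subtype
        marker_series = rank_markers(expr, cell_subtypes, n_top=cfg.top_markers)
        markers = {s: list(v.index) for s, v in marker_series.items()}
        arts = []
        if out is not None:
            pd.Series(labeling.cluster_to_subtype, name="subtype").rename_axis(
                "subcluster").to_csv(out / "subtype_map.tsv", sep="\t")
            cell_subtypes.rename_axis("cell_id").to_csv(
                out / "cell_subtypes.tsv", sep="\t")
            sim.to_csv(out / "similarity.tsv", sep="\t")
            write_gmt(markers, out / "markers.gmt")
            arts = [str(out / p) for p in ("subtype_map.tsv", "cell_subtypes.tsv",
                                           "similarity.tsv", "markers.gmt")]
        record("subtype", arts)

        # --- NMF consensus validation ---------------------------------------
        feature_genes = sorted(set(hvgs).union(*markers.values())
                               & set(expr.columns))
        report, _ = resample_concordance(expr, filtered.obs, cell_subtypes,
                                         cfg.nmf, feature_genes=feature_genes)
        arts = []
        if out is not None:
            write_report({"rates": report.rates, "median": report.median,
                          "min": report.min, "max": report.max},
                         out / "concordance_report.json")
            arts = [str(out / "concordance_report.json")]
        record("nmf_validate", arts)

        # --- signature scoring ----------------------------------------------
        subtype_scores = score_subtypes(expr, markers, method=cfg.score_method,
                                        cfg=cfg.scoring)
        score_labels = assign_subtype_by_score(subtype_scores)
        csc = mean_z_score(expr, list(cfg.scoring.csc_markers)).rename("csc_score")
        arts = []
        if out is not None:
            table = subtype_scores.copy()
            table["csc_score"] = csc
            table["assigned"] = score_labels
            table.rename_axis("cell_id").to_csv(out / "scores.tsv", sep="\t")
            arts = [str(out / "scores.tsv")]
        record("score", arts)

        # --- regulon activity -----------------------------------------------
        pseudo, pseudo_labels = make_pseudocells(expr, cell_subtypes, cfg.regulon)
        auc = RegulonAUCScorer(markers, cfg.regulon.auc_top_fraction
                               ).transform(pseudo)
        specificity = rss(auc, pseudo_labels, cfg.regulon)
        arts = []
        if out is not None:
            auc.rename_axis("pseudocell").to_csv(out / "regulon_auc.tsv", sep="\t")
            specificity.rename_axis("regulon").to_csv(out / "regulon_rss.tsv",
                                                      sep="\t")
            arts = [str(out / "regulon_auc.tsv"), str(out / "regulon_rss.tsv")]
        record("regulons", arts)

        # --- composition ------------------------------------------------------
        comp = composition_table(cell_subtypes, filtered.obs)
        grouping = group_cohort(comp)
        distances = distance_summary(comp)
        arts = []
        if out is not None:
            comp.rename_axis("sample_id").to_csv(out / "composition.tsv", sep="\t")
            grouping.sample_group.rename_axis("sample_id").to_csv(
                out / "grouping.tsv", sep="\t")
            write_report({
                "within_median": distances.within_median,
                "within_range": list(distances.within_range),
                "between_median": distances.between_median,
                "between_range": list(distances.between_range),
                "p_value": distances.p_value, "method": distances.method,
            }, out / "distance_summary.json")
            arts = [str(out / p) for p in ("composition.tsv", "grouping.tsv",
                                           "distance_summary.json")]
        record("composition", arts)
    except Exception as err:
        stage = STAGES[len(manifest["stages"])] if len(manifest["stages"]) < len(STAGES) else "?"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    if out is not None:
        manifest_out = dict(manifest)
        manifest_out["timestamp"] = datetime.datetime.now(
            datetime.timezone.utc).isoformat()
        (out / "manifest.json").write_text(
            json.dumps(manifest_out, indent=1, sort_keys=True))

    return PipelineResult(
        adata=filtered, truth=truth, expr=expr, hvgs=hvgs,
        subclusters=subclusters, cell_subtypes=cell_subtypes,
        cluster_to_subtype=labeling.cluster_to_subtype, markers=markers,
        concordance=report, scores=subtype_scores, score_labels=score_labels,
        csc_score=csc, regulon_auc=auc, regulon_rss=specificity,
        pseudocell_labels=pseudo_labels, composition=comp, grouping=grouping,
        distances=distances, qc_report=qc_report, manifest=manifest,
    )


def _config_dict(cfg: PipelineConfig) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        out[f.name] = dataclasses.asdict(value) if dataclasses.is_dataclass(value) \
            else value
    return out
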
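"""End-to-end orchestration: data -> screen -> disorder metrics -> marker/classifier.

:func:`run_full_pipeline` executes the stages on either a simulated cohort or
user-supplied tables, and (optionally) writes a deterministic report bundle:
the resolved config, per-stage correlation and difference matrices, the screen
report, the disorder summary, marker scores with clinical fits, and the
classifier report.  Reruns with identical (inputs, config, seed) produce
byte-identical bundles; any stage failure aborts with the stage name and marks
the bundle incomplete.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (STAGES, ClinicalTable, ExpressionMatrix, collapse_and_subset,
                      exclude_by_pmi, preprocess, read_clinical_table,
                      read_expression_table, read_stage_map,
                      write_clinical_table, write_expression_table)
from .correlation_screen import ScreenResult, difference_matrix, pearson_matrix, screen_stages
from .disorder_metrics import DisorderSummary, disorder_summary
from .marker_classifier import (ClassifierReport, MarkerScores, fit_evaluate_classifier,
                                linear_fit, make_features, pc1_scores, rotated_band_rule)
from .panel import GenePanel
from .synthetic_cohort import CohortConfig, generate_cohort


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved settings for one run; written beside the outputs."""

    # data source: either simulate (cohort config) or load from paths
    simulate: bool = True
    cohort: CohortConfig | None = None
    expression_path: str | None = None
    stage_map_path: str | None = None
    clinical_path: str | None = None
    panel_path: str | None = None
    # preprocessing
    preprocess_steps: tuple[str, ...] = ()
    log_offset: float = 0.0
    collapse: bool = False
    # screening
    k: float = 2.0
    sidedness: str = "upper"
    min_pair_count: int = 1
    intersection_mode: str = "genes"
    hub_override: tuple[str, ...] | None = None
    # disorder metrics
    dims: tuple[int, ...] = (3, 4, 5)
    # marker / classifier
    folds: int = 5
    svm_C: float = 1.0
    coverage_quantile: float = 0.95
    pmi_exclude_threshold: float | None = None
    # bookkeeping
    out_dir: str | None = None
    seed: int = 0

    def resolved_cohort(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        return CohortConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # implied by the bundle's location
        d["cohort"] = self.resolved_cohort().to_dict() if self.simulate else None
        d["cohort"] and d["cohort"].pop("panel", None)
        return d


@dataclass
class PipelineResult:
    expression: ExpressionMatrix
    clinical: ClinicalTable | None
    screen: ScreenResult
    hub_genes: tuple[str, ...]
    hub_source: str                      # "screen" or "override"
    disorder: DisorderSummary
    marker: MarkerScores
    fits: dict[str, dict]
    classifier: ClassifierReport
    band: ClassifierReport
    out_dir: Path | None = None


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_data(config: PipelineConfig):
    panel = (GenePanel.from_file(config.panel_path)
             if config.panel_path else GenePanel.default())
    if config.simulate:
        cohort = config.resolved_cohort()
        expr, clinical, truth = generate_cohort(cohort)
        return expr, clinical, truth, panel
    if not config.expression_path:
        raise ValueError("expression_path required when simulate is false")
    stage_map = read_stage_map(config.stage_map_path) if config.stage_map_path else None
    expr = read_expression_table(config.expression_path, stage_map=stage_map)
    clinical = read_clinical_table(config.clinical_path) if config.clinical_path else None
    if config.preprocess_steps:
        expr = preprocess(expr, config.preprocess_steps, log_offset=config.log_offset)
    if config.collapse:
        expr = collapse_and_subset(expr, panel)
    return expr, clinical, None, panel


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; write the report bundle when ``out_dir`` is set."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "INCOMPLETE").write_text("run in progress\n")
    try:
        result = _run(config, out)
    except PipelineError:
        if out:
            (out / "INCOMPLETE").write_text("run failed; outputs are partial\n")
        raise
    if out:
        (out / "INCOMPLETE").unlink(missing_ok=True)
    return result


def _run(config: PipelineConfig, out: Path | None) -> PipelineResult:
    try:
        expr, clinical, truth, panel = _load_data(config)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineError("data_io", e) from e

    if out:
        _json_dump({"config": config.to_dict()}, out / "resolved_config.json")
        write_expression_table(expr, out / "expression.tsv")
        if clinical is not None:
            write_clinical_table(clinical, out / "clinical.tsv")
        if truth is not None:
            _json_dump(
                {
                    "hub_genes": list(truth.hub_genes),
                    "seed": truth.seed,
                    "stage_means": {s: v.tolist() for s, v in truth.stage_means.items()},
                    "stage_correlations": {s: v.tolist() for s, v in truth.stage_correlations.items()},
                    "repair_distance": truth.repair_distance,
                },
                out / "truth.json",
            )

    try:
        screen = screen_stages(expr, k=config.k, sidedness=config.sidedness,
                               min_pair_count=config.min_pair_count,
                               intersection_mode=config.intersection_mode)
    except Exception as e:
        raise PipelineError("correlation_screen", e) from e

    if out:
        r_con = pearson_matrix(expr, "CON")
        for stage in STAGES:
            r = pearson_matrix(expr, stage)
            pd.DataFrame(r.values, index=r.gene_ids, columns=r.gene_ids).to_csv(
                out / f"correlation_{stage}.tsv", sep="\t", float_format="%.12g")
            if stage != "CON":
                d = difference_matrix(r, r_con)
                pd.DataFrame(d.values, index=d.gene_ids, columns=d.gene_ids).to_csv(
                    out / f"delta_{stage}.tsv", sep="\t", float_format="%.12g")
        _json_dump(screen.to_dict(), out / "screen.json")

    if config.hub_override:
        hub_genes, hub_source = tuple(config.hub_override), "override"
    else:
        hub_genes, hub_source = screen.omega, "screen"
    try:
        if len(hub_genes) < 2:
            raise ValueError(
                f"hub set {hub_genes} too small for network metrics; "
                "supply hub_override")
        max_dim = min(expr.stage_counts().values())
        dims = tuple(d for d in config.dims if d <= max_dim)
        disorder = disorder_summary(expr, hub_genes, dims=dims)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("disorder_metrics", e) from e

    if out:
        d = disorder.to_dict()
        d["hub_source"] = hub_source
        _json_dump(d, out / "disorder.json")
        rows = []
        for stage in STAGES:
            row = {"stage": stage,
                   "determinant": disorder.determinant[stage],
                   "system_entropy": disorder.system_entropy[stage]}
            for dim, h in disorder.determinant_entropy.items():
                row[f"det_entropy_dim{dim}"] = h[stage]
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "disorder.tsv", sep="\t", index=False,
                                  float_format="%.12g")

    try:
        marker_expr = expr
        excluded: list[str] = []
        if clinical is not None and config.pmi_exclude_threshold is not None:
            marker_expr, excluded = exclude_by_pmi(expr, clinical,
                                                   config.pmi_exclude_threshold)
        alpha = panel.alpha_ring
        marker_panel = marker_expr.subset_genes(["PSMC6", *alpha])
        marker = pc1_scores(marker_panel)
        fits: dict[str, dict] = {}
        if clinical is not None:
            clin_of = {s: i for i, s in enumerate(clinical.sample_ids)}
            for name in ("mmse", "nft"):
                col = getattr(clinical, name)
                if col is None:
                    continue
                idx = [clin_of[s] for s in marker.sample_ids if s in clin_of]
                y = col[idx]
                x = np.array([marker.pc1[marker.sample_ids.index(s)]
                              for s in marker.sample_ids if s in clin_of])
                fit = linear_fit(x, y)
                fits[f"pc1_vs_{name}"] = dataclasses.asdict(fit)
                ad_ids = [s for s in marker.sample_ids
                          if s in clin_of and marker_expr.stage.get(s) in ("INC", "MOD", "SEV")]
                if len(ad_ids) >= 3:
                    xa = np.array([marker.pc1[marker.sample_ids.index(s)] for s in ad_ids])
                    ya = col[[clin_of[s] for s in ad_ids]]
                    if xa.std() > 0:
                        fits[f"pc1_vs_{name}_ad_only"] = dataclasses.asdict(linear_fit(xa, ya))
    except Exception as e:
        raise PipelineError("marker", e) from e

    if out:
        pd.DataFrame({"sample_id": marker.sample_ids, "pc1": marker.pc1}).to_csv(
            out / "marker_scores.tsv", sep="\t", index=False, float_format="%.12g")
        _json_dump({"fits": fits,
                    "explained_ratio": marker.explained_ratio,
                    "loadings": dict(zip(marker.gene_ids, map(float, marker.loadings))),
                    "excluded_by_pmi": excluded},
                   out / "marker.json")

    try:
        features, ids = make_features(marker_expr, panel)
        labels = np.array(["CON" if marker_expr.stage.get(s) == "CON" else "AD"
                           for s in ids])
        classifier = fit_evaluate_classifier(features, labels, folds=config.folds,
                                             seed=config.seed, C=config.svm_C)
        band = rotated_band_rule(features, labels,
                                 coverage_quantile=config.coverage_quantile,
                                 threshold_point=classifier.threshold_point)
    except Exception as e:
        raise PipelineError("classifier", e) from e

    if out:
        _json_dump({"classifier": classifier.to_dict(), "band": band.to_dict()},
                   out / "classifier.json")
        pd.DataFrame(classifier.roc_points, columns=["fpr", "tpr"]).to_csv(
            out / "roc_points.tsv", sep="\t", index=False, float_format="%.12g")
        _json_dump(
            {"package": "proteocohere", "version": __version__, "seed": config.seed,
             "hub_source": hub_source, "hub_genes": list(hub_genes),
             "stages_completed": ["data_io", "correlation_screen",
                                  "disorder_metrics", "marker", "classifier"]},
            out / "run_log.json")

    return PipelineResult(expression=expr, clinical=clinical, screen=screen,
                          hub_genes=tuple(hub_genes), hub_source=hub_source,
                          disorder=disorder, marker=marker, fits=fits,
                          classifier=classifier, band=band, out_dir=out)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    cohort = raw.pop("cohort", None)
    cfg = PipelineConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in raw.items()})
    if cohort:
        cfg.cohort = CohortConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in cohort.items()})
    return cfg
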
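"""End-to-end pipeline: networks -> features -> selection -> classification.

``run_pipeline`` executes the four stages in order for a labelled cohort —
(1) low-order FCN construction, (2) hypergraph high-order FCN construction,
(3) two-stage feature selection, (4) SVM classification with decision-score
fusion under nested cross-validation — and writes every artifact needed to
reproduce the run (resolved config, seed, version, logs).  ``run_sweep``
repeats the evaluation across the incidence-threshold grid.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .classify import CVReport, nested_cross_validation, selection_frequency_ranking
from .config import PipelineConfig
from .fcn import HYPERGRAPH_HON, RoiTimeSeries, build_all_networks, build_incidence, build_low_order_fcn
from .synthetic import cohort_feature_matrices

logger = logging.getLogger("hyperfcn")


def _setup_logging(outdir: Path, level: str) -> None:
    logger.setLevel(level.upper())
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def metrics_table(report: CVReport) -> pd.DataFrame:
    """Per-method metrics on the percent scale (one row per method)."""
    rows = []
    for m in report.methods:
        r = report.metrics[m]
        rows.append(
            {
                "Method": m,
                "ACC": 100 * r.acc, "SEN": 100 * r.sen, "SPE": 100 * r.spe,
                "BAC": 100 * r.bac, "PPV": 100 * r.ppv, "NPV": 100 * r.npv,
                "F1": 100 * r.f1,
            }
        )
    return pd.DataFrame(rows)


def hyperedge_report(
    cohort: list[RoiTimeSeries],
    report: CVReport,
    threshold: float,
    absolute: bool = False,
    top: int = 10,
) -> list[dict]:
    """Trace the top-ranked hyperedge-pair features back to member ROIs.

    A feature of the hypergraph view is a pair of hyperedges (e_i, e_j).
    Incidence is per subject, so each hyperedge's membership is summarised
    per diagnostic group as the ROIs belonging to it in more than half of
    that group's subjects (majority vote).  ROIs and hyperedges are reported
    1-based.
    """
    ranking = selection_frequency_ranking(report, HYPERGRAPH_HON)[:top]
    if not ranking:
        return []
    groups: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for ts in cohort:
        lon = build_low_order_fcn(ts)
        hg = build_incidence(lon, threshold, absolute=absolute)
        groups[int(ts.label)].append(hg.H.astype(int))
    majority = {
        g: (np.sum(mats, axis=0) > len(mats) / 2) for g, mats in groups.items() if mats
    }
    roi_labels = cohort[0].roi_labels

    def members(group: int, edge_1based: int) -> list[str]:
        idx = np.flatnonzero(majority[group][:, edge_1based - 1])
        if roi_labels:
            return [roi_labels[i] for i in idx]
        return [f"ROI_{i + 1:03d}" for i in idx]

    out = []
    for rf in ranking:
        ei, ej = rf.pair
        out.append(
            {
                "hyperedge_pair": [ei, ej],
                "selection_count": rf.count,
                "mean_abs_weight": rf.mean_abs_weight,
                "members": {
                    f"e{e}": {
                        "NC": members(0, e) if 0 in majority else [],
                        "ASD": members(1, e) if 1 in majority else [],
                    }
                    for e in (ei, ej)
                },
            }
        )
    return out


def evaluate_cohort(
    cohort: list[RoiTimeSeries], config: PipelineConfig, threshold: float | None = None
) -> CVReport:
    """Build features at one threshold and run the nested cross-validation."""
    t = config.threshold if threshold is None else threshold
    include_chon = "C_HON" in config.methods
    views, labels, ids = cohort_feature_matrices(
        cohort, t, absolute=config.abs_threshold, include_corr_of_corr=include_chon
    )
    return nested_cross_validation(
        views,
        labels,
        subject_ids=ids,
        grid=config.grid(),
        methods=tuple(config.methods),
        seed=config.seed,
        outer_folds=config.outer_folds,
        inner_folds=config.inner_folds,
        equal_var=config.equal_var,
        threshold=t,
    )


def run_pipeline(config: PipelineConfig, cohort: list[RoiTimeSeries] | None = None) -> Path:
    """Execute the full pipeline and write all outputs to the output directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)
    config.to_yaml(outdir / "resolved_config.yaml")

    if cohort is None:
        if not config.manifest:
            raise ValueError("config.manifest is required when no cohort is given")
        cohort = hio.load_cohort(config.manifest)
    n_pos = sum(ts.label == 1 for ts in cohort)
    n_neg = sum(ts.label == 0 for ts in cohort)
    if min(n_pos, n_neg) < 2:
        raise ValueError("need at least 2 subjects per class")
    logger.info(
        "cohort: %d subjects (%d ASD / %d NC), %d ROIs",
        len(cohort), n_pos, n_neg, cohort[0].n_rois,
    )

    logger.info("step 1-2: constructing low-order and hypergraph high-order FCNs (t=%.2f)", config.threshold)
    if config.write_matrices:
        mdir = outdir / "matrices"
        mdir.mkdir(exist_ok=True)
        for ts in cohort:
            try:
                nets = build_all_networks(
                    ts,
                    config.threshold,
                    absolute=config.abs_threshold,
                    include_corr_of_corr="C_HON" in config.methods,
                )
            except Exception:
                logger.error("network construction failed for subject %s", ts.subject_id)
                raise
            for kind, cm in nets.items():
                hio.write_connectivity_matrix(cm, mdir / f"{ts.subject_id}.{kind}.tsv")

    logger.info("step 3-4: feature selection and nested %d-fold CV (seed=%d)",
                config.outer_folds, config.seed)
    report = evaluate_cohort(cohort, config)

    hio.write_json(report.to_dict(), outdir / "cv_report.json")
    metrics_table(report).to_csv(outdir / "metrics.tsv", sep="\t", index=False, float_format="%.2f")
    for view in report.views:
        ranking = selection_frequency_ranking(report, view)
        pd.DataFrame(
            [
                {
                    "feature_index": r.index,
                    "node_i": r.pair[0],
                    "node_j": r.pair[1],
                    "count": r.count,
                    "mean_abs_weight": r.mean_abs_weight,
                }
                for r in ranking
            ]
        ).to_csv(outdir / f"selection_frequency.{view}.tsv", sep="\t", index=False)
    if HYPERGRAPH_HON in report.views:
        hio.write_json(
            {
                "threshold": config.threshold,
                "top_hyperedge_connections": hyperedge_report(
                    cohort, report, config.threshold, absolute=config.abs_threshold
                ),
            },
            outdir / "discriminative_hyperedges.json",
        )
    logger.info("pooled metrics: %s",
                {m: round(report.metrics[m].acc, 4) for m in report.methods})
    for h in list(logger.handlers):
        h.close()
        logger.removeHandler(h)
    return outdir


def run_sweep(config: PipelineConfig, cohort: list[RoiTimeSeries] | None = None) -> Path:
    """Repeat the evaluation across the incidence-threshold grid.

    Writes ``sweep.tsv`` with one row per threshold and the hypergraph
    high-order method's pooled metrics (percent scale).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)
    config.to_yaml(outdir / "resolved_config.yaml")
    if cohort is None:
        if not config.manifest:
            raise ValueError("config.manifest is required when no cohort is given")
        cohort = hio.load_cohort(config.manifest)

    method = "H-C_HON" if "H-C_HON" in config.methods else config.methods[0]
    rows = []
    for t in config.sweep_thresholds:
        logger.info("sweep: threshold %.2f", t)
        report = evaluate_cohort(cohort, config, threshold=t)
        r = report.metrics[method]
        rows.append(
            {
                "threshold": t,
                "ACC": 100 * r.acc, "SEN": 100 * r.sen, "SPE": 100 * r.spe,
                "PPV": 100 * r.ppv, "NPV": 100 * r.npv, "F1": 100 * r.f1,
            }
        )
    pd.DataFrame(rows).to_csv(
        outdir / "sweep.tsv", sep="\t", index=False, float_format="%.2f"
    )
    for h in list(logger.handlers):
        h.close()
        logger.removeHandler(h)
    return outdir
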
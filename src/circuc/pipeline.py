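"""End-to-end pipeline: simulate/load -> preprocess -> SAM -> consensus ->
nested evaluation -> correlation clusters, with a machine-readable summary.

The pipeline is configured by a plain mapping (typically parsed from YAML)
and is fully reproducible from one master seed: every randomized stage
derives its own stream from the seed keyed by stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from circuc._seeds import stage_seed
from circuc.classify_eval import EvalParams, evaluate, misclassification_report
from circuc.cluster import correlation_clusters, hier_cluster_samples
from circuc.consensus import ConsensusParams, derive_consensus
from circuc.datatypes import FRACTIONS, ExprMatrix, SampleTable, ValidationError
from circuc.io import (
    average_replicates,
    read_expr_matrix,
    read_probe_matrix,
    read_sample_table,
    write_expr_matrix,
    write_sample_table,
)
from circuc.preprocess import PreprocessParams, preprocess_probes
from circuc.sam import SamParams, sam_calibrate
from circuc.synth import SimulationDesign, sample_table, simulate_feature_matrix

logger = logging.getLogger("circuc")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _filter_fields(cls, cfg: dict[str, Any]) -> dict[str, Any]:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(cfg) - names
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} options: {sorted(unknown)}")
    return dict(cfg)


def _round(obj: Any) -> Any:
    """Round floats for a byte-stable JSON summary."""
    if isinstance(obj, float):
        return float(f"{obj:.10g}")
    if isinstance(obj, dict):
        return {k: _round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Check labels and option names before any compute."""
    cfg = dict(config)
    fraction = cfg.get("fraction", "platelet")
    if fraction not in FRACTIONS:
        raise ValidationError(f"unknown fraction label: {fraction!r}")
    for section, cls in (("simulate", SimulationDesign), ("sam", SamParams),
                         ("preprocess", PreprocessParams)):
        if section in cfg and cfg[section] is not None:
            _filter_fields(cls, cfg[section])
    return cfg


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> Path:
    """Execute the configured stages and write all outputs under ``out_dir``.

    Returns the run directory.  Any stage failure raises :class:`StageError`
    naming the stage.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    fraction = cfg.get("fraction", "platelet")
    summary: dict[str, Any] = {"seed": seed, "fraction": fraction, "stages": []}

    # ------------------------------------------------ input / simulate
    try:
        if "expr" in cfg:
            meta = read_sample_table(cfg["meta"])
            meta = meta.for_fraction(fraction) if "fraction" in cfg else meta
            if "probes" in cfg:
                probes = read_probe_matrix(cfg["probes"], meta)
                pp = PreprocessParams(**_filter_fields(PreprocessParams,
                                                       cfg.get("preprocess") or {}))
                expr = preprocess_probes(probes, meta, pp)
                summary["stages"].append("preprocess")
            else:
                expr = read_expr_matrix(cfg["expr"], meta)
                expr = average_replicates(expr, meta)
            meta = meta.primary()
            truth = None
        else:
            sim_cfg = _filter_fields(SimulationDesign, cfg.get("simulate") or {})
            sim_cfg.setdefault("seed", stage_seed(seed, "simulate"))
            sim_cfg.setdefault("fraction", fraction)
            design = SimulationDesign(**sim_cfg)
            expr, truth = simulate_feature_matrix(design)
            meta = sample_table(design)
            write_expr_matrix(expr, out / "expr.tsv")
            write_sample_table(meta, out / "meta.tsv")
            truth.to_csv(out / "truth.tsv", sep="\t", index=False,
                         float_format="%.12g")
            summary["stages"].append("simulate")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", exc) from exc

    meta.require_two_per_class()
    case_mask = meta.groups_for(expr.sample_ids)

    # ------------------------------------------------ SAM on the full data
    try:
        sam_cfg = _filter_fields(SamParams, cfg.get("sam") or {})
        sam_cfg.setdefault("seed", stage_seed(seed, "sam"))
        sam_params = SamParams(**sam_cfg)
        sam_res = sam_calibrate(expr, case_mask, sam_params)
        sam_res.table.to_csv(out / "sam.tsv", sep="\t", float_format="%.12g")
        summary["stages"].append("sam")
        summary["sam"] = {
            "n_called": int(sam_res.table["called"].sum()),
            "s0": sam_res.s0, "delta": sam_res.delta, "pi0": sam_res.pi0,
            "n_permutations_used": sam_res.n_permutations_used,
        }
    except Exception as exc:
        raise StageError("sam", exc) from exc

    # ------------------------------------------------ consensus panel
    try:
        cons_cfg = dict(cfg.get("consensus") or {})
        inner_sam = cons_cfg.pop("sam_params", None)
        cons_cfg = _filter_fields(ConsensusParams, cons_cfg)
        cons_cfg.setdefault("seed", stage_seed(seed, "consensus"))
        if inner_sam is not None:
            cons_cfg["sam_params"] = SamParams(**_filter_fields(SamParams, inner_sam))
        cons_params = ConsensusParams(**cons_cfg)
        panel = derive_consensus(expr, meta, cons_params)
        panel.table.to_csv(out / "panel.tsv", sep="\t", float_format="%.12g")
        summary["stages"].append("consensus")
        summary["consensus"] = {
            "n_selected": int(panel.table["selected"].sum()),
            "selected": panel.selected_features,
            "threshold": panel.threshold,
            "n_iterations": panel.n_iterations,
        }
    except Exception as exc:
        raise StageError("consensus", exc) from exc

    # ------------------------------------------------ nested evaluation
    try:
        eval_cfg = dict(cfg.get("evaluate") or {})
        inner = eval_cfg.pop("inner_consensus", None)
        eval_cfg = _filter_fields(EvalParams, eval_cfg)
        eval_cfg.setdefault("seed", stage_seed(seed, "evaluate"))
        if inner is not None:
            inner_sam = inner.pop("sam_params", None)
            inner_cfg = _filter_fields(ConsensusParams, inner)
            if inner_sam is not None:
                inner_cfg["sam_params"] = SamParams(**_filter_fields(SamParams, inner_sam))
            eval_cfg["inner_consensus"] = ConsensusParams(**inner_cfg)
        eval_params = EvalParams(**eval_cfg)
        confusion, metrics = evaluate(expr, meta, eval_params)
        report = misclassification_report(confusion, meta)
        payload = {
            "confusion": {"tp": confusion.tp, "fp": confusion.fp,
                          "tn": confusion.tn, "fn": confusion.fn,
                          "n_repetitions": confusion.n_repetitions},
            "metrics": dataclasses.asdict(metrics),
            "per_sample": report.to_dict(orient="records"),
        }
        (out / "eval.json").write_text(
            json.dumps(_round(payload), indent=2, sort_keys=True) + "\n")
        summary["stages"].append("evaluate")
        summary["evaluate"] = {"confusion": payload["confusion"],
                               "metrics": payload["metrics"]}
    except Exception as exc:
        raise StageError("evaluate", exc) from exc

    # ------------------------------------------------ clusters
    try:
        clu_cfg = dict(cfg.get("cluster") or {})
        r_threshold = float(clu_cfg.get("r_threshold", 0.6))
        selected = summary["consensus"]["selected"]
        cluster_payload: dict[str, Any] = {"r_threshold": r_threshold}
        if len(selected) >= 2:
            cset = correlation_clusters(expr, selected, r_threshold=r_threshold)
            cluster_payload["clusters"] = cset.clusters
            cluster_payload["stats"] = cset.stats.to_dict(orient="records")
            cluster_payload["unassigned"] = cset.unassigned
        else:
            cluster_payload["clusters"] = []
            cluster_payload["stats"] = []
            cluster_payload["unassigned"] = selected
        sclust = hier_cluster_samples(expr, meta)
        cluster_payload["sample_two_group_misclassified"] = sclust.misclassified
        (out / "clusters.json").write_text(
            json.dumps(_round(cluster_payload), indent=2, sort_keys=True) + "\n")
        summary["stages"].append("cluster")
        summary["cluster"] = {
            "n_clusters": len(cluster_payload["clusters"]),
            "sample_two_group_misclassified": sclust.misclassified,
        }
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    (out / "summary.json").write_text(
        json.dumps(_round(summary), indent=2, sort_keys=True) + "\n")
    return out
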
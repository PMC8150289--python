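"""End-to-end orchestration of the synthetic reproduction of the study design.

``run_pipeline`` executes simulate -> segment -> extract -> select -> train
(designs A, B and C) -> perturb -> report, writing every artefact as a flat
file (NIfTI / CSV / JSON) stamped with a hash of the run configuration so
outputs are inspectable, diffable and reproducible.
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

from . import features as ft
from .imgio import write_mask, write_volume
from .models import repeated_cv, train_eval_transfer
from .robustness import reproducibility_sweep, sweep_table
from .segmentation import check_eligibility, threshold_segment
from .selection import select
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; serialized into every output for provenance."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    segmentation_fraction: float = 0.40
    min_voxels: int = 64
    n_levels: int = 64
    distances: tuple[int, ...] = (1, 2, 3, 4)
    alpha: float = 0.05
    single_corr_thresh: float = 0.90
    pair_corr_thresh: float = 0.30
    cv_repetitions: int = 100
    cv_folds: int = 3
    erosion_r: tuple[int, ...] = tuple(range(5, 36, 5))
    dilation_r: tuple[int, ...] = tuple(range(5, 26, 5))
    seed: int = 0
    write_volumes: bool = False
    output_dir: str = "pannet_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in raw:
            raw["cohort"] = CohortSpec(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["cohort"].items()
            })
        for key in ("distances", "erosion_r", "dilation_r"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        """Hash of the scientific parameters (where outputs go is excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("write_volumes", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run the whole analysis once; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    (out / "config.json").write_text(
        json.dumps({"hash": cfg_hash, **config.to_dict()}, indent=2, default=list))
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pannet_radiomics")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out, cfg_hash)
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(name: str, pid: str | None = None):
    where = f" (patient {pid})" if pid else ""
    return f"pipeline stage '{name}'{where} failed"


def _run(config: RunConfig, out: Path, cfg_hash: str) -> Path:
    log = logging.getLogger("pannet_radiomics.pipeline")
    log.info("run %s starting, master seed %d", cfg_hash, config.seed)

    # --- simulate
    phantoms, table = generate_cohort(config.cohort)
    if config.write_volumes:
        voldir = out / "volumes"
        voldir.mkdir(exist_ok=True)
        for pid, (vol, mask) in phantoms.items():
            write_volume(vol, voldir / f"{pid}_suv.nii.gz")
            write_mask(mask, voldir / f"{pid}_roi.nii.gz")

    # --- segment + eligibility
    exclusions = []
    segmented = {}
    for pid, (vol, mask) in phantoms.items():
        try:
            seg = threshold_segment(vol, mask, fraction=config.segmentation_fraction)
        except Exception as exc:  # noqa: BLE001 - abort with stage + patient
            raise RuntimeError(_stage("segment", pid)) from exc
        ok, reason = check_eligibility(seg, min_voxels=config.min_voxels)
        if not ok:
            exclusions.append({"id": pid, "reason": reason})
            log.info("excluded %s: %s", pid, reason)
        else:
            segmented[pid] = (vol, seg)
    (out / "exclusions.json").write_text(json.dumps(
        {"config_hash": cfg_hash, "excluded": exclusions}, indent=2))
    table = table[table["id"].isin(segmented)].reset_index(drop=True)
    if table.empty:
        raise RuntimeError(_stage("segment") + ": no eligible lesions")

    # --- extract
    rows = []
    for pid in table["id"]:
        vol, seg = segmented[pid]
        try:
            rows.append({"id": pid, **ft.extract_feature_vector(
                vol, seg, distances=config.distances, n_levels=config.n_levels)})
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(_stage("extract", pid)) from exc
    feats = table.merge(pd.DataFrame(rows), on="id")
    feats.to_csv(out / "features.csv", index=False, float_format="%.10g")

    # --- select (on HS rows only: the histology-anchored training design)
    hs = feats[feats["source"] == "HS"].reset_index(drop=True)
    bs = feats[feats["source"] == "BS"].reset_index(drop=True)
    result = select(hs, alpha=config.alpha, single_thresh=config.single_corr_thresh,
                    pair_thresh=config.pair_corr_thresh, seed=config.seed)
    result.singles.to_csv(out / "selection_singles.csv", index=False)
    result.pairs.head(200).to_csv(out / "selection_pairs.csv", index=False)
    pair = result.winner_pair
    if pair is None and len(result.pairs):
        pair = (result.pairs.iloc[0]["feature_a"], result.pairs.iloc[0]["feature_b"])
        log.warning("no Holm-surviving pair; falling back to best-ranked pair %s", pair)
    if pair is None:
        raise RuntimeError(_stage("select") + ": no candidate feature pair")
    (out / "selection.json").write_text(json.dumps({
        "config_hash": cfg_hash,
        "winner_single": result.winner_single,
        "winner_pair": list(pair),
        "n_candidate_pairs_total": result.n_candidate_pairs_total,
        "n_candidate_pairs_kept": result.n_candidate_pairs_kept,
        "thresholds": result.thresholds,
    }, indent=2))

    # --- train / evaluate
    report: dict = {"config_hash": cfg_hash, "pair": list(pair)}
    sig_a, tr_a, te_a = train_eval_transfer(hs, bs, pair, design="A", seed=config.seed)
    sig_b, tr_b, te_b = train_eval_transfer(bs, hs, pair, design="B", seed=config.seed)
    sig_a.to_json(out / "signature_A.json")
    sig_b.to_json(out / "signature_B.json")
    for name, metrics in (("model_a_train", tr_a), ("model_a_test", te_a),
                          ("model_b_train", tr_b), ("model_b_test", te_b)):
        report[name] = _metrics_payload(metrics)
    cv = repeated_cv(feats, pair, repetitions=config.cv_repetitions,
                     k=config.cv_folds, seed=config.seed)
    report["model_c"] = {
        "n_runs": cv.n_runs,
        "n_winners": cv.n_winners,
        "n_empty_repetitions": cv.n_empty_repetitions,
        "n_winner_train_side": cv.n_winner_train_side,
        "n_winner_val_side": cv.n_winner_val_side,
        "median_winner_val_auc": cv.median_winner_val_auc,
        "iqr_winner_val_auc": cv.iqr_winner_val_auc,
        "median_winner_sensitivity": cv.median_winner_sensitivity,
        "median_winner_specificity": cv.median_winner_specificity,
    }
    if cv.averaged_signature is not None:
        cv.averaged_signature.to_json(out / "signature_C.json")

    # --- perturb (reproducibility of the histology-trained signature)
    hs_phantoms = {pid: segmented[pid] for pid in hs["id"]}
    sweeps = []
    for direction, r_values in (("erode", config.erosion_r), ("dilate", config.dilation_r)):
        if not r_values:
            continue
        res = reproducibility_sweep(hs_phantoms, hs, sig_a, r_values, direction,
                                    min_voxels=config.min_voxels)
        sweeps.append(sweep_table(res))
    if sweeps:
        pd.concat(sweeps, ignore_index=True).to_csv(out / "perturbation_sweep.csv", index=False)

    # --- report (self-consistency gate: derived metrics vs confusion counts)
    for key in ("model_a_train", "model_a_test", "model_b_train", "model_b_test"):
        _check_consistency(report[key])
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("run %s complete", cfg_hash)
    return out


def _metrics_payload(metrics: dict) -> dict:
    cm = metrics["confusion"]
    return {
        "auc": metrics["auc"],
        "auc_ci": list(metrics["auc_ci"]),
        "p": metrics["p"],
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "ppv": cm.ppv,
        "npv": cm.npv,
        "accuracy": cm.accuracy,
        "informedness": cm.informedness,
        "fdr": cm.fdr,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
    }


def _check_consistency(payload: dict) -> None:
    c = payload["confusion"]
    tp, fp, tn, fn = c["tp"], c["fp"], c["tn"], c["fn"]
    derived = {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / (tp + fp + tn + fn),
    }
    for key, want in derived.items():
        got = payload[key]
        if np.isfinite(want) and abs(got - want) > 1e-12:
            raise RuntimeError(f"report self-consistency violated for {key}: {got} vs {want}")
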
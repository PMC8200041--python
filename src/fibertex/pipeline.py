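"""End-to-end orchestration: images -> features -> selection -> classification.

``run`` executes the whole analysis on either synthetic data (generator
presets, the default) or real two-channel TIFF stacks with an external label
table, and writes a reproducible report bundle of TSV artifacts: crop
manifest, feature table, selection trace, per-class metrics, ROC points,
canonical projections, and a JSON run log capturing the seed and every
effective parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import aggregate_precursor, ovr_suite
from .features import FEATURE_NAMES, build_table
from .fibers import packing_coefficient
from .io import Channel, SHGField, crop_rois, gate_by_coverage, read_label_table, read_stack
from .synth import CLASS_PRESETS, GeneratorParams, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "features_from_images"]


@dataclass
class RunConfig:
    mode: str = "synthetic"  # or "real"
    image_dir: Optional[str] = None
    label_table: Optional[str] = None
    out_dir: str = "fibertex_out"
    n_crops_per_class: int = 30
    crop_um: float = 45.0
    pixel_size_um: Optional[float] = None
    min_coverage: float = 0.70
    glcm_levels: int = 64
    min_fiber_length_px: float = 20.0
    alpha_enter: float = 0.35
    cv_folds: int = 5
    selection_mode: str = "inside"
    classify_groups: Tuple[str, ...] = ("distal_normal", "p53_signature", "STIC")
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.mode == "real":
            if not self.image_dir or not Path(self.image_dir).is_dir():
                raise ValueError("real mode needs an existing image_dir")
            if not self.label_table or not Path(self.label_table).is_file():
                raise ValueError("real mode needs an existing label_table TSV")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ValueError("min_coverage must lie in [0, 1]")
        if self.n_crops_per_class < 1:
            raise ValueError("n_crops_per_class must be >= 1")


def features_from_images(
    image_dir: str | Path,
    label_table: str | Path,
    crop_um: float = 45.0,
    pixel_size_um: Optional[float] = None,
    min_coverage: float = 0.70,
    glcm_levels: int = 64,
    min_fiber_length_px: float = 20.0,
) -> pd.DataFrame:
    """Read paired *_F/*_B TIFF stacks, crop, gate and featurize.

    Forward and backward channels of one physical crop are paired by
    (stack id, z index, origin); crops lacking either channel are skipped.
    """
    image_dir = Path(image_dir)
    labels = read_label_table(label_table)
    fwd_files = sorted(image_dir.glob("*_F.tif")) + sorted(image_dir.glob("*_F.tiff"))
    pairs: List[Tuple[str, SHGField, SHGField]] = []
    for f_path in fwd_files:
        b_path = f_path.with_name(f_path.name[: -len(f_path.suffix) - 2] + "_B" + f_path.suffix)
        if not b_path.exists():
            logger.warning("no backward stack for %s; skipped", f_path.name)
            continue
        f_fields = read_stack(f_path, pixel_size_um=pixel_size_um)
        b_fields = read_stack(b_path, pixel_size_um=pixel_size_um)
        for ff, bf in zip(f_fields, b_fields):
            f_crops = {c.origin: c for c in crop_rois(ff, crop_um)}
            b_crops = {c.origin: c for c in crop_rois(bf, crop_um)}
            for origin, fc in f_crops.items():
                bc = b_crops.get(origin)
                if bc is None:
                    continue
                fc.coverage = packing_coefficient(fc.pixels)
                if fc.coverage < min_coverage:
                    continue
                label = labels.get((fc.stack_id, origin[0], origin[1]), "unlabeled")
                fwd = SHGField(fc.pixels, Channel.FORWARD, fc.pixel_size_um,
                               stack_id=f"{fc.stack_id}_z{fc.z_index}_{origin[0]}_{origin[1]}",
                               z_index=fc.z_index)
                bwd = SHGField(bc.pixels, Channel.BACKWARD, bc.pixel_size_um,
                               stack_id=fwd.stack_id, z_index=bc.z_index)
                pairs.append((label, fwd, bwd))
    return build_table(pairs, glcm_levels=glcm_levels,
                       min_fiber_length_px=min_fiber_length_px)


def _synthetic_table(config: RunConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    crops, truths = generate_dataset(CLASS_PRESETS, config.n_crops_per_class, config.seed)
    manifest_rows = []
    kept: List[Tuple[str, SHGField, SHGField]] = []
    for (label, fwd, bwd), truth in zip(crops, truths):
        cov = packing_coefficient(fwd.pixels)
        manifest_rows.append({
            "crop_id": fwd.stack_id, "label": label, "coverage": cov,
            "true_coverage": truth.coverage, "true_kappa": truth.kappa,
            "true_straightness": truth.mean_straightness, "n_fibers": len(truth.fibers),
        })
        if cov >= config.min_coverage:
            kept.append((label, fwd, bwd))
    logger.info("coverage gate %.2f: retained %d / %d synthetic crops",
                config.min_coverage, len(kept), len(crops))
    table = build_table(kept, glcm_levels=config.glcm_levels,
                        min_fiber_length_px=config.min_fiber_length_px)
    return table, pd.DataFrame(manifest_rows)


def run(config: RunConfig) -> Dict[str, object]:
    """Execute the full pipeline and write the report bundle to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        table, manifest = _synthetic_table(config)
    else:
        table = features_from_images(
            config.image_dir, config.label_table, crop_um=config.crop_um,
            pixel_size_um=config.pixel_size_um, min_coverage=config.min_coverage,
            glcm_levels=config.glcm_levels,
            min_fiber_length_px=config.min_fiber_length_px,
        )
        manifest = table[["crop_id", "label"]].copy()

    manifest.to_csv(out / "crop_manifest.tsv", sep="\t", index=False)
    table.to_csv(out / "feature_table.tsv", sep="\t", index=False)

    groups = [g for g in config.classify_groups if g in set(table["label"])]
    suite = ovr_suite(table, groups=groups, k=config.cv_folds, seed=config.seed,
                      alpha_enter=config.alpha_enter, selection=config.selection_mode)
    agg = aggregate_precursor(table, k=config.cv_folds, seed=config.seed,
                              alpha_enter=config.alpha_enter,
                              selection=config.selection_mode)

    sel_frame = suite["selection"].to_frame()
    if len(sel_frame):
        feats = [f for f in FEATURE_NAMES if f in table.columns]
        sel_frame["feature"] = [feats[int(nm[1:])] for nm in sel_frame["feature"]]
    sel_frame.to_csv(out / "selection_trace.tsv", sep="\t", index=False)

    metrics = suite["metrics"].copy()
    agg_row = {"group": "precursor_vs_normal", "n": agg["counts"]["precursor"],
               "cv": True, **agg["metrics"]}
    metrics = pd.concat([metrics, pd.DataFrame([agg_row])], ignore_index=True)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)

    roc_rows = []
    for cls, curve in {**suite["roc"], "precursor_vs_normal": agg["roc"]}.items():
        for t, f, tp in zip(curve.thresholds, curve.fpr, curve.tpr):
            roc_rows.append({"class": cls, "threshold": t, "fpr": f, "tpr": tp})
    pd.DataFrame(roc_rows).to_csv(out / "roc_points.tsv", sep="\t", index=False)

    canon = suite["canonical"]
    pd.DataFrame({
        "label": canon["labels"],
        "cv1": canon["projections"][:, 0],
        "cv2": canon["projections"][:, 1] if canon["projections"].shape[1] > 1 else 0.0,
    }).to_csv(out / "canonical_projections.tsv", sep="\t", index=False)

    log = {
        "fibertex_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": dataclasses.asdict(config),
        "alignment_estimator": "alignment_op2",
        "n_records": int(len(table)),
        "n_complete": int(table["complete"].sum()) if "complete" in table else int(len(table)),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")

    return {"table": table, "suite": suite, "aggregate": agg, "metrics": metrics,
            "out_dir": str(out)}
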
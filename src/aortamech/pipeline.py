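"""End-to-end orchestration: phantom/data -> segmentation -> elasticity -> reports.

``run_pipeline`` executes the stages the study workflow chains together:
generate or load cine exams, train (or load) the segmentation U-Net, segment
every exam, score the segmentations against ground truth when available,
derive global and quadrant elastic properties, optionally analyse tensile
records, and compare predicted against ground-truth-derived quantities.
Every run writes its exact configuration (YAML, round-trippable) and a JSON
results bundle into the output directory, so reruns with a saved config
reproduce the deterministic outputs byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import agreement as agr
from .elasticity import elasticity_report
from .io import CineSequence, MaskSequence, PressurePair, load_mask_sequence, load_pressures, load_sequence
from .metrics import evaluate_masks
from .phantom import PhantomConfig, generate_phantom
from .tensile import load_tensile_csv, max_youngs_modulus, modulus_curve, stress_strain_curve
from .training import TrainConfig, TrainedModel, predict_mask, train
from .unet import UNetConfig

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible run needs.

    Either ``n_phantom_exams`` > 0 (synthetic study) or ``sequence_paths``
    (NIfTI volumes with YAML sidecars; mask paths aligned by position).
    ``checkpoint`` skips training and loads an existing model.
    """

    out_dir: str = "aortamech-run"
    seed: int = 0
    # data
    n_phantom_exams: int = 0
    n_test_exams: int = 1
    phantom: dict = field(default_factory=dict)
    sequence_paths: tuple[str, ...] = ()
    mask_paths: tuple[str, ...] = ()
    # model
    checkpoint: str | None = None
    unet: dict = field(default_factory=dict)
    train_cfg: dict = field(default_factory=dict)
    cross_validate: bool = False
    # analysis
    rotation_deg: float = 60.0
    tensile_csvs: tuple[str, ...] = ()
    smoothing_window: int = 11

    def to_yaml(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("sequence_paths", "mask_paths", "tensile_csvs"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        for key in ("phantom", "unet", "train_cfg"):
            for field_name, value in (data.get(key) or {}).items():
                if isinstance(value, list):
                    data[key][field_name] = tuple(value)
        return cls(**data)


def _load_exams(cfg: PipelineConfig):
    """Returns (train_exams, test_exams, pressures per test exam, truths or None)."""
    rng_seed = cfg.seed
    if cfg.n_phantom_exams > 0:
        exams, truths, pressures = [], [], []
        total = cfg.n_phantom_exams + cfg.n_test_exams
        for i in range(total):
            pcfg = PhantomConfig(**{**cfg.phantom, "seed": rng_seed + i})
            seq, masks, truth = generate_phantom(pcfg)
            exams.append((seq, masks))
            truths.append(truth)
            pressures.append(pcfg.pressure_pair)
        n_train = cfg.n_phantom_exams
        return exams[:n_train], exams[n_train:], pressures[n_train:], truths[n_train:]
    if not cfg.sequence_paths:
        raise ValueError("no data: set n_phantom_exams > 0 or provide sequence_paths")
    exams, pressures = [], []
    for i, spath in enumerate(cfg.sequence_paths):
        seq = load_sequence(spath)
        masks = load_mask_sequence(cfg.mask_paths[i]) if i < len(cfg.mask_paths) else None
        exams.append((seq, masks))
        try:
            pressures.append(load_pressures(spath))
        except ValueError:
            pressures.append(None)
    return exams, exams, pressures, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the results bundle (also on disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    results: dict = {"seed": cfg.seed}

    train_exams, test_exams, test_pressures, truths = _load_exams(cfg)

    unet_cfg = UNetConfig(**cfg.unet)
    if cfg.checkpoint:
        model = TrainedModel.load(cfg.checkpoint)
    else:
        if any(m is None for _, m in train_exams):
            raise ValueError("training requested but some exams have no masks")
        tcfg = TrainConfig(**{**cfg.train_cfg, "seed": cfg.seed})
        model = train(train_exams, unet_cfg, tcfg, cross_validate=cfg.cross_validate)
        model.save(out / "model.npz")

    seg_rows, gt_compliances, pred_compliances = [], [], []
    elasticity_reports = []
    for i, (seq, gt_masks) in enumerate(test_exams):
        pred = predict_mask(model, seq)
        pressures = test_pressures[i]
        if gt_masks is not None:
            m = evaluate_masks(pred.frames, gt_masks.frames, seq.pixel_spacing, seq.exam_id)
            seg_rows.append(m.per_image)
        if pressures is None:
            raise ValueError(
                f"compliance requested for exam {seq.exam_id!r} but no pressures are "
                "available (record systolic/diastolic mmHg in the YAML sidecar)"
            )
        report = elasticity_report(pred, pressures, cfg.rotation_deg)
        elasticity_reports.append(report)
        report.save_json(out / f"elasticity_{seq.exam_id}.json")
        pred_compliances.append(report.global_compliance)
        if gt_masks is not None:
            gt_report = elasticity_report(gt_masks, pressures, cfg.rotation_deg)
            gt_compliances.append(gt_report.global_compliance)

    if seg_rows:
        import pandas as pd

        per_image = pd.concat(seg_rows, ignore_index=True)
        per_image.to_csv(out / "segmentation_metrics.csv", index=False)
        results["segmentation"] = {
            "dice_mean": float(per_image["dice"].mean()),
            "dice_std": float(per_image["dice"].std(ddof=1)) if len(per_image) > 1 else 0.0,
            "iou_mean": float(per_image["iou"].mean()),
            "hausdorff_mm_mean": float(per_image["hausdorff_mm"].mean()),
        }
    results["elasticity"] = [r.to_json_dict() for r in elasticity_reports]
    if truths is not None:
        results["truth_compliance"] = [t.true_compliance for t in truths]
        results["truth_strain"] = [t.true_strain for t in truths]
    if len(gt_compliances) >= 2:
        ba = agr.bland_altman(pred_compliances, gt_compliances)
        results["compliance_agreement"] = ba.to_json_dict()

    tensile_results = []
    for path in cfg.tensile_csvs:
        record = load_tensile_csv(path)
        curve = stress_strain_curve(record)
        mod = modulus_curve(curve, cfg.smoothing_window)
        tensile_results.append(
            {"path": str(path), "axis": record.axis, "e_max_mpa": max_youngs_modulus(mod)}
        )
    if tensile_results:
        results["tensile"] = tensile_results

    (out / "results.json").write_text(json.dumps(results, indent=2))
    return results
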
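"""Study-level orchestration: configuration and the end-to-end pipeline.

``run_study`` wires the stages together for one imaging study:

    raw volumes -> FF/EF maps -> normalized features -> training set
    (image ROIs + synthesized novelty ROIs) -> [optional hyperparameter
    search] -> fit classifier -> classify VOI -> MRF de-noising -> habitat
    summary + overlay exports

Every stage failure aborts with the stage name; a JSON report records seed,
versions and per-stage provenance so any output is reproducible from the
configuration alone. All randomness descends from the single top-level seed.
"""

from __future__ import annotations

import json
import pickle
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import FAMILIES, GaussianNBModel, fit_classifier, classify_volume
from .crossval import run_cv
from .habitat_analysis import export_overlay, summarize_habitats, summary_to_json
from .mrf import MRFConfig, smooth_study
from .parameter_maps import (
    compute_enhancement_fraction,
    compute_fat_fraction,
    normalize_features,
)
from .training_data import (
    assemble_training_set,
    extract_roi_samples,
    load_roi_table,
    synthesize_novelty_rois,
)
from .volumes_io import Quantity, check_alignment, read_mask, read_volume, write_volume

__all__ = ["StudyConfig", "run_study"]

_REQUIRED_INPUTS = ("dixon_fat", "dixon_water", "t1_pre", "t1_post", "adc", "voi")


@dataclass
class StudyConfig:
    """Validated configuration for one end-to-end study run."""

    inputs: dict                       # role -> NIfTI path, roles as in _REQUIRED_INPUTS
    roi_table: str                     # CSV sidecar with roi_id/patient_id/class_id/mask_path
    out_dir: str
    family: str = "NB"
    hyperparameter: object = None      # scalar, None, or "auto" for a grid search
    holdout_patients: tuple = ()
    n_novelty_rois: int = 15
    mrf_beta: float = 1.0
    mrf_neighborhood: str = "2d8"
    mrf_max_iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        missing = [k for k in _REQUIRED_INPUTS if k not in self.inputs]
        if missing:
            raise ValueError(f"config is missing input roles: {missing}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        for role, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {role!r}: no such file {path}")
        if not Path(self.roi_table).exists():
            raise FileNotFoundError(f"ROI table not found: {self.roi_table}")

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        payload = json.loads(Path(path).read_text())
        payload["holdout_patients"] = tuple(payload.get("holdout_patients", ()))
        return cls(**payload)


def _mask_from_table_row(row, grid_ref):
    mask = read_mask(row.mask_path, label=str(row.roi_id))
    return mask


def run_study(config: StudyConfig) -> dict:
    """Execute the full pipeline for one study and write all outputs.

    Returns the report dict (also written to ``out_dir/report.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stages": [],
    }

    def stage(name):
        entry = {"stage": name, "status": "running", "started": time.time()}
        report["stages"].append(entry)
        return entry

    def fail(entry, exc):
        entry["status"] = "failed"
        entry["error"] = str(exc)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"stage {entry['stage']!r} failed: {exc}") from exc

    # -- compute-maps ------------------------------------------------------
    entry = stage("compute-maps")
    try:
        vols = {role: read_volume(path, {
            "dixon_fat": Quantity.SIGNAL, "dixon_water": Quantity.SIGNAL,
            "t1_pre": Quantity.SIGNAL, "t1_post": Quantity.SIGNAL,
            "adc": Quantity.ADC,
        }[role]) for role, path in config.inputs.items() if role != "voi"}
        voi = read_mask(config.inputs["voi"], label="voi")
        alignment = check_alignment(volumes=list(vols.values()), masks=[voi])
        if not alignment.ok:
            raise ValueError("; ".join(alignment.mismatches))
        ff = compute_fat_fraction(vols["dixon_fat"], vols["dixon_water"])
        ef = compute_enhancement_fraction(vols["t1_pre"], vols["t1_post"])
        features = normalize_features(vols["adc"], ef, ff)
        write_volume(ff, out_dir / "ff.nii.gz")
        write_volume(ef, out_dir / "ef.nii.gz")
        entry["outputs"] = ["ff.nii.gz", "ef.nii.gz"]
        entry["status"] = "ok"
    except Exception as exc:
        fail(entry, exc)

    # -- make-training -----------------------------------------------------
    entry = stage("make-training")
    try:
        table = load_roi_table(config.roi_table)
        image_rois = []
        for row in table.itertuples():
            mask = _mask_from_table_row(row, features.grid)
            image_rois.append(extract_roi_samples(
                features, mask, class_id=int(row.class_id), roi_id=str(row.roi_id),
                patient_id=str(row.patient_id), timepoint=str(row.timepoint)))
        novelty = synthesize_novelty_rois(n_rois=config.n_novelty_rois,
                                          seed=config.seed)
        cv_set, test_set = assemble_training_set(image_rois, novelty,
                                                 config.holdout_patients)
        entry["n_image_rois"] = len(image_rois)
        entry["n_novelty_rois"] = len(novelty)
        entry["cv_class_counts"] = {str(k): v for k, v in cv_set.class_counts().items()}
        entry["status"] = "ok"
    except Exception as exc:
        fail(entry, exc)

    # -- crossval (optional) ----------------------------------------------
    hyperparameter = config.hyperparameter
    if hyperparameter == "auto":
        entry = stage("crossval")
        try:
            _, curve = run_cv(cv_set, config.family, seed=config.seed)
            hyperparameter = curve.optimum
            curve.as_frame().to_csv(out_dir / "hyperparameter_curve.csv", index=False)
            entry["optimum"] = hyperparameter
            entry["status"] = "ok"
        except Exception as exc:
            fail(entry, exc)

    # -- train -------------------------------------------------------------
    entry = stage("train")
    try:
        model = fit_classifier(config.family, hyperparameter, cv_set, seed=config.seed)
        if isinstance(model.impl, GaussianNBModel):
            model.impl.to_json(out_dir / "model.json")
            entry["model_file"] = "model.json"
        else:
            with open(out_dir / "model.pkl", "wb") as fh:
                pickle.dump(model, fh)
            manifest = {"family": model.family, "hyperparameter": model.hyperparameter,
                        "seed": model.seed, "n_per_class": model.n_per_class,
                        "metadata": model.metadata, "file": "model.pkl"}
            (out_dir / "model.json").write_text(json.dumps(manifest, indent=2))
            entry["model_file"] = "model.pkl"
        entry["status"] = "ok"
    except Exception as exc:
        fail(entry, exc)

    # -- predict -----------------------------------------------------------
    entry = stage("predict")
    try:
        probs, raw_labels = classify_volume(model, features, voi)
        from .volumes_io import ParameterVolume
        write_volume(ParameterVolume(grid=features.grid,
                                     values=raw_labels.labels.astype(float),
                                     quantity=Quantity.NORMALIZED,
                                     valid=np.ones(features.grid.shape, bool),
                                     name="labels-raw"),
                     out_dir / "labels_raw.nii.gz")
        entry["status"] = "ok"
    except Exception as exc:
        fail(entry, exc)

    # -- mrf-smooth ---------------------------------------------------------
    entry = stage("mrf-smooth")
    try:
        mrf_config = MRFConfig(beta=config.mrf_beta,
                               neighborhood=config.mrf_neighborhood,
                               max_iterations=config.mrf_max_iterations)
        habitat, traces, mrf_summary = smooth_study(probs, voi, mrf_config)
        trace_rows = [(i, it, n) for i, t in enumerate(traces)
                      for it, n in enumerate(t.changes)]
        pd.DataFrame(trace_rows, columns=["slice", "iteration", "changed_voxels"]).to_csv(
            out_dir / "mrf_trace.csv", index=False)
        from .volumes_io import ParameterVolume
        write_volume(ParameterVolume(grid=features.grid,
                                     values=habitat.labels.astype(float),
                                     quantity=Quantity.NORMALIZED,
                                     valid=np.ones(features.grid.shape, bool),
                                     name="labels"),
                     out_dir / "labels.nii.gz")
        entry["median_iterations"] = mrf_summary["median_iterations"]
        entry["status"] = "ok"
    except Exception as exc:
        fail(entry, exc)

    # -- summarize ----------------------------------------------------------
    entry = stage("summarize")
    try:
        summary = summarize_habitats(habitat, vols["adc"], voi)
        summary_to_json(summary, out_dir / "habitat_summary.json")
        summary.as_frame().to_csv(out_dir / "habitat_summary.csv", index=False)
        overlay, legend = export_overlay(habitat)
        (out_dir / "overlay_legend.json").write_text(json.dumps(legend, indent=2))
        entry["fractions"] = {str(c): summary.fractions[c] for c in summary.fractions}
        entry["status"] = "ok"
    except Exception as exc:
        fail(entry, exc)

    report["hyperparameter"] = hyperparameter
    report["family"] = config.family
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
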
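"""End-to-end orchestration: train a model bundle, segment cases, run
experiments.  The CLI is a thin wrapper over these functions."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np

from .experiment import (
    EvalReport,
    PipelineConfig,
    loocv_harness,
    prepare_case,
    _structure_gt,
    _vh_region,
)
from .features import (
    FeatureConfig,
    assemble_features,
    compute_distance_features,
    compute_slic_features,
    compute_std_features,
    compute_tumor_prior,
    compute_vh_mask,
)
from .likelihood import LikelihoodModel, predict_proba, train_rf
from .metrics import dsc, hausdorff, mean_surface_distance
from .mrf import MRFConfig, estimate_sigmas, segment_tumor
from .phantom import PhantomCase, load_case
from .shape_model import ShapeModel, build_shape_model, fit_shape_model, mesh_to_labelmap
from .volume import LABEL_LENS, LABEL_SCLERA, LABEL_TUMOR, LABEL_VH, save_mask_nifti


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "feature" in d and isinstance(d["feature"], dict):
        d["feature"] = FeatureConfig(**d["feature"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    return PipelineConfig(**{k: v for k, v in d.items() if k in known})


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log(bundle_dir: Path, record: dict) -> None:
    with open(bundle_dir / "log.jsonl", "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def load_cohort(cohort_dir: str | Path) -> list[PhantomCase]:
    cohort_dir = Path(cohort_dir)
    case_dirs = sorted(p for p in cohort_dir.iterdir() if (p / "manifest.json").exists())
    missing = [str(p) for p in cohort_dir.iterdir() if p.is_dir() and not (p / "manifest.json").exists()]
    if missing:
        warnings.warn(f"skipping directories without manifest.json: {missing}", stacklevel=2)
    if not case_dirs:
        raise FileNotFoundError(f"no cases found under {cohort_dir}")
    return [load_case(p) for p in case_dirs]


def run_train(cohort_dir: str | Path, out_dir: str | Path, config: PipelineConfig | None = None):
    """Build the model bundle: shape model + tumor prior + RF likelihood."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = load_cohort(cohort_dir)
    canon = [prepare_case(c, config) for c in cases]
    if len(canon) == 1:
        warnings.warn("single training case: shape model degenerates to zero modes", stacklevel=2)

    model = build_shape_model(
        canon, config.variance_kept, config.profile_k, config.profile_spacing_mm
    )
    model.save(out_dir / "shape_model.h5")

    tumor_masks = [c.labels.data == LABEL_TUMOR for c in canon]
    prior = compute_tumor_prior(tumor_masks, canon[0].volume.spacing, config.feature.prior_sigma_mm)
    np.save(out_dir / "tumor_prior.npy", prior)
    s1, s2 = estimate_sigmas([c.volume for c in canon], tumor_masks)

    theta = config.theta_by_feature_set["epsf"]
    X_parts, y_parts = [], []
    stack = None
    for c, tm in zip(canon, tumor_masks):
        mask = compute_vh_mask(_vh_region(c.labels.data), c.volume.spacing, theta)
        f_l, f_vh = compute_distance_features(c.labels)
        stack = assemble_features(
            compute_std_features(c.volume, config.feature),
            compute_slic_features(c.volume, config.feature),
            {"f_l": f_l, "f_vh": f_vh, "f_t": prior},
            mask,
            c.volume.spacing,
            use_epsf=True,
        )
        X_parts.append(stack.matrix())
        y_parts.append(tm[mask])
    rf = train_rf(
        np.concatenate(X_parts),
        np.concatenate(y_parts),
        feature_names=stack.feature_order,
        n_trees=config.n_trees,
        neg_fraction=config.neg_fraction,
        seed=config.seed,
    )
    rf.save(out_dir / "likelihood.joblib")

    (out_dir / "config.json").write_text(json.dumps(
        {**config_to_dict(config), "sigma_t1_sq": s1, "sigma_t2_sq": s2}, indent=2, sort_keys=True
    ))
    _log(out_dir, {
        "event": "train",
        "n_cases": len(cases),
        "seed": config.seed,
        "oob_score": rf.training_log.get("oob_score"),
        "checksums": {p.name: _file_checksum(p) for p in sorted(out_dir.glob("*"))
                      if p.is_file() and p.name != "log.jsonl"},
    })
    return out_dir


def run_segment(bundle_dir: str | Path, case_dir: str | Path, out_dir: str | Path):
    """Segment one case with a trained bundle; metrics written when GT exists."""
    bundle_dir, out_dir = Path(bundle_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stored = json.loads((bundle_dir / "config.json").read_text())
    config = config_from_dict(stored)
    model = ShapeModel.load(bundle_dir / "shape_model.h5")
    prior = np.load(bundle_dir / "tumor_prior.npy")
    rf = LikelihoodModel.load(bundle_dir / "likelihood.joblib")

    case = load_case(case_dir)
    canon = prepare_case(case, config)
    fit = fit_shape_model(model, canon.volume)
    fitted = mesh_to_labelmap(fit.meshes, canon.volume.shape, canon.volume.spacing, canon.volume.origin)
    fitted.save(out_dir / "structures.nii.gz")

    theta = config.theta_by_feature_set["epsf"]
    mask = compute_vh_mask(fitted.data == LABEL_VH, canon.volume.spacing, theta)
    f_l, f_vh = compute_distance_features(fitted)
    stack = assemble_features(
        compute_std_features(canon.volume, config.feature),
        compute_slic_features(canon.volume, config.feature),
        {"f_l": f_l, "f_vh": f_vh, "f_t": prior},
        mask,
        canon.volume.spacing,
        use_epsf=True,
    )
    prob = predict_proba(rf, stack)
    save_mask_nifti(prob.data, canon.volume.spacing, canon.volume.origin, out_dir / "tumor_prob.nii.gz")
    mrf_config = MRFConfig(
        alpha=config.alpha, lam=config.lam,
        sigma_t1_sq=stored.get("sigma_t1_sq", 1.0), sigma_t2_sq=stored.get("sigma_t2_sq", 1.0),
    )
    gc = segment_tumor(prob, canon.volume, mask, mrf_config)
    save_mask_nifti(gc, canon.volume.spacing, canon.volume.origin, out_dir / "tumor_labeling.nii.gz")

    result = {"converged": bool(fit.converged), "iterations": int(fit.iterations)}
    gt_tumor = canon.labels.data == LABEL_TUMOR
    if gt_tumor.any():
        result["metrics"] = {
            "tumor_dsc_gc": dsc(gt_tumor, gc),
            "tumor_hd_mm": hausdorff(gt_tumor, gc, canon.volume.spacing) if gc.any() else None,
            "tumor_msd_mm": mean_surface_distance(gt_tumor, gc, canon.volume.spacing) if gc.any() else None,
            "structure_dsc": {
                s: dsc(_structure_gt(canon.labels.data, s), fitted.data == code)
                for s, code in (("sclera", LABEL_SCLERA), ("vh", LABEL_VH), ("lens", LABEL_LENS))
            },
        }
    (out_dir / "result.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return result


def run_experiment(
    cohort_dir_or_cases,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    feature_sets: tuple[str, ...] = ("std", "epsf"),
) -> EvalReport:
    """Drive the LOOCV harness and write report.csv + summary.json."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(cohort_dir_or_cases, (str, Path)):
        cases = load_cohort(cohort_dir_or_cases)
    else:
        cases = list(cohort_dir_or_cases)

    import pandas as pd

    from .experiment import _summarize

    manifest = {
        "config": config_to_dict(config),
        "feature_sets": list(feature_sets),
        "case_seeds": [int(c.params.seed) for c in cases],
    }
    manifest_path = out_dir / "manifest.json"
    report_path = out_dir / "report.csv"
    if manifest_path.exists() and report_path.exists():
        if json.loads(manifest_path.read_text()) == json.loads(json.dumps(manifest)):
            df = pd.read_csv(report_path)
            return EvalReport(df, _summarize(df, feature_sets))

    report = loocv_harness(cases, config, feature_sets)
    report.to_csv(report_path)
    (out_dir / "summary.json").write_text(json.dumps(report.summary, indent=2, sort_keys=True))
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
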
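"""Cross-validation harness mirroring the evaluation design of the method.

`loocv_harness` runs a leave-one-out experiment over a phantom cohort: per
fold it builds the pathological shape model on the training cases, fits it
to the held-out case, derives the θ-band and patient-specific features,
trains the random-forest likelihood (tumor prior from training folds only),
infers the MAP labeling by graph cut, and evaluates DSC / Hausdorff / mean
surface distance / AUC before and after the cut, for STD-only and
STD+EPSF feature sets.

`pm_vs_hm_experiment` compares a shape model trained on pathological cases
(PM) against one trained on tumor-free cases (HM) when both segment held-out
pathological eyes — the same build code path on two cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    FeatureConfig,
    compute_distance_features,
    compute_feature_stack,
    compute_slic_features,
    compute_std_features,
    compute_tumor_prior,
    compute_vh_mask,
    assemble_features,
)
from .likelihood import train_rf, predict_proba
from .metrics import dsc, hausdorff, mean_surface_distance, roc_auc
from .mrf import MRFConfig, estimate_sigmas, segment_tumor
from .phantom import PhantomCase, PhantomParams, generate_cohort
from .preprocess import NormalizationMap, align_to_canonical
from .shape_model import build_shape_model, fit_shape_model, mesh_to_labelmap
from .volume import LABEL_LENS, LABEL_SCLERA, LABEL_TUMOR, LABEL_VH

import trimesh


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline with the method's defaults."""

    variance_kept: float = 0.95
    profile_k: int = 7
    profile_spacing_mm: float = 0.75
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    theta_by_feature_set: dict = field(default_factory=lambda: {"std": 0.0, "epsf": 2.0})
    n_trees: int = 200
    neg_fraction: float = 0.2
    alpha: float = 0.3
    lam: float = 0.7
    norm_percentiles: tuple[float, float] = (1.0, 99.0)
    norm_targets: tuple[float, float] = (0.0, 100.0)
    seed: int = 0


@dataclass
class EvalReport:
    """Per-case rows plus cohort aggregates and paired-test p-values."""

    cases: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.cases.to_csv(path, index=False, float_format="%.6f")


def prepare_case(case: PhantomCase, config: PipelineConfig) -> PhantomCase:
    """Canonical alignment (from the case landmarks) + intensity normalization."""
    volume, labels, transform = align_to_canonical(case.volume, case.labels, case.landmarks)
    for name in list(volume.channels):
        nm = NormalizationMap.from_channel(
            volume.channels[name], config.norm_percentiles, config.norm_targets
        )
        volume.channels[name] = nm.apply(volume.channels[name])
    meshes = {
        name: trimesh.Trimesh(transform.apply(m.vertices), m.faces.copy(), process=False)
        for name, m in case.meshes.items()
    }
    landmarks = {k: transform.apply(v) for k, v in case.landmarks.items()}
    return PhantomCase(volume, labels, landmarks, meshes, case.params)


def _vh_region(labels: np.ndarray) -> np.ndarray:
    # anatomical vitreous chamber: VH plus any endophytic tumor inside it
    return (labels == LABEL_VH) | (labels == LABEL_TUMOR)


def _structure_gt(labels: np.ndarray, name: str) -> np.ndarray:
    if name == "sclera":
        return labels == LABEL_SCLERA
    if name == "vh":
        return _vh_region(labels)
    if name == "lens":
        return labels == LABEL_LENS
    raise KeyError(name)


def _case_planes(case: PhantomCase, config: PipelineConfig) -> dict:
    """Fold-independent per-case planes (intensity features, GT geometry)."""
    std = compute_std_features(case.volume, config.feature)
    slic = compute_slic_features(case.volume, config.feature)
    f_l, f_vh = compute_distance_features(case.labels)
    return {
        "std": std,
        "slic": slic,
        "f_l": f_l,
        "f_vh": f_vh,
        "tumor": case.labels.data == LABEL_TUMOR,
        "vh_region": _vh_region(case.labels.data),
    }


def loocv_harness(
    cases: list[PhantomCase],
    config: PipelineConfig | None = None,
    feature_sets: tuple[str, ...] = ("std", "epsf"),
    preprocessed: bool = False,
) -> EvalReport:
    """Leave-one-out evaluation over the cohort and feature-set grid."""
    config = config or PipelineConfig()
    if len(cases) < 3:
        raise ValueError("LOOCV needs a cohort of at least 3 cases")
    canon = cases if preprocessed else [prepare_case(c, config) for c in cases]
    planes = [_case_planes(c, config) for c in canon]

    rows = []
    for k, test in enumerate(canon):
        train_idx = [i for i in range(len(canon)) if i != k]
        if not planes[k]["tumor"].any():
            warnings.warn(f"fold {k}: held-out case has no tumor voxels; skipped", stacklevel=2)
            continue
        train_cases = [canon[i] for i in train_idx]

        model = build_shape_model(
            train_cases, config.variance_kept, config.profile_k, config.profile_spacing_mm
        )
        fit = fit_shape_model(model, test.volume)
        fitted = mesh_to_labelmap(
            fit.meshes, test.volume.shape, test.volume.spacing, test.volume.origin
        )

        for sname in ("sclera", "vh", "lens"):
            gt = _structure_gt(test.labels.data, sname)
            pred = fitted.data == {"sclera": LABEL_SCLERA, "vh": LABEL_VH, "lens": LABEL_LENS}[sname]
            rows.append(
                {
                    "case": k,
                    "target": sname,
                    "feature_set": "shape_model",
                    "dsc": dsc(gt, pred),
                    "dsc_gc": np.nan,
                    "auc": np.nan,
                    "hd_mm": hausdorff(gt, pred, test.volume.spacing),
                    "msd_mm": mean_surface_distance(gt, pred, test.volume.spacing),
                    "tumor_radius_mm": test.params.tumor_radius_mm,
                }
            )

        prior = compute_tumor_prior(
            [planes[i]["tumor"] for i in train_idx],
            test.volume.spacing,
            config.feature.prior_sigma_mm,
        )
        s1, s2 = estimate_sigmas(
            [canon[i].volume for i in train_idx], [planes[i]["tumor"] for i in train_idx]
        )
        mrf_config = MRFConfig(
            alpha=config.alpha, lam=config.lam, sigma_t1_sq=s1, sigma_t2_sq=s2
        )
        fitted_vh = fitted.data == LABEL_VH

        for fi, fset in enumerate(feature_sets):
            use_epsf = fset == "epsf"
            theta = config.theta_by_feature_set[fset]

            X_parts, y_parts = [], []
            for i in train_idx:
                tr_mask = compute_vh_mask(planes[i]["vh_region"], canon[i].volume.spacing, theta)
                epsf_planes = (
                    {"f_l": planes[i]["f_l"], "f_vh": planes[i]["f_vh"], "f_t": prior}
                    if use_epsf
                    else None
                )
                stack = assemble_features(
                    planes[i]["std"], planes[i]["slic"], epsf_planes, tr_mask,
                    canon[i].volume.spacing, use_epsf,
                )
                X_parts.append(stack.matrix())
                y_parts.append(planes[i]["tumor"][tr_mask])
            X_train = np.concatenate(X_parts)
            y_train = np.concatenate(y_parts)

            rf = train_rf(
                X_train,
                y_train,
                feature_names=stack.feature_order,
                n_trees=config.n_trees,
                neg_fraction=config.neg_fraction,
                seed=(config.seed * 1009 + 31 * k + fi) % (2**31 - 1),
            )

            test_mask = compute_vh_mask(fitted_vh, test.volume.spacing, theta)
            if use_epsf:
                f_l_t, f_vh_t = compute_distance_features(fitted)
                test_epsf = {"f_l": f_l_t, "f_vh": f_vh_t, "f_t": prior}
            else:
                test_epsf = None
            test_stack = assemble_features(
                planes[k]["std"], planes[k]["slic"], test_epsf, test_mask,
                test.volume.spacing, use_epsf,
            )
            prob = predict_proba(rf, test_stack)

            gt_tumor = planes[k]["tumor"]
            raw = prob.data > 0.5
            gc = segment_tumor(prob, test.volume, test_mask, mrf_config)
            gt_in_mask = gt_tumor[test_mask]
            if gt_in_mask.any() and not gt_in_mask.all():
                _, _, auc = roc_auc(prob.data, gt_tumor, test_mask)
            else:
                warnings.warn(f"fold {k}/{fset}: single-class θ-band; AUC undefined", stacklevel=2)
                auc = np.nan
            rows.append(
                {
                    "case": k,
                    "target": "tumor",
                    "feature_set": fset,
                    "dsc": dsc(gt_tumor, raw),
                    "dsc_gc": dsc(gt_tumor, gc),
                    "auc": auc,
                    "hd_mm": hausdorff(gt_tumor, gc, test.volume.spacing) if gc.any() else np.nan,
                    "msd_mm": mean_surface_distance(gt_tumor, gc, test.volume.spacing)
                    if gc.any()
                    else np.nan,
                    "tumor_radius_mm": test.params.tumor_radius_mm,
                }
            )

    df = pd.DataFrame(rows)
    return EvalReport(df, _summarize(df, feature_sets))


def _summarize(df: pd.DataFrame, feature_sets: tuple[str, ...]) -> dict:
    summary: dict = {}
    for (target, fset), grp in df.groupby(["target", "feature_set"]):
        key = f"{target}_{fset}"
        summary[key] = {
            "dsc_mean": float(grp["dsc"].mean()),
            "dsc_sd": float(grp["dsc"].std()),
            "dsc_gc_mean": float(grp["dsc_gc"].mean()),
            "auc_mean": float(grp["auc"].mean()),
            "hd_mean_mm": float(grp["hd_mm"].mean()),
            "msd_mean_mm": float(grp["msd_mm"].mean()),
            "n": int(len(grp)),
        }
    tumors = df[df["target"] == "tumor"]
    if {"std", "epsf"} <= set(feature_sets) and len(tumors):
        piv = tumors.pivot(index="case", columns="feature_set", values="dsc_gc").dropna()
        if len(piv) >= 2:
            t, p = stats.ttest_rel(piv["epsf"], piv["std"])
            summary["paired_ttest_epsf_vs_std_dsc_gc"] = {"t": float(t), "p": float(p)}
    for fset in feature_sets:
        sub = tumors[tumors["feature_set"] == fset][["dsc", "dsc_gc"]].dropna()
        if len(sub) >= 2:
            t, p = stats.ttest_rel(sub["dsc_gc"], sub["dsc"])
            summary[f"paired_ttest_gc_vs_raw_{fset}"] = {"t": float(t), "p": float(p)}
    return summary


def tumor_size_bins(report: EvalReport, feature_set: str = "epsf", n_bins: int = 3) -> pd.DataFrame:
    """Mean tumor DSC (after graph cut) per tumor-radius bin, small to large."""
    t = report.cases
    t = t[(t["target"] == "tumor") & (t["feature_set"] == feature_set)].copy()
    t = t.sort_values("tumor_radius_mm").reset_index(drop=True)
    t["size_bin"] = pd.qcut(t["tumor_radius_mm"], q=n_bins, labels=False)
    return t.groupby("size_bin").agg(
        dsc_gc_mean=("dsc_gc", "mean"),
        radius_min=("tumor_radius_mm", "min"),
        radius_max=("tumor_radius_mm", "max"),
        n=("case", "count"),
    )


def pm_vs_hm_experiment(
    seed: int = 0,
    n_train: int = 8,
    n_test: int = 4,
    config: PipelineConfig | None = None,
    base_params: PhantomParams | None = None,
) -> dict:
    """Fit pathological-trained vs healthy-trained shape models to held-out
    pathological cases; returns mean per-structure DSC for both."""
    config = config or PipelineConfig()
    base = base_params or PhantomParams()
    path_cases = generate_cohort(n_train + n_test, base=base, seed=seed)
    healthy_cases = generate_cohort(
        n_train, base=replace(base, with_tumor=False), seed=seed + 104729
    )
    path_canon = [prepare_case(c, config) for c in path_cases]
    healthy_canon = [prepare_case(c, config) for c in healthy_cases]

    pm = build_shape_model(
        path_canon[:n_train], config.variance_kept, config.profile_k, config.profile_spacing_mm
    )
    hm = build_shape_model(
        healthy_canon, config.variance_kept, config.profile_k, config.profile_spacing_mm
    )

    results: dict = {"pm": {}, "hm": {}}
    per_structure: dict = {m: {s: [] for s in ("sclera", "vh", "lens")} for m in ("pm", "hm")}
    for test in path_canon[n_train:]:
        for mname, model in (("pm", pm), ("hm", hm)):
            fit = fit_shape_model(model, test.volume)
            fitted = mesh_to_labelmap(
                fit.meshes, test.volume.shape, test.volume.spacing, test.volume.origin
            )
            for sname in ("sclera", "vh", "lens"):
                gt = _structure_gt(test.labels.data, sname)
                pred = fitted.data == {
                    "sclera": LABEL_SCLERA, "vh": LABEL_VH, "lens": LABEL_LENS
                }[sname]
                per_structure[mname][sname].append(dsc(gt, pred))
    for mname in ("pm", "hm"):
        for sname, vals in per_structure[mname].items():
            results[mname][sname] = float(np.mean(vals))
        results[mname]["mean"] = float(
            np.mean([results[mname][s] for s in ("sclera", "vh", "lens")])
        )
    return results
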
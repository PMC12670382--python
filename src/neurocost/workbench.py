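"""Config-driven end-to-end runs tying the DNN arm and the fMRI arm together.

A single global seed derives every stage seed by fixed offsets, so arms are
independently re-runnable yet jointly reproducible.  All statistics land in
one machine-readable summary JSON (timestamp-free, so identical configs give
bit-identical summaries); the log captures versions, seeds, and decisions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .activation import EnsembleSpec, compute_layer_costs, ensemble_statistics
from .association import (CVConfig, cv_predict, nonparametric_p,
                          per_layer_associations, spearman_assoc)
from .fmri import (aggregate_roi_costs, roi_associations, sparseness_association,
                   sparseness_profile, voxelwise_map)
from .nn import toy_cnn
from .ratings import normalize_ratings
from .synthetic import (DEFAULT_ROIS, PlantedLinkSpec, SyntheticBetaSpec,
                        SyntheticImageSpec, gen_images, gen_ratings_from_cost,
                        gen_voxel_betas, train_toy_classifier)

logger = logging.getLogger("neurocost.workbench")

_STAGE_OFFSETS = {"images": 1, "link": 2, "train": 3, "betas": 4, "ratings": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed by documented offsets."""
    return (global_seed * 1_000_003 + _STAGE_OFFSETS[stage]) % (2 ** 31)


@dataclass
class ExperimentConfig:
    """Everything an end-to-end run needs; JSON round-trippable.

    When the input paths are None the corresponding inputs are synthesized
    with planted structure (the demo mode); paths, when given, must exist at
    validation time.
    """

    arm: str = "both"                  # "dnn" | "fmri" | "both"
    out_dir: str = "neurocost_run"
    seed: int = 0
    # DNN arm
    metric: str = "active_count"
    n_images: int = 200
    side_px: int = 32
    n_ensemble: int = 50
    target_rho: float = -0.3
    images_dir: str | None = None
    ratings_csv: str | None = None     # raw table: participant_id,image_id,rating
    # fMRI arm
    n_images_fmri: int = 200
    rois: tuple = DEFAULT_ROIS
    voxels_per_roi: int = 12
    repeats: int = 2
    n_subjects: int = 4
    planted_roi_rho: dict = field(default_factory=lambda: {"PPA": -0.4})
    beta_noise_sd: float = 1.0
    alpha: float = 1e-4
    betas_csv: str | None = None
    # shared
    cv_k: int = 10
    cv_seed: int = 0

    def validate(self) -> None:
        if self.arm not in ("dnn", "fmri", "both"):
            raise ValueError(f"arm must be dnn|fmri|both, got {self.arm!r}")
        for label in ("images_dir", "ratings_csv", "betas_csv"):
            path = getattr(self, label)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{label} does not exist: {path}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = json.load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.rois, list):
            cfg.rois = tuple(cfg.rois)
        return cfg


# ---------------------------------------------------------------------------
# arms


def _dnn_arm(cfg: ExperimentConfig, out: str) -> dict:
    logger.info("DNN arm: %d images @ %dpx, metric=%s, %d-seed ensemble",
                cfg.n_images, cfg.side_px, cfg.metric, cfg.n_ensemble)
    if cfg.images_dir is not None:
        from PIL import Image as PILImage
        from .activation import preprocess_image
        names = sorted(f for f in os.listdir(cfg.images_dir)
                       if f.lower().endswith((".png", ".jpg", ".jpeg")))
        images = [preprocess_image(PILImage.open(os.path.join(cfg.images_dir, f)),
                                   side=cfg.side_px) for f in names]
        ids = names
    else:
        spec = SyntheticImageSpec(n_images=cfg.n_images, side_px=cfg.side_px,
                                  seed=stage_seed(cfg.seed, "images"))
        images = [img.astype(np.float32).transpose(2, 0, 1) / 255.0
                  for img in gen_images(spec)]
        ids = [f"synth{i:04d}" for i in range(len(images))]

    net, train_report = train_toy_classifier(
        seed=stage_seed(cfg.seed, "train"), side=24)
    logger.info("toy classifier held-out accuracy %.3f (chance %.3f)",
                train_report["test_acc"], train_report["chance"])

    costs = compute_layer_costs(net, images, metric=cfg.metric, image_ids=ids)
    costs.to_csv(os.path.join(out, "layer_costs.csv"))

    if cfg.ratings_csv is not None:
        normalized = normalize_ratings(pd.read_csv(cfg.ratings_csv))
        y = normalized.vector_for(ids)
    else:
        link = PlantedLinkSpec(target_rho=cfg.target_rho,
                               seed=stage_seed(cfg.seed, "link"))
        y = gen_ratings_from_cost(costs.totals, link)

    total_assoc = spearman_assoc(costs.totals, y)
    logger.info("total-cost Spearman rho=%.3f p=%.3g",
                total_assoc.rho, total_assoc.p)

    ens = EnsembleSpec(arch_factory=toy_cnn,
                       seeds=tuple(range(cfg.n_ensemble)), metric=cfg.metric)
    nulls = ensemble_statistics(
        ens, images, stat=lambda m: spearman_assoc(m.totals, y).rho)
    ensemble_p = nonparametric_p(total_assoc.rho, nulls, tail="lower")
    logger.info("ensemble p=%.4f over %d untrained models",
                ensemble_p, cfg.n_ensemble)

    cv = cv_predict(costs, y, CVConfig(k=cfg.cv_k, seed=cfg.cv_seed))
    cv.to_frame().to_csv(os.path.join(out, "cv_predictions.csv"), index=False)
    per_layer = per_layer_associations(costs, y)
    per_layer.to_csv(os.path.join(out, "per_layer_associations.csv"),
                     index=False)

    return {
        "n_images": len(ids),
        "metric": cfg.metric,
        "toy_classifier": train_report,
        "total_cost_rho": total_assoc.rho,
        "total_cost_p": total_assoc.p,
        "ensemble_null_rhos": nulls.tolist(),
        "ensemble_p": ensemble_p,
        "cv_accuracy_rho": cv.accuracy_rho,
        "cv_accuracy_p": cv.accuracy_p,
        "full_r2": cv.full_r2,
        "cv_train_r2": cv.cv_train_r2,
        "cumulative_r2": cv.cumulative_r2.tolist(),
    }


def _fmri_arm(cfg: ExperimentConfig, out: str) -> dict:
    logger.info("fMRI arm: %d images, %d subjects, %d ROIs x %d voxels",
                cfg.n_images_fmri, cfg.n_subjects, len(cfg.rois),
                cfg.voxels_per_roi)
    rng = np.random.default_rng(stage_seed(cfg.seed, "ratings"))
    ratings = rng.standard_normal(cfg.n_images_fmri)
    if cfg.betas_csv is not None:
        betas = pd.read_csv(cfg.betas_csv)
    else:
        spec = SyntheticBetaSpec(
            n_images=cfg.n_images_fmri, n_subjects=cfg.n_subjects,
            rois=tuple(cfg.rois), voxels_per_roi=cfg.voxels_per_roi,
            repeats=cfg.repeats, planted_roi_rho=dict(cfg.planted_roi_rho),
            beta_noise_sd=cfg.beta_noise_sd,
            seed=stage_seed(cfg.seed, "betas"))
        betas = gen_voxel_betas(spec, ratings)

    costs = aggregate_roi_costs(betas)
    rating_series = pd.Series(ratings, index=np.arange(cfg.n_images_fmri))
    assoc = roi_associations(costs, rating_series)
    assoc.to_csv(os.path.join(out, "roi_associations.csv"), index=False)
    profile = sparseness_profile(betas)
    profile.to_csv(os.path.join(out, "roi_sparseness.csv"), index=False)
    r, dof, p = sparseness_association(profile, assoc)
    logger.info("sparseness association r(%d)=%.3f p=%.3f", dof, r, p)

    vmap = voxelwise_map(betas, rating_series, alpha=cfg.alpha)
    vmap.to_csv(os.path.join(out, "voxelwise_map.csv"), index=False)

    cv = cv_predict(costs.pivot("group"), rating_series.to_numpy(),
                    CVConfig(k=cfg.cv_k, seed=cfg.cv_seed))

    return {
        "n_images": cfg.n_images_fmri,
        "roi_associations": assoc.drop(columns=["undefined"])
                                 .to_dict(orient="records"),
        "sparseness": profile.to_dict(orient="records"),
        "sparseness_association": {"r": r, "df": dof, "p": p},
        "voxelwise_flagged": int(vmap["flag"].sum()),
        "voxelwise_total": int(len(vmap)),
        "alpha": cfg.alpha,
        "cross_roi_cv_accuracy_rho": cv.accuracy_rho,
        "cross_roi_cv_accuracy_p": cv.accuracy_p,
        "cross_roi_full_r2": cv.full_r2,
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the configured arm(s) and write tables + summary JSON.

    Any stage failure aborts with a stage-named diagnostic and flags the
    partial summary as incomplete.
    """
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("neurocost")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("neurocost %s | numpy %s | seed %d | arm %s",
                __version__, np.__version__, config.seed, config.arm)

    summary: dict = {"config": asdict(config), "version": __version__,
                     "complete": False}
    try:
        if config.arm in ("dnn", "both"):
            try:
                summary["dnn"] = _dnn_arm(config, out)
            except Exception as err:
                raise RuntimeError(f"DNN arm failed: {err}") from err
        if config.arm in ("fmri", "both"):
            try:
                summary["fmri"] = _fmri_arm(config, out)
            except Exception as err:
                raise RuntimeError(f"fMRI arm failed: {err}") from err
        summary["complete"] = True
    finally:
        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        root.removeHandler(handler)
        handler.close()
    return summary


def format_report(summary: dict) -> str:
    """Human-readable digest; every number also lives in the summary JSON."""
    lines = [f"neurocost run (seed {summary['config']['seed']}, "
             f"arm {summary['config']['arm']})"]
    if "dnn" in summary:
        d = summary["dnn"]
        lines += [
            "DNN arm:",
            f"  total-cost Spearman rho = {d['total_cost_rho']:.3f} "
            f"(p = {d['total_cost_p']:.3g})",
            f"  ensemble p = {d['ensemble_p']:.4f} over "
            f"{len(d['ensemble_null_rhos'])} untrained models",
            f"  CV prediction accuracy rho = {d['cv_accuracy_rho']:.3f}; "
            f"full-model R^2 = {d['full_r2']:.3f}",
        ]
    if "fmri" in summary:
        f = summary["fmri"]
        lines.append("fMRI arm:")
        for rec in f["roi_associations"]:
            lines.append(f"  {rec['roi']}: rho = {rec['rho']:.3f} "
                         f"[{rec['ci_low']:.3f}, {rec['ci_high']:.3f}] "
                         f"(p = {rec['p']:.3g})")
        sa = f["sparseness_association"]
        lines += [
            f"  sparseness association r({sa['df']}) = {sa['r']:.3f} "
            f"(p = {sa['p']:.3f})",
            f"  voxels flagged at alpha={f['alpha']:g}: "
            f"{f['voxelwise_flagged']}/{f['voxelwise_total']}",
            f"  cross-ROI CV accuracy rho = "
            f"{f['cross_roi_cv_accuracy_rho']:.3f}",
        ]
    return "\n".join(lines)
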
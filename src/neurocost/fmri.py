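"""ROI-level metabolic costs from single-trial voxel betas.

The metabolic cost of processing an image in a brain region is the signed
sum of the single-trial beta values (percent signal change) over the
region's voxels; per-presentation sums are averaged over repeats, then over
subjects, giving the image-level series correlated with ratings.  An
exploratory sparseness analysis summarizes each ROI's voxel activity
distribution with the Gini index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import spearman_assoc

logger = logging.getLogger(__name__)

BETA_COLUMNS = ("subject", "image", "presentation", "roi", "voxel", "beta")


def _check_beta_table(betas: pd.DataFrame, need_roi: bool = True) -> None:
    need = [c for c in BETA_COLUMNS if need_roi or c != "roi"]
    missing = [c for c in need if c not in betas.columns]
    if missing:
        raise ValueError(f"beta table missing columns: {missing}")


# ---------------------------------------------------------------------------
# ROI aggregation


@dataclass
class RoiCostTable:
    """ROI-summed betas at three aggregation levels (long format).

    ``per_presentation``: (subject, image, presentation, roi, cost);
    ``per_subject_image``: repeat-averaged; ``per_image``: subject-averaged
    over the subjects contributing each image.
    """

    per_presentation: pd.DataFrame
    per_subject_image: pd.DataFrame
    per_image: pd.DataFrame
    repeat_policy: str = "average"

    @property
    def rois(self) -> list[str]:
        return sorted(self.per_image["roi"].unique())

    def pivot(self, level: str = "group") -> pd.DataFrame:
        """Wide view: images x ROIs (group level) or (subject, image) x ROIs."""
        if level == "group":
            return self.per_image.pivot(index="image", columns="roi",
                                        values="cost")
        if level == "subject":
            return self.per_subject_image.pivot(
                index=["subject", "image"], columns="roi", values="cost")
        raise ValueError(f"level must be 'group' or 'subject', got {level!r}")


def aggregate_roi_costs(betas: pd.DataFrame, roi_map: dict | None = None,
                        repeat_policy: str = "average") -> RoiCostTable:
    """Sum voxel betas into per-presentation ROI costs, then average.

    ``roi_map`` (voxel id -> ROI name) overrides/provides the ROI column;
    voxels absent from the map (or mapped to None) are ignored.  Repeats are
    arithmetically averaged by default; ``repeat_policy='first'`` keeps only
    each image's first presentation (a robustness mode, repetition being
    known to shift aesthetic responses).

    Raises
    ------
    ValueError
        if a referenced ROI ends up with zero voxels, naming the ROI.
    """
    _check_beta_table(betas, need_roi=roi_map is None)
    df = betas.copy()
    if roi_map is not None:
        df["roi"] = df["voxel"].map(roi_map)
        referenced = {r for r in roi_map.values() if r is not None}
        present = set(df.loc[df["roi"].notna(), "roi"].unique())
        empty = sorted(referenced - present)
        if empty:
            raise ValueError(f"ROI(s) with zero voxels: {', '.join(empty)}")
    df = df[df["roi"].notna()]
    if df.empty:
        raise ValueError("no voxels assigned to any ROI")
    if df.duplicated(["subject", "image", "presentation", "voxel"]).any():
        raise ValueError("duplicate (subject, image, presentation, voxel) rows")

    per_pres = (df.groupby(["subject", "image", "presentation", "roi"],
                           sort=True, observed=True)["beta"]
                .sum().rename("cost").reset_index())
    if repeat_policy == "average":
        per_si = (per_pres.groupby(["subject", "image", "roi"], sort=True,
                                   observed=True)["cost"]
                  .mean().reset_index())
    elif repeat_policy == "first":
        first = per_pres.sort_values("presentation").groupby(
            ["subject", "image", "roi"], sort=True, observed=True).first()
        per_si = first.reset_index()[["subject", "image", "roi", "cost"]]
    else:
        raise ValueError(f"repeat_policy must be 'average' or 'first', "
                         f"got {repeat_policy!r}")
    n_subjects = per_si.groupby(["image", "roi"], observed=True)["subject"].nunique()
    if n_subjects.nunique() > 1:
        logger.info("subject coverage varies across images "
                    "(%d..%d subjects); averaging over contributors",
                    n_subjects.min(), n_subjects.max())
    per_image = (per_si.groupby(["image", "roi"], sort=True,
                                observed=True)["cost"]
                 .mean().reset_index())
    return RoiCostTable(per_presentation=per_pres, per_subject_image=per_si,
                        per_image=per_image, repeat_policy=repeat_policy)


# ---------------------------------------------------------------------------
# ROI associations


def roi_associations(costs: RoiCostTable, ratings, level: str = "group",
                     ci_level: float = 0.95) -> pd.DataFrame:
    """Per-ROI Spearman correlation between ROI cost and ratings, with CI.

    ``ratings`` is a NormalizedRatings or a mapping/Series image -> value.
    Group level correlates the subject-averaged series; subject level emits
    one row per (subject, ROI).  Requires >= 4 images in common.
    """
    if hasattr(ratings, "table"):
        rate = ratings.table.set_index("image_id")["mean_z"]
    else:
        rate = pd.Series(ratings)
    rows = []
    if level == "group":
        groups = [((None, roi), sub) for roi, sub in
                  costs.per_image.groupby("roi", observed=True)]
    elif level == "subject":
        groups = [((subj, roi), sub) for (subj, roi), sub in
                  costs.per_subject_image.groupby(["subject", "roi"],
                                                  observed=True)]
    else:
        raise ValueError(f"level must be 'group' or 'subject', got {level!r}")
    for (subj, roi), sub in groups:
        common = sub[sub["image"].isin(rate.index)]
        n = len(common)
        if n < 4:
            raise ValueError(f"ROI {roi}: only {n} images in common with "
                             "ratings (need >= 4)")
        x = common["cost"].to_numpy()
        y = rate.loc[common["image"]].to_numpy()
        row = {"roi": roi, "n_images": n}
        if subj is not None:
            row["subject"] = subj
        if np.ptp(x) == 0:
            row.update(rho=np.nan, p=np.nan, ci_low=np.nan, ci_high=np.nan,
                       undefined=True)
        else:
            r = spearman_assoc(x, y, ci_level=ci_level)
            row.update(rho=r.rho, p=r.p, ci_low=r.ci_low, ci_high=r.ci_high,
                       undefined=False)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gini sparseness


def gini_index(v, signed_policy: str | None = None) -> float:
    """Gini inequality index of a non-negative vector, in [0, 1).

    G = (2 * sum_i i * x_(i)) / (n * sum x) - (n + 1) / n with x sorted
    ascending and 1-based ranks: 0 for a uniform vector, (n-1)/n for a
    one-hot vector.  Signed inputs (betas can be negative) require a policy:
    ``'abs'`` (magnitudes) or ``'positive-part'`` (clamp negatives to 0).
    """
    x = np.asarray(v, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("gini_index expects a non-empty 1-D vector")
    if np.any(x < 0):
        if signed_policy == "abs":
            x = np.abs(x)
        elif signed_policy == "positive-part":
            x = np.maximum(x, 0)
        else:
            raise ValueError("negative values require signed_policy "
                             "'abs' or 'positive-part'")
    total = x.sum()
    if total == 0:
        raise ValueError("sparseness undefined for an all-zero vector")
    xs = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float(2.0 * np.sum(ranks * xs) / (n * total) - (n + 1) / n)


def sparseness_profile(betas: pd.DataFrame,
                       signed_policy: str = "abs") -> pd.DataFrame:
    """Mean Gini index per ROI across images.

    Voxel values are repeat- and subject-averaged per image before the Gini
    is taken over the ROI's voxel vector; per-image indices are then averaged
    across images.
    """
    _check_beta_table(betas)
    voxel_means = (betas.groupby(["roi", "image", "voxel"], sort=True,
                                 observed=True)["beta"]
                   .mean().reset_index())
    rows = []
    for roi, sub in voxel_means.groupby("roi", observed=True):
        ginis = [gini_index(img_sub["beta"].to_numpy(),
                            signed_policy=signed_policy)
                 for _, img_sub in sub.groupby("image", observed=True)]
        rows.append({"roi": roi, "mean_gini": float(np.mean(ginis)),
                     "n_images": len(ginis)})
    return pd.DataFrame(rows)


def sparseness_association(profile: pd.DataFrame,
                           assoc: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson correlation across ROIs between mean Gini and the ROI-level
    cost-rating correlation.  Returns (r, df, p) with df = n_rois - 2."""
    merged = profile.merge(assoc[["roi", "rho"]], on="roi")
    merged = merged.dropna(subset=["mean_gini", "rho"])
    n = len(merged)
    if n < 3:
        raise ValueError(f"need >= 3 ROIs, got {n}")
    r, p = stats.pearsonr(merged["mean_gini"], merged["rho"])
    return float(r), n - 2, float(p)


# ---------------------------------------------------------------------------
# voxelwise maps


def voxelwise_map(betas: pd.DataFrame, ratings,
                  alpha: float = 1e-4) -> pd.DataFrame:
    """Per-voxel Spearman correlation with ratings, thresholded uncorrected.

    Betas are repeat-averaged (and subject-averaged when several subjects
    are present) per voxel and image.  Each voxel row carries rho, p, and a
    pass flag (p < alpha, sign retained via rho); constant voxel series are
    flagged undefined and never pass.  Negative-only / positive-only views
    are the rows with ``flag`` and the corresponding rho sign.
    """
    _check_beta_table(betas, need_roi=False)
    if hasattr(ratings, "table"):
        rate = ratings.table.set_index("image_id")["mean_z"]
    else:
        rate = pd.Series(ratings)
    series = (betas.groupby(["voxel", "image"], sort=True,
                            observed=True)["beta"]
              .mean().reset_index())
    rows = []
    for voxel, sub in series.groupby("voxel", observed=True):
        common = sub[sub["image"].isin(rate.index)]
        if len(common) < 4:
            raise ValueError(f"voxel {voxel}: series length {len(common)} < 4")
        x = common["beta"].to_numpy()
        y = rate.loc[common["image"]].to_numpy()
        if np.ptp(x) == 0:
            rows.append({"voxel": voxel, "rho": np.nan, "p": np.nan,
                         "flag": False, "undefined": True})
        else:
            rho, p = stats.spearmanr(x, y)
            rows.append({"voxel": voxel, "rho": float(rho), "p": float(p),
                         "flag": bool(p < alpha), "undefined": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI adapters


def nifti_to_beta_table(beta_imgs: dict, label_img, legend: dict,
                        subject: str = "sub1") -> pd.DataFrame:
    """Build a long beta table from NIfTI volumes.

    ``beta_imgs`` maps image id -> a 4-D NIfTI (presentations along the last
    axis) or a list of 3-D NIfTI volumes, one per presentation; ``label_img``
    is an integer ROI label volume on the same grid; ``legend`` maps ROI name
    -> label integer.  Voxels labelled 0 or absent from the legend are left
    unassigned and ignored.  No resampling is performed: grids must match.
    """
    import nibabel as nib  # noqa: F401  (documented dependency of this adapter)

    labels = np.asanyarray(label_img.dataobj).astype(int)
    inverse = {v: k for k, v in legend.items()}
    coords = np.argwhere(np.isin(labels, list(inverse)))
    if coords.size == 0:
        raise ValueError("no voxels carry a legend label")
    voxel_ids = [f"{x}_{y}_{z}" for x, y, z in coords]
    rois = [inverse[labels[tuple(c)]] for c in coords]
    rows = []
    for image_id, vols in beta_imgs.items():
        if hasattr(vols, "dataobj"):
            data = np.asanyarray(vols.dataobj)
            vols_list = ([data] if data.ndim == 3 else
                         [data[..., t] for t in range(data.shape[-1])])
        else:
            vols_list = [np.asanyarray(v.dataobj) for v in vols]
        for pres, vol in enumerate(vols_list, start=1):
            if vol.shape != labels.shape:
                raise ValueError(f"beta volume for image {image_id} has shape "
                                 f"{vol.shape}, label volume {labels.shape}")
            rows.append(pd.DataFrame({
                "subject": subject, "image": image_id, "presentation": pres,
                "roi": rois, "voxel": voxel_ids,
                "beta": vol[tuple(coords.T)].astype(float),
            }))
    return pd.concat(rows, ignore_index=True)


def map_to_nifti(voxel_map: pd.DataFrame, label_img, column: str = "rho",
                 sign: str | None = None):
    """Render a voxelwise map back onto the label volume's grid.

    ``sign='negative'``/'positive' keeps only flagged voxels of that sign
    (the uncorrected-threshold views); other voxels are 0.
    """
    import nibabel as nib

    shape = label_img.shape
    out = np.zeros(shape, dtype=np.float32)
    sel = voxel_map[~voxel_map["undefined"]]
    if sign == "negative":
        sel = sel[sel["flag"] & (sel["rho"] < 0)]
    elif sign == "positive":
        sel = sel[sel["flag"] & (sel["rho"] > 0)]
    elif sign is not None:
        raise ValueError("sign must be None, 'negative', or 'positive'")
    for _, row in sel.iterrows():
        x, y, z = map(int, str(row["voxel"]).split("_"))
        out[x, y, z] = row[column]
    return nib.Nifti1Image(out, label_img.affine, dtype=np.float32)
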
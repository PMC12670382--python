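"""Synthetic stimuli, ratings, and voxel betas with known planted structure.

Every generator is a pure function of its spec: the same spec yields
bit-identical output.  The planted quantities (spectral slope, cost-rating
link, ROI-level correlations) are chosen so that running the downstream
analysis on the generated data recovers them, which is what the acceptance
surface of this package rests on.

Images emulate naturalistic statistics via a 1/f^alpha amplitude spectrum
with random phases; rating tables emulate a crowd-rating design (each image
rated by an equal number of raters on a 1..K scale); beta tables emulate
single-trial percent-signal-change estimates grouped into named ROIs with
repeated presentations across subjects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

DEFAULT_ROIS = ("V1", "V2", "V3", "V4", "PPA", "FFA", "LOC", "OPA")


# ---------------------------------------------------------------------------
# 1/f images


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Spec for 1/f^alpha noise images.

    ``spectral_slope`` is the alpha of the amplitude spectrum 1/f^alpha
    (natural images: alpha ~ 1); ``contrast`` is the RMS contrast of the
    [0, 1] pixel values before clipping.
    """

    n_images: int = 16
    side_px: int = 375
    spectral_slope: float = 1.0
    contrast: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.side_px < 8:
            raise ValueError("side_px must be >= 8")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticImageSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


def _one_over_f_field(side: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Real-valued field whose amplitude spectrum falls off as 1/f^alpha."""
    fx = np.fft.fftfreq(side)[:, None]
    fy = np.fft.fftfreq(side)[None, :]
    f = np.hypot(fx, fy)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-alpha)
    white = rng.standard_normal((side, side))
    field = np.fft.ifft2(np.fft.fft2(white) * amp).real
    return field


def gen_images(spec: SyntheticImageSpec) -> list[np.ndarray]:
    """Generate RGB 1/f^alpha images as uint8 arrays (side, side, 3).

    The luminance field is replicated across the three channels; pixel
    values are centred at 0.5, scaled to the requested RMS contrast, clipped
    to [0, 1], and quantized to 8 bits.
    """
    rng = np.random.default_rng(spec.seed)
    images = []
    for _ in range(spec.n_images):
        field = _one_over_f_field(spec.side_px, spec.spectral_slope, rng)
        field = (field - field.mean()) / field.std()
        pix = np.clip(0.5 + spec.contrast * field, 0.0, 1.0)
        arr = (pix * 255).round().astype(np.uint8)
        images.append(np.repeat(arr[:, :, None], 3, axis=2))
    return images


def save_images(images: list[np.ndarray], out_dir, prefix: str = "img") -> list[str]:
    """Write images as PNG; returns the file names (the image ids)."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    names = []
    for i, arr in enumerate(images):
        name = f"{prefix}{i:04d}.png"
        Image.fromarray(arr).save(os.path.join(out_dir, name))
        names.append(name)
    return names


def fit_spectral_slope(image: np.ndarray) -> float:
    """Least-squares slope of the radially averaged log amplitude spectrum.

    For a 1/f^alpha image the fitted slope is ~ -alpha.  Fit range is radial
    frequency 2 .. side/4 (integer rings), avoiding the DC bin and the
    corner-dominated highest frequencies.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    arr = arr - arr.mean()
    side = arr.shape[0]
    amp = np.abs(np.fft.fft2(arr))
    fx = np.fft.fftfreq(side)[:, None] * side
    fy = np.fft.fftfreq(side)[None, :] * side
    r = np.hypot(fx, fy).round().astype(int)
    rmax = side // 4
    radial = np.array([amp[r == k].mean() for k in range(2, rmax + 1)])
    freqs = np.arange(2, rmax + 1, dtype=float)
    slope, _ = np.polyfit(np.log(freqs), np.log(radial), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# raw rating tables


def gen_raw_ratings(image_ids, n_participants: int, images_per_participant: int,
                    scale_max: int = 5, seed: int = 0,
                    image_appeal=None) -> pd.DataFrame:
    """Crowd-rating table with a balanced image-to-rater assignment.

    Each participant rates ``images_per_participant`` distinct images; images
    are assigned greedily to the least-covered first, so per-image rater
    counts differ by at most one.  Ratings are integers 1..scale_max: uniform
    draws by default, or a discretized noisy readout of ``image_appeal``
    (a per-image latent vector) shifted by a per-participant leniency bias.
    """
    image_ids = list(image_ids)
    n_images = len(image_ids)
    if scale_max < 2:
        raise ValueError("scale_max must be >= 2")
    if images_per_participant > n_images:
        raise ValueError("images_per_participant exceeds number of images")
    if image_appeal is not None:
        image_appeal = np.asarray(image_appeal, dtype=float)
        if image_appeal.size != n_images:
            raise ValueError("image_appeal length must match image_ids")

    rng = np.random.default_rng(seed)
    counts = np.zeros(n_images, dtype=int)
    rows_part, rows_img = [], []
    for p in range(n_participants):
        # least-covered first, random tie-break
        order = np.lexsort((rng.random(n_images), counts))
        chosen = order[:images_per_participant]
        counts[chosen] += 1
        rows_part.append(np.full(images_per_participant, p))
        rows_img.append(chosen)
    part = np.concatenate(rows_part)
    img_idx = np.concatenate(rows_img)

    if image_appeal is None:
        rating = rng.integers(1, scale_max + 1, size=part.size)
    else:
        bias = rng.normal(0.0, 0.5, size=n_participants)
        latent = image_appeal[img_idx] + bias[part] + rng.normal(0, 1, part.size)
        mid = (scale_max + 1) / 2.0
        rating = np.clip(np.round(mid + latent * scale_max / 4.0),
                         1, scale_max).astype(int)
    return pd.DataFrame({
        "participant_id": [f"p{p:04d}" for p in part],
        "image_id": [image_ids[i] for i in img_idx],
        "rating": rating,
    })


# ---------------------------------------------------------------------------
# planted cost-rating link


@dataclass(frozen=True)
class PlantedLinkSpec:
    """Linear link from a per-image cost vector to ratings.

    ``rating = slope * standardize(cost) + N(0, noise_sd^2)``.  If
    ``target_rho`` is given, the slope is fixed to sign(target_rho) and
    ``noise_sd`` is solved by bisection on pilot draws so the realized
    Spearman correlation matches the target.
    """

    slope: float = -1.0
    noise_sd: float = 1.0
    target_rho: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target_rho is not None and not -1 <= self.target_rho <= 1:
            raise ValueError("target_rho must be in [-1, 1]")


def _solve_noise_sd(z: np.ndarray, target: float, rng: np.random.Generator,
                    pilot_n: int = 200, reps: int = 40, iters: int = 30) -> float:
    """Bisection on the noise SD so Spearman(z, z + eps) ~ target magnitude."""
    target = abs(target)

    def realized(sigma: float) -> float:
        vals = np.empty(reps)
        for r in range(reps):
            zz = rng.choice(z, size=min(pilot_n, z.size), replace=False)
            vals[r] = stats.spearmanr(zz, zz + rng.normal(0, sigma, zz.size))[0]
        return float(vals.mean())

    lo, hi = 0.0, 1.0
    while realized(hi) > target:
        hi *= 2.0
        if hi > 1e4:
            break
    for _ in range(iters):
        mid = (lo + hi) / 2.0
        if realized(mid) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gen_ratings_from_cost(cost, link: PlantedLinkSpec) -> np.ndarray:
    """Per-image rating vector linearly linked to a cost vector.

    With ``target_rho`` set, the generator calibrates the noise level so the
    realized Spearman correlation between cost and rating approximates the
    target; the ground truth is then available for recovery tests.
    """
    cost = np.asarray(cost, dtype=float)
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost vector must be finite")
    rng = np.random.default_rng(link.seed)
    constant = np.ptp(cost) == 0
    if constant:
        if link.target_rho not in (None, 0.0) or \
                (link.target_rho is None and link.slope != 0):
            raise ValueError("cannot plant a nonzero correlation on a "
                             "constant cost vector")
        return rng.normal(0, max(link.noise_sd, 1.0), cost.size)
    z = (cost - cost.mean()) / cost.std()
    if link.target_rho is None:
        return link.slope * z + rng.normal(0, link.noise_sd, cost.size)
    if link.target_rho == 0:
        return rng.normal(0, max(link.noise_sd, 1.0), cost.size)
    sign = np.sign(link.target_rho)
    pilot_rng = np.random.default_rng((link.seed + 1) * 7919)
    sigma = _solve_noise_sd(z, link.target_rho, pilot_rng)
    return sign * z + rng.normal(0, sigma, cost.size)


# ---------------------------------------------------------------------------
# voxel beta tables


@dataclass(frozen=True)
class SyntheticBetaSpec:
    """Spec for single-trial voxel beta tables with planted ROI correlations.

    Betas are in percent-signal-change units.  ``planted_roi_rho`` maps ROI
    names to the image-level Spearman correlation that the fully aggregated
    series (voxel-summed, repeat-averaged, subject-averaged) should have
    with the rating vector; unlisted ROIs carry no rating signal.
    """

    n_images: int = 100
    n_subjects: int = 4
    rois: tuple = DEFAULT_ROIS
    voxels_per_roi: int = 16
    repeats: int = 2
    planted_roi_rho: dict = field(default_factory=dict)
    beta_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name, count in (("n_images", self.n_images),
                            ("n_subjects", self.n_subjects),
                            ("voxels_per_roi", self.voxels_per_roi),
                            ("repeats", self.repeats)):
            if count < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.beta_noise_sd < 0:
            raise ValueError("beta_noise_sd must be >= 0")
        for roi, rho in self.planted_roi_rho.items():
            if roi not in self.rois:
                raise ValueError(f"planted ROI {roi!r} absent from rois")
            if not -1 <= rho <= 1:
                raise ValueError(f"planted rho for {roi} outside [-1, 1]")


def _solve_signal_amplitude(zr: np.ndarray, ratings: np.ndarray, target: float,
                            sigma_eff: float, rng: np.random.Generator,
                            reps: int = 30, iters: int = 30) -> float:
    """Bisection on the signal amplitude a so that
    Spearman(a*zr + N(0, sigma_eff^2), ratings) ~ target magnitude."""
    target = abs(target)

    def realized(a: float) -> float:
        vals = np.empty(reps)
        for r in range(reps):
            vals[r] = stats.spearmanr(
                a * zr + rng.normal(0, sigma_eff, zr.size), ratings)[0]
        return abs(float(vals.mean()))

    lo, hi = 0.0, sigma_eff
    while realized(hi) < target:
        hi *= 2.0
        if hi > 1e6 * max(sigma_eff, 1.0):
            break
    for _ in range(iters):
        mid = (lo + hi) / 2.0
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gen_voxel_betas(spec: SyntheticBetaSpec, ratings) -> pd.DataFrame:
    """Long table (subject, image, presentation, roi, voxel, beta).

    Per ROI, a per-image signal (a monotone transform of the rating ranks,
    amplitude calibrated by bisection against the aggregate noise level) is
    spread across voxels by fixed non-negative loadings; voxel-level noise is
    i.i.d. N(0, beta_noise_sd^2) and per-voxel baselines are constant across
    images (so they cancel in image-level correlations).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size != spec.n_images:
        raise ValueError(f"ratings length {ratings.size} != n_images "
                         f"{spec.n_images}")
    rng = np.random.default_rng(spec.seed)
    n_i, n_s, n_r, n_v = (spec.n_images, spec.n_subjects, spec.repeats,
                          spec.voxels_per_roi)
    # rank-standardized ratings: the monotone carrier of the planted signal
    zr = stats.rankdata(ratings)
    zr = (zr - zr.mean()) / zr.std()
    sigma_eff = spec.beta_noise_sd * np.sqrt(n_v / (n_r * n_s))

    frames = []
    for roi in spec.rois:
        target = spec.planted_roi_rho.get(roi, 0.0)
        if target == 0:
            signal = np.zeros(n_i)
        elif sigma_eff == 0:
            if abs(target) != 1:
                raise ValueError(
                    f"{roi}: noiseless betas can only plant rho of 0 or +/-1")
            signal = np.sign(target) * zr
        else:
            amp_rng = np.random.default_rng(
                rng.integers(0, 2**31))
            a = _solve_signal_amplitude(np.sign(target) * zr, ratings,
                                        target, sigma_eff, amp_rng)
            signal = a * np.sign(target) * zr
        loadings = rng.gamma(2.0, 1.0, size=n_v)
        loadings /= loadings.sum()
        baseline = rng.normal(0.0, 0.5, size=n_v)
        # beta[s, i, r, v]
        beta = (loadings[None, None, None, :] * signal[None, :, None, None]
                + baseline[None, None, None, :]
                + rng.normal(0, spec.beta_noise_sd, (n_s, n_i, n_r, n_v)))
        frames.append(pd.DataFrame({
            "subject": np.repeat([f"sub{s + 1}" for s in range(n_s)],
                                 n_i * n_r * n_v),
            "image": np.tile(np.repeat(np.arange(n_i), n_r * n_v), n_s),
            "presentation": np.tile(np.repeat(np.arange(1, n_r + 1), n_v),
                                    n_s * n_i),
            "roi": roi,
            "voxel": np.tile([f"{roi}_v{v:03d}" for v in range(n_v)],
                             n_s * n_i * n_r),
            "beta": beta.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# toy classifier


def toy_texture_dataset(n: int, n_classes: int, side: int,
                        rng: np.random.Generator):
    """Class-conditioned textures: oriented gratings (orientation encodes
    the class) embedded in 1/f noise.  Returns (X, y) with X of shape
    (n, 3, side, side) float32 in [0, 1]."""
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    X = np.empty((n, 3, side, side), dtype=np.float32)
    y = rng.integers(0, n_classes, size=n)
    for i in range(n):
        theta = y[i] * np.pi / n_classes + rng.normal(0, 0.05)
        freq = rng.uniform(3.0, 6.0)
        phase = rng.uniform(0, 2 * np.pi)
        grating = np.sin(2 * np.pi * freq *
                         (xx * np.cos(theta) + yy * np.sin(theta)) / side
                         + phase)
        noise = _one_over_f_field(side, 1.0, rng)
        noise = (noise - noise.mean()) / noise.std()
        img = np.clip(0.5 + 0.3 * grating + 0.12 * noise, 0, 1)
        X[i] = img.astype(np.float32)[None, :, :]
    return X, y


def train_toy_classifier(arch=None, n_classes: int = 4, n_train: int = 400,
                         epochs: int = 12, seed: int = 0, side: int = 24,
                         n_test: int = 100, lr: float = 0.05,
                         momentum: float = 0.9, batch_size: int = 32):
    """Train a small conv net on a texture-orientation task.

    Returns ``(network, report)`` where the network is usable by the cost
    pipeline exactly like an untrained one, and the report records train and
    held-out accuracy.  Non-convergence (held-out accuracy at or below
    chance) is reported as a warning, not a failure.
    """
    from .nn import softmax_cross_entropy, toy_cnn

    rng = np.random.default_rng(seed)
    net = arch() if arch is not None else toy_cnn(n_classes=n_classes)
    net.initialize(seed)
    X, y = toy_texture_dataset(n_train + n_test, n_classes, side, rng)
    Xtr, ytr = X[:n_train], y[:n_train]
    Xte, yte = X[n_train:], y[n_train:]
    for _ in range(epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, batch_size):
            idx = order[start:start + batch_size]
            logits = net.forward(Xtr[idx])
            _, grad = softmax_cross_entropy(logits, ytr[idx])
            net.backward(grad)
            net.sgd_step(lr, momentum)
    train_acc = float((net.forward(Xtr).argmax(axis=1) == ytr).mean())
    test_acc = float((net.forward(Xte).argmax(axis=1) == yte).mean())
    chance = 1.0 / n_classes
    converged = test_acc > chance
    if not converged:
        warnings.warn(f"toy classifier did not exceed chance "
                      f"({test_acc:.3f} <= {chance:.3f})", stacklevel=2)
    report = {"train_acc": train_acc, "test_acc": test_acc, "chance": chance,
              "epochs": epochs, "n_train": n_train, "n_test": n_test,
              "converged": converged, "seed": seed}
    return net, report
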
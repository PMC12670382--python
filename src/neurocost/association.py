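"""Rank correlations, ensemble nonparametric p-values, and cross-validated
layer-wise regression of ratings on cost proxies.

All rank statistics use average ranks for ties.  The k-fold machinery pins
the exact partition: indices are permuted once under the configured seed and
sliced into k near-equal contiguous folds (the standard shuffled k-fold),
so results are bit-reproducible across runs and languages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# rank correlation


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None


def spearman_assoc(x, y, ci_level: float | None = None) -> SpearmanResult:
    """Spearman rank correlation with two-sided p and optional CI.

    The confidence interval uses the Fisher z-transform with the
    rank-correlation variance 1.06/(n-3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    ci_low = ci_high = None
    if ci_level is not None:
        if n < 4:
            raise ValueError("CI requires n >= 4")
        z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
        se = np.sqrt(1.06 / (n - 3))
        crit = stats.norm.ppf(0.5 + ci_level / 2)
        ci_low = float(np.tanh(z - crit * se))
        ci_high = float(np.tanh(z + crit * se))
    return SpearmanResult(rho=float(rho), p=float(p), n=n,
                          ci_low=ci_low, ci_high=ci_high)


# ---------------------------------------------------------------------------
# ensemble nonparametric p


def nonparametric_p(observed: float, nulls, tail: str = "lower",
                    add_one: bool = False) -> float:
    """One-tailed ensemble p: the fraction of null statistics strictly beyond
    the observed value (18 of 1,000 below ⇒ p = 0.018).

    ``add_one=True`` switches to the (count+1)/(N+1) small-sample variant.
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    if tail == "lower":
        count = int(np.sum(nulls < observed))
    elif tail == "upper":
        count = int(np.sum(nulls > observed))
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    if add_one:
        return (count + 1) / (nulls.size + 1)
    return count / nulls.size


@dataclass
class NullEnsembleSummary:
    """Observed statistic against a per-seed null distribution."""

    observed_stat: float
    null_stats: np.ndarray
    tail: str = "lower"
    add_one: bool = False
    p: float = field(init=False)

    def __post_init__(self):
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        self.p = nonparametric_p(self.observed_stat, self.null_stats,
                                 tail=self.tail, add_one=self.add_one)


# ---------------------------------------------------------------------------
# cross-validated regression


@dataclass(frozen=True)
class CVConfig:
    """Shuffled k-fold configuration (defaults: k=10, seeded shuffle)."""

    k: int = 10
    shuffle: bool = True
    seed: int = 0

    def splitter(self, n: int) -> KFold:
        if not 2 <= self.k <= n:
            raise ValueError(f"fold count k={self.k} outside [2, n={n}]")
        return KFold(n_splits=self.k, shuffle=self.shuffle,
                     random_state=self.seed if self.shuffle else None)


@dataclass
class CVPredictionResult:
    image_ids: list
    predictions: np.ndarray        # pooled out-of-fold predictions
    fold_coefficients: np.ndarray  # k x (p+1), intercept first
    accuracy_rho: float
    accuracy_p: float
    full_r2: float                 # all-data in-sample fit (canonical)
    cv_train_r2: float             # full-model training R^2 averaged over folds
    cumulative_r2: np.ndarray      # per-depth fold-averaged training R^2
    config: CVConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"image_id": self.image_ids,
                             "prediction": self.predictions})


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS with intercept; least-norm solution (with a warning) when the
    design is rank-deficient."""
    A = _design(X)
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(f"rank-deficient design (rank {rank} < {A.shape[1]}); "
                      "using least-norm solution", stacklevel=3)
    return coef


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def _costs_to_arrays(costs, outcome):
    """Accept a LayerCostMatrix-like object, DataFrame, or ndarray, plus a
    NormalizedRatings-like outcome or plain vector; return aligned arrays."""
    if hasattr(costs, "values") and hasattr(costs, "image_ids"):
        X = np.asarray(costs.values, dtype=float)
        ids = list(costs.image_ids)
        names = [str(b) for b in costs.blocks] if hasattr(costs, "blocks") else None
    elif isinstance(costs, pd.DataFrame):
        X = costs.to_numpy(dtype=float)
        ids = list(costs.index)
        names = [str(c) for c in costs.columns]
    else:
        X = np.asarray(costs, dtype=float)
        ids = list(range(len(X)))
        names = None
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    if hasattr(outcome, "vector_for"):
        y = outcome.vector_for(ids)
    else:
        y = np.asarray(outcome, dtype=float)
    if len(y) != len(X):
        raise ValueError(f"{len(X)} cost rows vs {len(y)} outcome values")
    return X, y, ids, names


def cv_predict(costs, outcome, config: CVConfig = CVConfig()) -> CVPredictionResult:
    """Out-of-fold linear prediction of the outcome from layer-wise costs.

    Every image is predicted exactly once, by the OLS model fit on the folds
    that exclude it; accuracy is the Spearman correlation between pooled
    predictions and the outcome.  ``full_r2`` is the in-sample R^2 of the
    all-data fit; the cumulative curve adds predictors in depth order and
    averages training R^2 over the k training fits.
    """
    X, y, ids, _ = _costs_to_arrays(costs, outcome)
    n, p = X.shape
    kf = config.splitter(n)
    predictions = np.empty(n)
    fold_coefs = np.empty((config.k, p + 1))
    cum = np.zeros((config.k, p))
    full_train_r2 = np.empty(config.k)
    for f, (train, test) in enumerate(kf.split(X)):
        coef = _ols(X[train], y[train])
        fold_coefs[f] = coef
        predictions[test] = _design(X[test]) @ coef
        yhat_train = _design(X[train]) @ coef
        full_train_r2[f] = _r2(y[train], yhat_train)
        for d in range(p):
            cd = _ols(X[train][:, :d + 1], y[train])
            cum[f, d] = _r2(y[train], _design(X[train][:, :d + 1]) @ cd)
    acc = spearman_assoc(predictions, y)
    full_coef = _ols(X, y)
    full_r2 = _r2(y, _design(X) @ full_coef)
    return CVPredictionResult(
        image_ids=ids, predictions=predictions, fold_coefficients=fold_coefs,
        accuracy_rho=acc.rho, accuracy_p=acc.p, full_r2=full_r2,
        cv_train_r2=float(full_train_r2.mean()),
        cumulative_r2=cum.mean(axis=0), config=config)


def cumulative_variance_curve(costs, outcome,
                              config: CVConfig = CVConfig()) -> np.ndarray:
    """Explained variance as layers are added in depth order.

    At depth d, the training R^2 of the regression on blocks 1..d, averaged
    over the k training fits.  The curve is non-decreasing and its final
    value equals the fold-averaged full-model training R^2.
    """
    return cv_predict(costs, outcome, config).cumulative_r2


# ---------------------------------------------------------------------------
# per-layer tests


def per_layer_associations(costs, outcome, adjust: str = "fdr_bh") -> pd.DataFrame:
    """Column-wise Spearman tests of each block's cost against the outcome.

    Returns one row per block with rho, raw p, and Benjamini-Hochberg
    adjusted p (within the network).  Constant-cost blocks are flagged
    ``undefined`` and excluded from the adjustment rather than raised.
    """
    X, y, _, names = _costs_to_arrays(costs, outcome)
    rows = []
    for j, name in enumerate(names):
        col = X[:, j]
        if np.ptp(col) == 0:
            rows.append({"block": name, "rho": np.nan, "p": np.nan,
                         "undefined": True})
        else:
            r = spearman_assoc(col, y)
            rows.append({"block": name, "rho": r.rho, "p": r.p,
                         "undefined": False})
    df = pd.DataFrame(rows)
    ok = ~df["undefined"]
    df["p_adj"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj"] = multipletests(df.loc[ok, "p"], method=adjust)[1]
    return df
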
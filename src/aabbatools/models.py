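"""Regression harnesses: MLP, gradient boosting with feature relevance, and a
Gaussian process with a multiplied Linear x RBF kernel.

All three harnesses report the test mean absolute error (MAE) and coefficient
of determination (r^2) aggregated over repeated random splits (MLP, GP) or
k-fold cross-validation (GBM). The GBM additionally returns per-feature
relevance fractions from the Friedman-MSE impurity criterion, normalized to
sum to one; these drive the accumulated-relevance pruning in
:mod:`aabbatools.reduce`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, DotProduct, WhiteKernel
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

__all__ = [
    "GPKernelParams",
    "ModelReport",
    "RelevanceTable",
    "SplitPlan",
    "gp_kernel",
    "gp_gram",
    "metrics",
    "train_gbm",
    "train_gp",
    "train_mlp",
]


# ---------------------------------------------------------------------------
# Plans and reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """Repeated random train/validation/test splits.

    ``fractions`` must sum to 1 (default 80:10:10). Each repeat draws its own
    permutation from a seed derived from ``seed`` and the repeat index, so
    repeats are independent yet reproducible.
    """

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        if min(self.fractions) < 0 or self.fractions[0] <= 0 or self.fractions[2] <= 0:
            raise ValueError("train and test fractions must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def repeat_seed(self, repeat: int) -> int:
        return int(np.random.SeedSequence([self.seed, repeat]).generate_state(1)[0] % (2**31))

    def split(self, n: int, repeat: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Index arrays (train, validation, test) for one repeat."""
        rng = np.random.default_rng(self.repeat_seed(repeat))
        perm = rng.permutation(n)
        n_train = int(round(self.fractions[0] * n))
        n_val = int(round(self.fractions[1] * n))
        n_train = max(1, min(n_train, n - 2))
        n_val = min(n_val, n - n_train - 1)
        return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


@dataclass
class ModelReport:
    """MAE / r^2 statistics over repeats (or folds), plus the best repeat."""

    mae_mean: float
    mae_sd: float
    r2_mean: float
    r2_sd: float
    mae_lowest: float
    r2_at_lowest: float
    per_repeat: pd.DataFrame = field(repr=False, default=None)  # columns: mae, r2

    @classmethod
    def from_runs(cls, maes: list[float], r2s: list[float]) -> "ModelReport":
        maes_a, r2s_a = np.asarray(maes, float), np.asarray(r2s, float)
        best = int(np.argmin(maes_a))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # nan r2 on degenerate targets
            r2_mean = float(np.nanmean(r2s_a)) if np.any(np.isfinite(r2s_a)) else float("nan")
            r2_sd = float(np.nanstd(r2s_a, ddof=min(1, len(r2s_a) - 1))) if len(r2s_a) > 1 else 0.0
        return cls(
            mae_mean=float(maes_a.mean()),
            mae_sd=float(maes_a.std(ddof=1)) if len(maes_a) > 1 else 0.0,
            r2_mean=r2_mean,
            r2_sd=r2_sd,
            mae_lowest=float(maes_a[best]),
            r2_at_lowest=float(r2s_a[best]),
            per_repeat=pd.DataFrame({"mae": maes_a, "r2": r2s_a}),
        )

    def to_dict(self) -> dict:
        return {
            "mae_mean": self.mae_mean,
            "mae_sd": self.mae_sd,
            "r2_mean": self.r2_mean,
            "r2_sd": self.r2_sd,
            "mae_lowest": self.mae_lowest,
            "r2_at_lowest": self.r2_at_lowest,
        }


@dataclass
class RelevanceTable:
    """Per-feature relevance fractions (sum to 1) with a descending-relevance
    rank; ties broken by original column order."""

    labels: list[str]
    relevance: np.ndarray

    def __post_init__(self) -> None:
        self.relevance = np.asarray(self.relevance, float)
        if len(self.labels) != len(self.relevance):
            raise ValueError("labels and relevance must have equal length")
        total = self.relevance.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"relevance fractions must sum to 1, got {total}")

    @property
    def rank(self) -> np.ndarray:
        # stable sort on negated relevance -> ties keep original column order
        return np.argsort(-self.relevance, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        order = self.rank
        return pd.DataFrame(
            {
                "label": [self.labels[i] for i in order],
                "relevance": self.relevance[order],
                "column": order,
            }
        )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(MAE, r^2). r^2 is the coefficient of determination
    ``1 - SS_res / SS_tot``; a zero-variance ``y_true`` yields NaN with a
    warning rather than an error."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 2:
        raise ValueError("metrics needs two equal-length 1-D arrays with >= 2 entries")
    mae = float(np.mean(np.abs(y_true - y_pred)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("y_true has zero variance; r^2 is undefined", RuntimeWarning)
        return mae, float("nan")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return mae, 1.0 - ss_res / ss_tot


def _check_xy(X: np.ndarray | pd.DataFrame, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per target value")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features/targets contain non-finite values")
    return X, y


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------


def train_mlp(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    plan: SplitPlan,
    *,
    hidden_layers: tuple[int, ...] = (128, 128),
    max_epochs: int = 2000,
    patience: int = 50,
) -> ModelReport:
    """Multilayer perceptron harness.

    Architecture: two hidden layers of 128 ReLU units, Adam on the MSE loss.
    Per repeat the rows are split per ``plan``; features are standardized with
    statistics from the train rows only, and training stops early when the
    validation MSE stalls for ``patience`` epochs. Validation monitoring uses
    a shuffled holdout of the pooled train+validation rows sized to the plan's
    validation share.
    """
    X, y = _check_xy(X, y)
    if len(y) < 20:
        raise ValueError("train_mlp needs at least 20 rows")
    maes, r2s = [], []
    for rep in range(plan.n_repeats):
        tr, va, te = plan.split(len(y), rep)
        scaler = StandardScaler().fit(X[tr])
        fit_idx = np.concatenate([tr, va])
        val_fraction = max(len(va), 1) / len(fit_idx)
        batch = int(np.clip(len(tr) // 10, 1, 64))
        # early stopping scores R^2 on the holdout, which is undefined for a
        # zero-variance target; fall back to plain loss-based stopping there
        use_early_stopping = len(va) > 0 and float(np.std(y[fit_idx])) > 0.0
        model = MLPRegressor(
            hidden_layer_sizes=hidden_layers,
            activation="relu",
            solver="adam",
            batch_size=batch,
            max_iter=max_epochs,
            early_stopping=use_early_stopping,
            validation_fraction=val_fraction,
            n_iter_no_change=patience,
            random_state=plan.repeat_seed(rep) % (2**31),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter
            model.fit(scaler.transform(X[fit_idx]), y[fit_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mae, r2 = metrics(y[te], model.predict(scaler.transform(X[te])))
        maes.append(mae)
        r2s.append(r2)
    return ModelReport.from_runs(maes, r2s)


# ---------------------------------------------------------------------------
# GBM
# ---------------------------------------------------------------------------


def train_gbm(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    *,
    n_estimators: int = 1000,
    max_depth: int = 5,
    learning_rate: float = 0.05,
    cv_folds: int = 5,
    seed: int = 0,
    labels: list[str] | None = None,
) -> tuple[ModelReport, RelevanceTable]:
    """Gradient-boosting ensemble of regression trees with k-fold CV.

    1000 trees of depth 5, learning rate 0.05, MSE loss, evaluated by 5-fold
    cross-validation by default. Feature relevance is the Friedman-MSE
    impurity importance of each feature, averaged over the folds and
    normalized to sum to one. Features are not standardized (trees are
    invariant to monotone rescaling).
    """
    if labels is None and isinstance(X, pd.DataFrame):
        labels = list(X.columns)
    X, y = _check_xy(X, y)
    if labels is None:
        labels = [f"x{i}" for i in range(X.shape[1])]
    if len(y) < 20:
        raise ValueError("train_gbm needs at least 20 rows")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
    maes, r2s = [], []
    importances = np.zeros(X.shape[1])
    for fold, (tr, te) in enumerate(kf.split(X)):
        # sklearn's gradient-boosting trees split on the Friedman-MSE
        # improvement criterion; feature_importances_ are the corresponding
        # impurity reductions.
        model = GradientBoostingRegressor(
            n_estimators=n_estimators,
            max_depth=max_depth,
            learning_rate=learning_rate,
            random_state=(seed + fold) % (2**31),
        )
        model.fit(X[tr], y[tr])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mae, r2 = metrics(y[te], model.predict(X[te]))
        maes.append(mae)
        r2s.append(r2)
        importances += model.feature_importances_
    total = importances.sum()
    if total <= 0:  # e.g. constant target: no split ever reduced impurity
        relevance = np.full(X.shape[1], 1.0 / X.shape[1])
    else:
        relevance = importances / total
    return ModelReport.from_runs(maes, r2s), RelevanceTable(labels, relevance)


# ---------------------------------------------------------------------------
# Gaussian process
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPKernelParams:
    """Hyperparameters of the multiplied Linear x RBF covariance."""

    variance_linear: float = 1.0
    variance_rbf: float = 1.0
    length_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.variance_linear, self.variance_rbf, self.length_scale) <= 0:
            raise ValueError("GP kernel parameters must be strictly positive")


def gp_kernel(x: np.ndarray, x2: np.ndarray, params: GPKernelParams) -> float:
    """Covariance between two points:

    ``k(x, x') = [sigma2_lin * <x, x'>] * [sigma2_rbf * exp(-||x - x'||^2 / (2 lambda^2))]``

    the product of a homogeneous linear kernel and an RBF kernel. Note the two
    variances act only through their product.
    """
    x = np.asarray(x, float)
    x2 = np.asarray(x2, float)
    if x.shape != x2.shape or x.ndim != 1:
        raise ValueError(f"gp_kernel: dimension mismatch {x.shape} vs {x2.shape}")
    lin = params.variance_linear * float(x @ x2)
    sq = float(np.sum((x - x2) ** 2))
    rbf = params.variance_rbf * np.exp(-sq / (2.0 * params.length_scale**2))
    return lin * rbf


def gp_gram(X: np.ndarray, params: GPKernelParams, *, jitter: float = 0.0) -> np.ndarray:
    """Gram matrix of :func:`gp_kernel` over the rows of ``X`` (vectorized),
    with optional diagonal jitter."""
    X = np.asarray(X, float)
    lin = params.variance_linear * (X @ X.T)
    sq = np.sum(X**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    rbf = params.variance_rbf * np.exp(-d2 / (2.0 * params.length_scale**2))
    K = lin * rbf
    if jitter:
        K = K + jitter * np.eye(len(K))
    return K


def train_gp(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    plan: SplitPlan,
    *,
    n_restarts: int = 3,
    standardize: bool = True,
    max_rows: int = 5000,
) -> ModelReport:
    """Gaussian-process harness with the Linear x RBF product kernel.

    Per repeat: split per ``plan``, standardize on the train rows, fit the
    kernel amplitude, RBF length-scale and observation noise by maximizing the
    log marginal likelihood (multi-restart L-BFGS) on the pooled
    train+validation rows, and report test MAE / r^2. Dense exact inference:
    refuses more than ``max_rows`` rows.
    """
    X, y = _check_xy(X, y)
    if len(y) < 20:
        raise ValueError("train_gp needs at least 20 rows")
    if len(y) > max_rows:
        raise ValueError(f"dense GP limited to {max_rows} rows, got {len(y)}")
    maes, r2s = [], []
    for rep in range(plan.n_repeats):
        tr, va, te = plan.split(len(y), rep)
        fit_idx = np.concatenate([tr, va])
        scaler = StandardScaler().fit(X[tr]) if standardize else None
        Xf = scaler.transform(X[fit_idx]) if scaler is not None else X[fit_idx]
        Xt = scaler.transform(X[te]) if scaler is not None else X[te]
        # center and scale the target so the kernel amplitude and noise level
        # live near 1 regardless of the target's units
        y_mean = y[fit_idx].mean()
        y_scale = y[fit_idx].std() or 1.0
        kernel = (
            ConstantKernel(1.0, (1e-6, 1e6))
            * DotProduct(sigma_0=0.0, sigma_0_bounds="fixed")
            * RBF(length_scale=np.sqrt(Xf.shape[1]) or 1.0, length_scale_bounds=(1e-2, 1e5))
            + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-10, 1e2))
        )
        gpr = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-10,  # base jitter; WhiteKernel carries the fitted noise
            normalize_y=False,
            n_restarts_optimizer=max(n_restarts - 1, 0),
            random_state=plan.repeat_seed(rep) % (2**31),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gpr.fit(Xf, (y[fit_idx] - y_mean) / y_scale)
            pred = gpr.predict(Xt) * y_scale + y_mean
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mae, r2 = metrics(y[te], pred)
        maes.append(mae)
        r2s.append(r2)
    return ModelReport.from_runs(maes, r2s)
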
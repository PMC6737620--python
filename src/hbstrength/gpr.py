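"""Gaussian-process regression of site strengths with an applicability domain.

The covariance is K = C * M + W: a constant kernel C (optimized on a log
scale between 1e-3 and 1e3) times a stationary kernel M — by default the
Matérn family evaluated on the scaled distance gamma * d(x_i, x_j) / l, with
fixed smoothness nu in {0.5, 1.5, 2.5} and length scale l optimized between
1e-2 and 1e2 — plus a white kernel W with a fixed noise level of 0.05 on the
standardized-target scale.

Predictions return the posterior mean (back-transformed to kJ/mol) together
with a "variance estimate", defined as 1.96 times the posterior standard
deviation, i.e. the half-width of the 95% confidence interval.  A query
whose variance estimate exceeds the role-specific threshold (4.2 kJ/mol for
acceptors, 3.2 for donors — the plateau values reached by fully trained
models) is outside the applicability domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    Matern,
    RationalQuadratic,
    WhiteKernel,
)
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

AD_THRESHOLDS = {"HBA": 4.2, "HBD": 3.2}  # kJ/mol, variance-estimate scale


@dataclass(frozen=True)
class KernelConfig:
    kernel_form: str = "Matern"  # Matern | RBF | RationalQuadratic
    nu: float = 1.5
    C: float = 1.0
    C_bounds: tuple[float, float] = (1e-3, 1e3)
    length_scale: float = 1.0
    length_scale_bounds: tuple[float, float] = (1e-2, 1e2)
    white_noise: float = 0.05  # fixed, standardized-target scale
    gamma: float = 1.0  # fixed distance scale inside the Matérn form

    def __post_init__(self) -> None:
        if self.kernel_form not in ("Matern", "RBF", "RationalQuadratic"):
            raise ValueError(f"unknown kernel form {self.kernel_form!r}")
        if self.kernel_form == "Matern" and self.nu not in (0.5, 1.5, 2.5):
            raise ValueError("nu must be one of 0.5, 1.5, 2.5")
        for lo, hi in (self.C_bounds, self.length_scale_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must be positive and ordered")
        if self.white_noise < 0 or self.gamma < 0:
            raise ValueError("white_noise and gamma must be non-negative")


def kernel_eval(
    x_i: np.ndarray, x_j: np.ndarray, cfg: KernelConfig, same_point: bool = False
) -> float:
    """Closed-form evaluation of C * M(x_i, x_j) + [white_noise iff i == j].

    The Matérn factor is evaluated on t = gamma * ||x_i - x_j|| / l:
    nu=0.5 gives exp(-t); nu=1.5 gives (1 + sqrt(3) t) exp(-sqrt(3) t);
    nu=2.5 gives (1 + sqrt(5) t + 5 t^2 / 3) exp(-sqrt(5) t).
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError(f"dimension mismatch: {x_i.shape} vs {x_j.shape}")
    t = cfg.gamma * float(np.linalg.norm(x_i - x_j)) / cfg.length_scale
    if cfg.kernel_form == "RBF":
        m = math.exp(-0.5 * t * t)
    elif cfg.kernel_form == "RationalQuadratic":
        m = (1 + t * t / 2) ** -1.0
    elif cfg.nu == 0.5:
        m = math.exp(-t)
    elif cfg.nu == 1.5:
        s = math.sqrt(3) * t
        m = (1 + s) * math.exp(-s)
    else:
        s = math.sqrt(5) * t
        m = (1 + s + s * s / 3) * math.exp(-s)
    value = cfg.C * m
    if same_point:
        value += cfg.white_noise
    return value


def kernel_matrix(X: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    """Full training covariance matrix (white noise on the diagonal)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    K = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = kernel_eval(X[i], X[j], cfg, same_point=(i == j))
    return K


def build_sklearn_kernel(cfg: KernelConfig):
    """The scikit-learn kernel object corresponding to a KernelConfig.

    gamma rescales the distance and is therefore absorbed into the length
    scale (l_eff = l / gamma) for the optimizer.
    """
    scale = cfg.length_scale / cfg.gamma if cfg.gamma else cfg.length_scale
    bounds = tuple(b / cfg.gamma if cfg.gamma else b for b in cfg.length_scale_bounds)
    if cfg.kernel_form == "Matern":
        stationary = Matern(length_scale=scale, length_scale_bounds=bounds, nu=cfg.nu)
    elif cfg.kernel_form == "RBF":
        stationary = RBF(length_scale=scale, length_scale_bounds=bounds)
    else:
        stationary = RationalQuadratic(length_scale=scale, length_scale_bounds=bounds)
    return (
        ConstantKernel(cfg.C, cfg.C_bounds) * stationary
        + WhiteKernel(cfg.white_noise, noise_level_bounds="fixed")
    )


@dataclass
class GPRModel:
    """A fitted GP with the target standardization needed for back-transform."""

    regressor: GaussianProcessRegressor
    config: KernelConfig
    y_mean: float
    y_scale: float
    role: str = "HBA"
    X_train: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def optimized_params(self) -> dict:
        return {
            k: (float(v) if np.isscalar(v) else v)
            for k, v in self.regressor.kernel_.get_params().items()
            if k.endswith(("constant_value", "length_scale", "noise_level"))
        }


@dataclass
class EvalMetrics:
    rmse: float
    r2: float
    spearman: float
    mean_variance_estimate: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


def fit_gpr(
    X: np.ndarray,
    y: np.ndarray,
    cfg: KernelConfig | None = None,
    seed: int = 0,
    role: str = "HBA",
    n_restarts: int = 5,
) -> GPRModel:
    """Fit a GP on standardized targets, optimizing C and l by restarted
    maximization of the log marginal likelihood within the configured bounds."""
    cfg = cfg or KernelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per target")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in X or y")
    y_mean = float(y.mean())
    y_scale = float(y.std())
    if y_scale == 0:
        y_scale = 1.0
    z = (y - y_mean) / y_scale
    gp = GaussianProcessRegressor(
        kernel=build_sklearn_kernel(cfg),
        n_restarts_optimizer=n_restarts,
        random_state=seed,
        normalize_y=False,
    )
    try:
        gp.fit(X, z)
    except np.linalg.LinAlgError as exc:
        K = kernel_matrix(X, cfg)
        raise np.linalg.LinAlgError(
            f"singular kernel despite white noise (condition number "
            f"{np.linalg.cond(K):.3e})"
        ) from exc
    return GPRModel(regressor=gp, config=cfg, y_mean=y_mean, y_scale=y_scale,
                    role=role, X_train=X)


def predict_gpr(model: GPRModel, X_query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(posterior means kJ/mol, variance estimates = 1.96 * posterior sd)."""
    X_query = np.asarray(X_query, dtype=float)
    if X_query.ndim != 2 or X_query.shape[1] != model.X_train.shape[1]:
        raise ValueError("query dimensionality does not match training data")
    z_mean, z_sd = model.regressor.predict(X_query, return_std=True)
    mean = z_mean * model.y_scale + model.y_mean
    var_estimate = 1.96 * z_sd * model.y_scale
    return mean, var_estimate


def posterior_sd(model: GPRModel, X_query: np.ndarray) -> np.ndarray:
    """Raw posterior standard deviation in kJ/mol (variance estimate / 1.96)."""
    _, var_estimate = predict_gpr(model, X_query)
    return var_estimate / 1.96


def _metrics(y_true: np.ndarray, y_pred: np.ndarray, var_est: np.ndarray) -> EvalMetrics:
    return EvalMetrics(
        rmse=float(np.sqrt(np.mean((y_true - y_pred) ** 2))),
        r2=float(r2_score(y_true, y_pred)),
        spearman=float(stats.spearmanr(y_true, y_pred).statistic),
        mean_variance_estimate=float(np.mean(var_est)),
    )


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    cfg: KernelConfig | None = None,
    k: int = 10,
    seed: int = 0,
    role: str = "HBA",
    n_restarts: int = 2,
) -> tuple[list[EvalMetrics], EvalMetrics]:
    """k-fold cross validation with a deterministic shuffled split.

    Returns per-fold metrics and pooled metrics over the concatenated
    held-out predictions (each point held out exactly once).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < k:
        raise ValueError(f"need at least k={k} samples, got {len(X)}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    pooled_pred = np.empty_like(y)
    pooled_var = np.empty_like(y)
    for train_idx, test_idx in splitter.split(X):
        model = fit_gpr(X[train_idx], y[train_idx], cfg, seed=seed, role=role,
                        n_restarts=n_restarts)
        pred, var_est = predict_gpr(model, X[test_idx])
        pooled_pred[test_idx] = pred
        pooled_var[test_idx] = var_est
        per_fold.append(_metrics(y[test_idx], pred, var_est))
    return per_fold, _metrics(y, pooled_pred, pooled_var)


def learning_curve(
    X: np.ndarray,
    y: np.ndarray,
    cfg: KernelConfig | None = None,
    fractions: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11)),
    seed: int = 0,
    role: str = "HBA",
    n_restarts: int = 2,
):
    """Training-fraction learning curve with nested subsets.

    Each fraction's training set contains the previous one (a fixed shuffled
    order under ``seed``); the fitted model is evaluated on the full data
    set, so fraction 1.0 reports training-set performance and smaller
    fractions mix seen and unseen points.  Returns a pandas DataFrame with
    rmse, r2, spearman and the mean variance estimate per fraction.
    """
    import pandas as pd

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.random.default_rng(seed).permutation(len(X))
    rows = []
    for fraction in fractions:
        n_train = max(1, int(round(fraction * len(X))))
        if n_train < 5:
            raise ValueError(f"fraction {fraction} yields only {n_train} points")
        subset = order[:n_train]
        model = fit_gpr(X[subset], y[subset], cfg, seed=seed, role=role,
                        n_restarts=n_restarts)
        pred, var_est = predict_gpr(model, X)
        m = _metrics(y, pred, var_est)
        rows.append({
            "fraction": fraction,
            "n_train": n_train,
            "rmse": m.rmse,
            "r2": m.r2,
            "spearman": m.spearman,
            "mean_variance_estimate": m.mean_variance_estimate,
        })
    return pd.DataFrame(rows)


def ad_check(
    variance_estimate: float, role: str, threshold: float | None = None
) -> str:
    """Applicability-domain gate: ``outside`` iff the variance estimate
    strictly exceeds the role threshold (HBA 4.2, HBD 3.2 kJ/mol)."""
    if variance_estimate < 0:
        raise ValueError("variance estimate must be non-negative")
    if threshold is None:
        try:
            threshold = AD_THRESHOLDS[role]
        except KeyError:
            raise ValueError(f"role must be HBA or HBD, got {role!r}") from None
    return "outside" if variance_estimate > threshold else "inside"
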
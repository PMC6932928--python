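"""Diagnostic multiclass classifier: grouped-penalty multinomial lasso with stability selection.

The selection model is a multinomial logistic regression penalized by a
group lasso that ties together the class coefficients of each CpG:

    minimize  -(1/n) * sum_i log p_{i, y_i}  +  lambda * sum_j ||B_j.||_2

where ``B_j.`` is the row of class coefficients of feature j and the
intercepts are unpenalized. A CpG therefore enters or leaves the model for
all classes at once. The problem is solved by accelerated proximal gradient
(FISTA) with group soft-thresholding; features are standardized internally
and coefficients are reported on the original beta scale.

Marker stability is assessed over repeated stratified 2:1 train/test
partitions: within each partition the penalty is tuned by stratified
10-fold cross-validation using the one-standard-error rule on accuracy
(largest lambda whose mean CV accuracy is within one SE of the maximum),
the model is refit at the chosen lambda, and the CpGs with any nonzero
class coefficient are recorded. CpGs selected in at least ``freq_threshold``
of the partitions form the final marker panel, on which an (essentially
unpenalized, ridge-stabilized) multinomial logistic model is fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .exceptions import StratificationError, ValidationError

DEFAULT_GRID_SIZE = 100
DEFAULT_LAMBDA_MIN_RATIO = 1e-3


# ---------------------------------------------------------------------------
# core solver


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    lookup = {c: k for k, c in enumerate(classes)}
    out = np.zeros((len(y), len(classes)))
    for i, v in enumerate(y):
        out[i, lookup[v]] = 1.0
    return out


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def penalized_objective(Xs, Y, coef, intercept, lam) -> float:
    """Value of the grouped-lasso multinomial objective (standardized scale)."""
    n = Xs.shape[0]
    Z = Xs @ coef + intercept
    Z = Z - Z.max(axis=1, keepdims=True)
    log_p = Z - np.log(np.exp(Z).sum(axis=1, keepdims=True))
    nll = -np.sum(log_p * Y) / n
    return float(nll + lam * np.sqrt((coef**2).sum(axis=1)).sum())


def lambda_max(X: np.ndarray, y) -> float:
    """Smallest penalty at which every feature group is exactly zero.

    Computed from the gradient of the negative log-likelihood at the
    intercept-only (class frequency) solution, on standardized features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    Xs, _, _ = _standardize(X)
    Y = _one_hot(y, classes)
    p0 = Y.mean(axis=0)
    G = Xs.T @ (np.tile(p0, (len(y), 1)) - Y) / len(y)
    return float(np.sqrt((G**2).sum(axis=1)).max())


def lambda_grid(X, y, grid_size: int = DEFAULT_GRID_SIZE,
                min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO) -> np.ndarray:
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, min_ratio * lmax, grid_size)


@dataclass
class GroupedLassoFit:
    """Solution of one grouped multinomial lasso problem.

    ``coef``/``intercept`` are on the original feature scale; the
    standardized-scale solution and the scaler are kept for KKT checks and
    warm starts.
    """

    classes: np.ndarray
    coef: np.ndarray  # p x K, original scale
    intercept: np.ndarray  # K
    coef_std: np.ndarray  # p x K, standardized scale
    intercept_std: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    lam: float
    objective: float
    n_iter: int

    @property
    def active_features(self) -> np.ndarray:
        return np.where((self.coef_std != 0).any(axis=1))[0]


def _kkt_max_violation(Xs, Y, B, b0, lam) -> float:
    n = Xs.shape[0]
    P = _softmax(Xs @ B + b0)
    G = Xs.T @ (P - Y) / n
    norms = np.sqrt((B**2).sum(axis=1))
    zero = norms == 0
    v = float(np.abs((P - Y).sum(axis=0) / n).max())
    if zero.any():
        v = max(v, float(np.maximum(np.sqrt((G[zero] ** 2).sum(axis=1)) - lam, 0.0).max()))
    if (~zero).any():
        resid = G[~zero] + lam * B[~zero] / norms[~zero, None]
        v = max(v, float(np.sqrt((resid**2).sum(axis=1)).max()))
    return v


def fit_grouped_multinomial_lasso(
    X,
    y,
    lam: float,
    *,
    max_iter: int = 20000,
    tol: float = 1e-10,
    kkt_tol: float | None = None,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> GroupedLassoFit:
    """Solve the grouped-penalty multinomial lasso at one penalty value.

    FISTA with a fixed step from the Lipschitz bound 0.5 * smax(X~)^2 / n
    (X~ including the intercept column), monotone restarts, and group
    soft-thresholding as the proximal map. Iterates until the relative
    objective change falls below ``tol``; when ``kkt_tol`` is given the
    stationarity conditions are additionally polished below that level.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("need at least two classes")
    n, p = X.shape
    K = len(classes)

    Xs, mean, scale = _standardize(X)
    Y = _one_hot(y, classes)
    Xa = np.hstack([Xs, np.ones((n, 1))])
    smax = np.linalg.norm(Xa, 2)
    L = 0.5 * smax**2 / n
    step = 1.0 / L

    if warm_start is not None:
        B = warm_start[0].copy()
        b0 = warm_start[1].copy()
    else:
        B = np.zeros((p, K))
        b0 = np.log(np.maximum(Y.mean(axis=0), 1e-12))
        b0 = b0 - b0.mean()

    def objective(Bc, b0c):
        return penalized_objective(Xs, Y, Bc, b0c, lam)

    obj = objective(B, b0)
    VB, vb0 = B.copy(), b0.copy()
    t_mom = 1.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        P = _softmax(Xs @ VB + vb0)
        R = (P - Y) / n
        GB = Xs.T @ R
        g0 = R.sum(axis=0)

        B_new = VB - step * GB
        norms = np.sqrt((B_new**2).sum(axis=1))
        shrink = np.maximum(0.0, 1.0 - step * lam / np.where(norms > 0, norms, 1.0))
        B_new = B_new * shrink[:, None]
        b0_new = vb0 - step * g0

        obj_new = objective(B_new, b0_new)
        if obj_new > obj:  # monotone restart: plain proximal step from (B, b0)
            P = _softmax(Xs @ B + b0)
            R = (P - Y) / n
            B_new = B - step * (Xs.T @ R)
            norms = np.sqrt((B_new**2).sum(axis=1))
            shrink = np.maximum(0.0, 1.0 - step * lam / np.where(norms > 0, norms, 1.0))
            B_new = B_new * shrink[:, None]
            b0_new = b0 - step * R.sum(axis=0)
            obj_new = objective(B_new, b0_new)
            t_mom = 1.0

        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        VB = B_new + ((t_mom - 1.0) / t_new) * (B_new - B)
        vb0 = b0_new + ((t_mom - 1.0) / t_new) * (b0_new - b0)
        done = abs(obj - obj_new) <= tol * max(1.0, abs(obj))
        B, b0, obj, t_mom = B_new, b0_new, obj_new, t_new
        if done and kkt_tol is not None and n_iter % 10 == 0:
            done = _kkt_max_violation(Xs, Y, B, b0, lam) <= kkt_tol
        elif done and kkt_tol is not None:
            done = False
        if done:
            break

    # Softmax identifiability: center rows (likelihood- and prediction-
    # invariant, penalty-minimal) and intercepts.
    active = (B != 0).any(axis=1)
    B[active] = B[active] - B[active].mean(axis=1, keepdims=True)
    b0 = b0 - b0.mean()
    obj = objective(B, b0)

    coef = B / scale[:, None]
    intercept = b0 - (mean / scale) @ B
    return GroupedLassoFit(
        classes=classes,
        coef=coef,
        intercept=intercept,
        coef_std=B,
        intercept_std=b0,
        scaler_mean=mean,
        scaler_scale=scale,
        lam=lam,
        objective=obj,
        n_iter=n_iter,
    )


def kkt_residuals(X, y, fit: GroupedLassoFit) -> dict[str, float]:
    """Worst-case KKT violations of a grouped-lasso solution.

    For zero groups the gradient norm must not exceed lambda; for active
    groups the gradient must equal -lambda * B_j / ||B_j||. Returns the
    maximum violation of each condition (both should be ~0 at an optimum).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Xs = (X - fit.scaler_mean) / fit.scaler_scale
    Y = _one_hot(y, fit.classes)
    n = len(y)
    P = _softmax(Xs @ fit.coef_std + fit.intercept_std)
    G = Xs.T @ (P - Y) / n
    norms = np.sqrt((fit.coef_std**2).sum(axis=1))
    zero = norms == 0
    viol_zero = 0.0
    if zero.any():
        viol_zero = float(
            np.maximum(np.sqrt((G[zero] ** 2).sum(axis=1)) - fit.lam, 0.0).max()
        )
    viol_active = 0.0
    if (~zero).any():
        direction = fit.coef_std[~zero] / norms[~zero, None]
        resid = G[~zero] + fit.lam * direction
        viol_active = float(np.sqrt((resid**2).sum(axis=1)).max())
    viol_intercept = float(np.abs((P - Y).sum(axis=0) / n).max())
    return {
        "zero_groups": viol_zero,
        "active_groups": viol_active,
        "intercepts": viol_intercept,
    }


# ---------------------------------------------------------------------------
# cross-validation and stability selection


@dataclass(frozen=True)
class GroupedLassoConfig:
    """Tuning constants of the diagnostic selection stage."""

    n_folds: int = 10
    n_partitions: int = 10
    train_fraction: float = 2.0 / 3.0
    freq_threshold: int = 9
    grid_size: int = DEFAULT_GRID_SIZE
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO
    seed: int = 0

    def validate(self) -> None:
        if self.freq_threshold > self.n_partitions + 1:
            raise ValidationError("freq_threshold cannot exceed n_partitions + 1")
        if not (0 < self.train_fraction < 1):
            raise ValidationError("train_fraction must lie in (0, 1)")


@dataclass
class CVResult:
    """Accuracy table of a lambda path and the 1-SE choice."""

    lambda_selected: float
    table: pd.DataFrame  # columns: lam, mean_accuracy, se_accuracy


def _fit_path(X, y, grid, **kwargs) -> list[GroupedLassoFit]:
    fits = []
    warm = None
    for lam in grid:
        fit = fit_grouped_multinomial_lasso(X, y, lam, warm_start=warm, **kwargs)
        warm = (fit.coef_std, fit.intercept_std)
        fits.append(fit)
    return fits


def _predict_from_fit(fit: GroupedLassoFit, X: np.ndarray) -> np.ndarray:
    P = _softmax(X @ fit.coef + fit.intercept)
    return fit.classes[np.argmax(P, axis=1)]


def one_se_lambda(table: pd.DataFrame) -> float:
    """Largest lambda with mean accuracy >= max mean accuracy - SE at the max."""
    best = table["mean_accuracy"].idxmax()  # first (largest-lambda) maximizer
    threshold = table.loc[best, "mean_accuracy"] - table.loc[best, "se_accuracy"]
    ok = table.loc[table["mean_accuracy"] >= threshold, "lam"]
    return float(ok.max())


def cv_select_lambda(
    X,
    y,
    n_folds: int = 10,
    lambda_grid_values=None,
    seed: int = 0,
    *,
    grid_size: int = DEFAULT_GRID_SIZE,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = 1e-8,
) -> CVResult:
    """Choose the penalty by stratified K-fold CV accuracy with the 1-SE rule.

    The path is evaluated from ``lambda_max`` downward (computed on the full
    input unless an explicit grid is given); the returned value is the
    largest lambda whose mean CV accuracy is at least the maximum mean
    accuracy minus the standard error at the maximizing lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if lambda_grid_values is None:
        grid = lambda_grid(X, y, grid_size, lambda_min_ratio)
    else:
        grid = np.asarray(lambda_grid_values, dtype=float)
        if np.any(np.diff(grid) >= 0):
            raise ValidationError("lambda grid must be strictly decreasing")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = np.zeros((n_folds, len(grid)))
    n_classes = len(np.unique(y))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < n_classes or len(np.unique(y[va])) < n_classes:
            raise StratificationError(f"fold {f} lost a class")
        fits = _fit_path(X[tr], y[tr], grid, tol=tol)
        for j, fit in enumerate(fits):
            accs[f, j] = np.mean(_predict_from_fit(fit, X[va]) == y[va])

    mean = accs.mean(axis=0)
    se = accs.std(axis=0, ddof=1) / np.sqrt(n_folds)
    table = pd.DataFrame({"lam": grid, "mean_accuracy": mean, "se_accuracy": se})
    return CVResult(lambda_selected=one_se_lambda(table), table=table)


@dataclass
class StabilitySelection:
    """Per-feature selection frequencies over resampling replicates."""

    frequencies: pd.Series  # feature id -> count of replicates selecting it
    n_replicates: int
    threshold: int
    strict: bool = False  # False: selected iff freq >= threshold; True: freq > threshold

    @property
    def selected(self) -> list[str]:
        if self.strict:
            keep = self.frequencies > self.threshold
        else:
            keep = self.frequencies >= self.threshold
        return self.frequencies.index[keep].tolist()

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "frequency": self.frequencies,
                "selected": [g in sel for g in self.frequencies.index],
            }
        )


def stability_select(
    X: pd.DataFrame,
    y,
    config: GroupedLassoConfig = GroupedLassoConfig(),
    *,
    tol: float = 1e-8,
) -> StabilitySelection:
    """Selection frequencies over repeated stratified 2:1 partitions.

    For each partition the training two-thirds is cross-validated over the
    lambda path (1-SE rule on accuracy), refit at the chosen lambda, and the
    features with any nonzero class coefficient are counted. Features
    reaching ``freq_threshold`` of ``n_partitions`` form the selected set.
    """
    config.validate()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    if (counts * config.train_fraction < config.n_folds).any():
        small = counts.index[counts * config.train_fraction < config.n_folds].tolist()
        raise StratificationError(
            f"classes with fewer training samples than CV folds: {small}"
        )

    Xv = X.to_numpy(dtype=float)
    sss = StratifiedShuffleSplit(
        n_splits=config.n_partitions,
        train_size=config.train_fraction,
        random_state=config.seed,
    )
    freq = pd.Series(0, index=X.columns, dtype=int)
    child_seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_partitions
    ).astype(np.int64) & 0x7FFFFFFF
    for rep, (tr, _te) in enumerate(sss.split(Xv, y)):
        cv = cv_select_lambda(
            Xv[tr],
            y[tr],
            n_folds=config.n_folds,
            seed=int(child_seeds[rep]),
            grid_size=config.grid_size,
            lambda_min_ratio=config.lambda_min_ratio,
            tol=tol,
        )
        fit = fit_grouped_multinomial_lasso(Xv[tr], y[tr], cv.lambda_selected, tol=tol)
        freq.iloc[fit.active_features] += 1
    return StabilitySelection(
        frequencies=freq,
        n_replicates=config.n_partitions,
        threshold=config.freq_threshold,
    )


# ---------------------------------------------------------------------------
# final model


@dataclass
class DiagnosticModel:
    """Multinomial logistic model on the selected CpG panel.

    Fitted by (ridge-stabilized) maximum likelihood on standardized
    features; the tiny ridge term guarantees a finite optimum under
    quasi-separation. Serializes losslessly to JSON.
    """

    classes: list[str]
    cpgs: list[str]
    intercept: np.ndarray  # K
    coef: np.ndarray  # p x K, standardized scale
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    fitted_on: list[str] = field(default_factory=list)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [g for g in self.cpgs if g not in X.columns]
        if missing:
            raise ValidationError(f"model CpGs missing from input: {missing}")
        Xv = X[self.cpgs].to_numpy(dtype=float)
        return (Xv - self.scaler_mean) / self.scaler_scale

    def predict_proba(self, X: pd.DataFrame) -> pd.DataFrame:
        P = _softmax(self._design(X) @ self.coef + self.intercept)
        return pd.DataFrame(P, index=X.index, columns=self.classes)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        proba = self.predict_proba(X)
        return proba.idxmax(axis=1)

    def to_json(self, path=None) -> str:
        payload = {
            "classes": list(self.classes),
            "cpgs": list(self.cpgs),
            "intercept": self.intercept.tolist(),
            "coef": self.coef.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "fitted_on": list(self.fitted_on),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DiagnosticModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            classes=payload["classes"],
            cpgs=payload["cpgs"],
            intercept=np.asarray(payload["intercept"], dtype=float),
            coef=np.asarray(payload["coef"], dtype=float),
            scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(payload["scaler_scale"], dtype=float),
            fitted_on=payload.get("fitted_on", []),
        )


def fit_final_multinomial(
    X: pd.DataFrame, y, *, ridge: float = 1e-6, max_iter: int = 10000
) -> DiagnosticModel:
    """Fit the final multinomial logistic model on the selected CpGs."""
    if X.shape[1] == 0:
        raise ValidationError(
            "selected CpG set is empty; relax the stability-frequency threshold"
        )
    y = np.asarray(y)
    Xv = X.to_numpy(dtype=float)
    Xs, mean, scale = _standardize(Xv)
    n = len(y)
    clf = LogisticRegression(
        C=1.0 / (n * ridge), solver="lbfgs", max_iter=max_iter
    )
    clf.fit(Xs, y)
    classes = clf.classes_.tolist()
    coef = clf.coef_.T  # p x K in sklearn's symmetric multinomial parameterization
    intercept = clf.intercept_
    if coef.shape[1] == 1:  # binary case stored as a single column
        coef = np.hstack([-coef, coef])
        intercept = np.array([-intercept[0], intercept[0]])
    return DiagnosticModel(
        classes=classes,
        cpgs=X.columns.tolist(),
        intercept=np.asarray(intercept, dtype=float),
        coef=np.asarray(coef, dtype=float),
        scaler_mean=mean,
        scaler_scale=scale,
        fitted_on=list(map(str, X.index)),
    )


def predict_proba(model: DiagnosticModel, X: pd.DataFrame) -> pd.DataFrame:
    """Class probability matrix (rows sum to one)."""
    return model.predict_proba(X)
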
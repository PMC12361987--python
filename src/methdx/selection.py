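"""Stability selection of marker panels by repeated-subsample LASSO.

Candidate DMSs enter an L1-penalized logistic regression.  The penalty
lambda is chosen once on the full training set — by 10-fold
cross-validated binomial deviance under the "1-se" rule (largest lambda
whose mean CV deviance stays within one standard error of the minimum),
or by AIC/BIC on the full fit.  The training cohort is then subsampled
without replacement ``n_subsamples`` times (stratified by class,
fraction ``subsample_fraction``), the LASSO refit at that lambda on each
subsample, and a candidate counts as selected in a subsample when its
coefficient is nonzero.  The final panel keeps candidates whose
selection count exceeds ``freq_threshold`` (e.g. > 450 of 500).

Penalty convention: the objective is mean logistic loss plus
``lambda * ||w||_1`` (intercept unpenalized), so the liblinear ``C``
equals ``1 / (n * lambda)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import warnings

from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

_NONZERO_TOL = 1e-8
_FIT_TOL = 1e-9
#: liblinear penalizes its intercept column; a large intercept_scaling makes
#: that penalty negligible so the analytic lambda_max stays valid
_LIBLINEAR_KW = dict(solver="liblinear", tol=_FIT_TOL, max_iter=2000,
                     intercept_scaling=100.0)


@dataclass(frozen=True)
class StabilityConfig:
    n_subsamples: int = 500
    subsample_fraction: float = 0.8
    freq_threshold: int = 450
    cv_folds: int = 10
    lambda_rule: str = "one_se"          # one_se | min | aic | bic
    lambda_grid_size: int = 100
    lambda_decades: float = 4.0
    lambda_per_subsample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.freq_threshold > self.n_subsamples:
            raise ValueError("freq_threshold cannot exceed n_subsamples")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.lambda_rule not in {"one_se", "min", "aic", "bic"}:
            raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")


@dataclass
class StabilityResult:
    counts: pd.Series                 # candidate -> selection count
    selected: list[str]
    lambda_: float
    imputation_means: pd.Series
    scale: pd.Series
    config: StabilityConfig = field(repr=False, default_factory=StabilityConfig)

    def selected_at(self, freq_threshold: int) -> list[str]:
        return list(self.counts.index[self.counts > freq_threshold])


def _l1_clf(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    """Fitted L1 logistic at penalty lam (mean-loss scale)."""
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (len(y) * lam), **_LIBLINEAR_KW)
    with warnings.catch_warnings():
        # near-convergence at tiny lambda is fine for support recovery
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def _lasso_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coefficients of L1 logistic at penalty lam (mean-loss scale)."""
    return _l1_clf(X, y, lam).coef_.ravel()


def lambda_grid(X: np.ndarray, y: np.ndarray, size: int = 100, decades: float = 4.0) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (all-zero fit) downward."""
    ybar = y.mean()
    lam_max = 1.02 * np.abs(X.T @ (y - ybar)).max() / len(y)  # 2% slack for solver tolerance
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), size)


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def choose_lambda(
    X: np.ndarray,
    y: np.ndarray,
    config: StabilityConfig | None = None,
    grid: np.ndarray | None = None,
) -> float:
    """Pick the LASSO penalty on a fully imputed, standardized matrix.

    ``one_se``/``min`` use stratified seeded K-fold CV of binomial
    deviance; ``aic``/``bic`` penalize the full-fit deviance with the
    count of nonzero coefficients (plus intercept).
    """
    config = config or StabilityConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    if grid is None:
        grid = lambda_grid(X, y, config.lambda_grid_size, config.lambda_decades)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if grid.size == 1:
        return float(grid[0])

    if config.lambda_rule in {"one_se", "min"}:
        n_folds = min(config.cv_folds, int(np.bincount(y.astype(int)).min()))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
        dev = np.zeros((grid.size, n_folds))
        for f, (tr, te) in enumerate(skf.split(X, y)):
            for j, lam in enumerate(grid):
                clf = _l1_clf(X[tr], y[tr], lam)
                dev[j, f] = _binomial_deviance(y[te], clf.predict_proba(X[te])[:, 1])
        mean_dev = dev.mean(axis=1)
        se = dev.std(axis=1, ddof=1) / np.sqrt(n_folds)
        j_min = int(np.argmin(mean_dev))
        if config.lambda_rule == "min":
            return float(grid[j_min])
        ok = mean_dev <= mean_dev[j_min] + se[j_min]
        return float(grid[np.nonzero(ok)[0][0]])  # grid descending: first ok = largest lambda

    # information criteria on the full fit
    n = len(y)
    best_lam, best_crit = float(grid[0]), np.inf
    for lam in grid:
        coef = _lasso_fit(X, y, lam)
        C = 1.0 / (n * lam)
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 tol=_FIT_TOL, max_iter=2000)
        clf.fit(X, y)
        p = clf.predict_proba(X)[:, 1]
        deviance = n * _binomial_deviance(y, p)
        df = int((np.abs(coef) > _NONZERO_TOL).sum()) + 1
        crit = deviance + (2.0 * df if config.lambda_rule == "aic" else np.log(n) * df)
        if crit < best_crit - 1e-12:
            best_crit, best_lam = crit, float(lam)
    return best_lam


def _prepare_design(matrix: pd.DataFrame, sample_order: list[str]) -> tuple[np.ndarray, pd.Series, pd.Series]:
    """Samples x candidates array with frozen mean imputation and scaling."""
    X = matrix[sample_order].T.to_numpy(dtype=float)
    means = pd.Series(np.nanmean(X, axis=0), index=matrix.index)
    inds = np.where(np.isnan(X))
    X[inds] = means.to_numpy()[inds[1]]
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scale = pd.Series(sd, index=matrix.index)
    X = (X - means.to_numpy()) / sd
    return X, means, scale


def stability_select(
    matrix: pd.DataFrame,
    labels: pd.Series,
    config: StabilityConfig | None = None,
    *,
    case: str = "malignant",
) -> StabilityResult:
    """Run stability selection over the candidate sites in ``matrix``.

    ``matrix`` is sites x samples restricted to candidate DMSs; missing
    values are imputed with candidate means computed once on the full
    training set and frozen across subsamples.
    """
    config = config or StabilityConfig()
    if matrix.shape[0] == 0:
        raise ValueError("no candidate sites")
    samples = [s for s in labels.index if s in matrix.columns]
    y = (labels.loc[samples] == case).to_numpy(dtype=float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need >= 2 samples in each class")

    X, means, scale = _prepare_design(matrix, samples)
    lam = choose_lambda(X, y, config)

    rng = np.random.default_rng(config.seed)
    case_idx = np.nonzero(y == 1)[0]
    ctrl_idx = np.nonzero(y == 0)[0]
    n_case_sub = max(2, int(round(config.subsample_fraction * len(case_idx))))
    n_ctrl_sub = max(2, int(round(config.subsample_fraction * len(ctrl_idx))))

    counts = np.zeros(matrix.shape[0], dtype=int)
    for _ in range(config.n_subsamples):
        idx = np.concatenate([
            rng.choice(case_idx, size=min(n_case_sub, len(case_idx)), replace=False),
            rng.choice(ctrl_idx, size=min(n_ctrl_sub, len(ctrl_idx)), replace=False),
        ])
        lam_b = choose_lambda(X[idx], y[idx], config) if config.lambda_per_subsample else lam
        coef = _lasso_fit(X[idx], y[idx], lam_b)
        counts += (np.abs(coef) > _NONZERO_TOL).astype(int)

    counts_s = pd.Series(counts, index=matrix.index, name="selection_count")
    selected = list(counts_s.index[counts_s > config.freq_threshold])
    return StabilityResult(counts=counts_s, selected=selected, lambda_=lam,
                           imputation_means=means, scale=scale, config=config)
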
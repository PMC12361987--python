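"""The logistic diagnostic model and its evaluation.

:class:`DiagnosticModel` is a model object in the statsmodels mould:
built from a methylation matrix, class labels, a selected marker panel
and optional clinical covariates (age standardized by training
statistics, gender and smoking as 0/1 indicators).  ``fit()`` performs
an unpenalized maximum-likelihood logistic fit (the "unbiased
coefficient estimates" refit of the stability-selected panel) and
returns a :class:`DiagnosticResults` carrying coefficients, standard
errors, diagnostics and a ``summary()`` table.  On detected separation
the fit falls back to a small L2 ridge (1e-4) and records a warning.

The probability score of a sample is the fitted class probability
``1 / (1 + exp(-(b0 + sum_j b_j x_j)))`` in [0, 1]; classification uses
a configurable threshold (default 0.5, score >= threshold => malignant).
Performance is summarized by sensitivity, specificity, PPV, NPV,
accuracy and the midrank (Mann-Whitney) AUC.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from methdx.simulate import BENIGN, MALIGNANT

DEFAULT_COVARIATES = ("age", "gender", "smoking")
_RIDGE_ALPHA = 1e-4
_SEPARATION_PARAM_BOUND = 1e3


def split_cohort(samples, ratio: float = 0.7, seed: int = 0) -> tuple[list[str], list[str]]:
    """Random train/validation split: train size = floor(n * ratio)."""
    samples = list(samples)
    if len(samples) == 0:
        raise ValueError("no samples to split")
    if not (0.0 < ratio <= 1.0):
        raise ValueError("ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(math.floor(len(samples) * ratio))
    train = [samples[i] for i in sorted(order[:n_train])]
    validation = [samples[i] for i in sorted(order[n_train:])]
    return train, validation


def _encode_covariates(metadata: pd.DataFrame, covariates, age_mean: float, age_sd: float) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = (metadata["age"].astype(float) - age_mean) / (age_sd if age_sd > 0 else 1.0)
        elif cov == "gender":
            bad = set(metadata["gender"]) - {"M", "F"}
            if bad:
                raise ValueError(f"unknown gender level(s) {bad}")
            cols["gender"] = (metadata["gender"] == "M").astype(float)
        elif cov == "smoking":
            bad = set(metadata["smoking"]) - {"ever", "never"}
            if bad:
                raise ValueError(f"unknown smoking level(s) {bad}")
            cols["smoking"] = (metadata["smoking"] == "ever").astype(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=metadata.index)


class DiagnosticModel:
    """Unpenalized logistic diagnostic model over a marker panel.

    Parameters
    ----------
    matrix
        Sites x samples beta matrix containing the marker rows.
    labels
        sample_id -> class ('malignant' / 'benign').
    markers
        Marker site ids (the stability-selected panel).
    metadata
        Per-sample clinical table (needed when covariates are used).
    covariates
        Clinical covariates to adjust for; subset of
        ('age', 'gender', 'smoking').
    """

    def __init__(self, matrix: pd.DataFrame, labels: pd.Series, markers,
                 metadata: pd.DataFrame | None = None,
                 covariates=DEFAULT_COVARIATES,
                 case: str = MALIGNANT, control: str = BENIGN):
        self.markers = list(markers)
        missing = [m for m in self.markers if m not in matrix.index]
        if missing:
            raise ValueError(f"markers absent from matrix: {missing}")
        # covariates require a metadata table; a marker-only model otherwise
        self.covariates = tuple(covariates) if metadata is not None else ()
        samples = [s for s in labels.index if s in matrix.columns]
        self.samples = samples
        self.labels = labels.loc[samples]
        self.case, self.control = case, control
        y = self.labels.map({case: 1.0, control: 0.0})
        if y.isna().any():
            raise ValueError("labels contain classes other than case/control")
        if y.sum() < 1 or (1 - y).sum() < 1:
            raise ValueError("both classes must be present")
        self.y = y.to_numpy()
        self.matrix = matrix
        self.metadata = metadata

        marker_block = matrix.loc[self.markers, samples].T
        self.imputation_means = marker_block.mean(axis=0)
        self.age_mean = float(metadata.loc[samples, "age"].mean()) if ("age" in self.covariates) else 0.0
        self.age_sd = float(metadata.loc[samples, "age"].std(ddof=0)) if ("age" in self.covariates) else 1.0
        self._X = self._design(matrix, metadata, samples)

    @classmethod
    def from_cohort(cls, matrix, metadata, markers, *, covariates=DEFAULT_COVARIATES,
                    label_column: str = "class", case: str = MALIGNANT, control: str = BENIGN):
        """Build from a beta matrix plus a metadata table holding labels."""
        return cls(matrix, metadata[label_column], markers, metadata=metadata,
                   covariates=covariates, case=case, control=control)

    def _design(self, matrix: pd.DataFrame, metadata: pd.DataFrame | None, samples) -> pd.DataFrame:
        X = matrix.loc[self.markers, samples].T.copy()
        X = X.fillna(self.imputation_means)
        if self.covariates:
            cov = _encode_covariates(metadata.loc[samples], self.covariates, self.age_mean, self.age_sd)
            X = pd.concat([X, cov], axis=1)
        X.insert(0, "intercept", 1.0)
        return X

    def fit(self, threshold: float = 0.5) -> "DiagnosticResults":
        """Maximum-likelihood fit; ridge (alpha=1e-4) fallback on separation."""
        X = self._X.to_numpy(dtype=float)
        ridge_used, warning = False, None
        try:
            import warnings as _warnings
            with np.errstate(all="ignore"), _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # separation is handled below
                res = sm.Logit(self.y, X).fit(disp=0, maxiter=200, warn_convergence=False)
            params, bse = res.params, res.bse
            converged = bool(res.mle_retvals.get("converged", False))
            if (not converged or not np.all(np.isfinite(bse))
                    or np.abs(params).max() > _SEPARATION_PARAM_BOUND):
                raise np.linalg.LinAlgError("separation suspected")
        except Exception:
            params, bse = _ridge_logistic(X, self.y, _RIDGE_ALPHA)
            ridge_used, converged = True, True
            warning = f"separation detected; refit with L2 ridge alpha={_RIDGE_ALPHA}"
        names = list(self._X.columns)
        return DiagnosticResults(
            model=self,
            params=pd.Series(np.asarray(params), index=names),
            bse=pd.Series(np.asarray(bse), index=names),
            converged=converged,
            ridge_used=ridge_used,
            warning=warning,
            threshold=float(threshold),
        )


def _ridge_logistic(X: np.ndarray, y: np.ndarray, alpha: float,
                    max_iter: int = 200, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Newton IRLS for logistic NLL + (alpha/2)||w||^2, intercept unpenalized."""
    n, p = X.shape
    pen = np.full(p, alpha)
    pen[0] = 0.0  # column 0 is the intercept
    w = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ w
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (mu - y) + pen * w
        W = mu * (1.0 - mu)
        H = (X * W[:, None]).T @ X + np.diag(pen)
        step = np.linalg.solve(H, grad)
        w = w - step
        if np.abs(step).max() < tol:
            break
    mu = 1.0 / (1.0 + np.exp(-(X @ w)))
    W = mu * (1.0 - mu)
    H = (X * W[:, None]).T @ X + np.diag(pen)
    bse = np.sqrt(np.diag(np.linalg.inv(H)))
    return w, bse


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class PerfMetrics:
    """Exact-precision performance metrics; NaN where undefined."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    auc: float | None = None

    def display(self) -> dict:
        """Report-style rounding: integer percent for sensitivity and
        specificity, three decimals for the proportions."""
        out = {
            "sensitivity_pct": int(round(100 * self.sensitivity)) if not math.isnan(self.sensitivity) else None,
            "specificity_pct": int(round(100 * self.specificity)) if not math.isnan(self.specificity) else None,
            "ppv": round(self.ppv, 3) if not math.isnan(self.ppv) else None,
            "npv": round(self.npv, 3) if not math.isnan(self.npv) else None,
            "accuracy": round(self.accuracy, 3) if not math.isnan(self.accuracy) else None,
        }
        if self.auc is not None:
            out["auc"] = round(self.auc, 3)
        return out


def classify(scores: pd.Series, labels: pd.Series, threshold: float = 0.5,
             *, case: str = MALIGNANT, control: str = BENIGN) -> ConfusionMatrix:
    """Tally predictions (score >= threshold => malignant) against labels."""
    missing = [s for s in scores.index if s not in labels.index]
    if missing:
        raise ValueError(f"missing labels for {missing}")
    pred_pos = scores >= threshold
    truth_pos = labels.loc[scores.index] == case
    return ConfusionMatrix(
        tp=int((pred_pos & truth_pos).sum()),
        fn=int((~pred_pos & truth_pos).sum()),
        fp=int((pred_pos & ~truth_pos).sum()),
        tn=int((~pred_pos & ~truth_pos).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def evaluate_confusion(cm: ConfusionMatrix) -> PerfMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy from a 2x2 table."""
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    return PerfMetrics(
        sensitivity=_safe_div(cm.tp, cm.tp + cm.fn),
        specificity=_safe_div(cm.tn, cm.tn + cm.fp),
        ppv=_safe_div(cm.tp, cm.tp + cm.fp),
        npv=_safe_div(cm.tn, cm.tn + cm.fn),
        accuracy=_safe_div(cm.tp + cm.tn, cm.total),
    )


def roc_auc(scores: pd.Series, labels: pd.Series, *, case: str = MALIGNANT) -> float:
    """Midrank AUC: P(case score > control score) + 0.5 P(tie)."""
    y = (labels.loc[scores.index] == case).to_numpy()
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores.to_numpy())
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_points(scores: pd.Series, labels: pd.Series, *, case: str = MALIGNANT) -> pd.DataFrame:
    """Empirical ROC curve as (fpr, tpr) rows over all score thresholds."""
    y = (labels.loc[scores.index] == case).to_numpy()
    order = np.argsort(-scores.to_numpy(), kind="mergesort")
    y = y[order]
    s = scores.to_numpy()[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep only the last point of each tied-score run
    last = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tps[last] / max(y.sum(), 1)]
    fpr = np.r_[0.0, fps[last] / max((~y).sum(), 1)]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


class DiagnosticResults:
    """Fit results: coefficients, uncertainties, scoring and evaluation."""

    def __init__(self, model: DiagnosticModel, params: pd.Series, bse: pd.Series,
                 converged: bool, ridge_used: bool, warning: str | None, threshold: float):
        self.model = model
        self.params = params
        self.bse = bse
        self.converged = converged
        self.ridge_used = ridge_used
        self.warning = warning
        self.threshold = threshold

    def predict(self, matrix: pd.DataFrame | None = None,
                metadata: pd.DataFrame | None = None,
                samples=None) -> pd.Series:
        """Probability scores in [0, 1] for new (or training) samples."""
        matrix = self.model.matrix if matrix is None else matrix
        metadata = self.model.metadata if metadata is None else metadata
        if samples is None:
            samples = [s for s in matrix.columns
                       if metadata is None or s in metadata.index]
        X = self.model._design(matrix, metadata, list(samples))
        eta = X.to_numpy(dtype=float) @ self.params.to_numpy()
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=list(samples), name="score")

    def evaluate(self, matrix=None, metadata=None, labels: pd.Series | None = None,
                 samples=None) -> dict:
        """Confusion matrix + metrics + AUC on a sample set."""
        labels = self.model.labels if labels is None else labels
        scores = self.predict(matrix, metadata, samples if samples is not None else list(labels.index))
        scores = scores.loc[[s for s in scores.index if s in labels.index]]
        cm = classify(scores, labels, self.threshold, case=self.model.case, control=self.model.control)
        metrics = evaluate_confusion(cm)
        auc = roc_auc(scores, labels, case=self.model.case)
        return {"confusion": cm, "metrics": metrics, "auc": auc, "scores": scores}

    def summary(self) -> str:
        lines = ["Diagnostic logistic model",
                 f"  samples: {len(self.model.samples)}  markers: {len(self.model.markers)}"
                 f"  covariates: {', '.join(self.model.covariates) or 'none'}",
                 f"  converged: {self.converged}  ridge fallback: {self.ridge_used}",
                 ""]
        if self.warning:
            lines.insert(1, f"  WARNING: {self.warning}")
        lines.append(f"  {'term':<24}{'coef':>12}{'std err':>12}")
        for name in self.params.index:
            lines.append(f"  {name:<24}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}")
        return "\n".join(lines)

    def to_json(self, path: str | os.PathLike | None = None) -> dict:
        payload = {
            "markers": self.model.markers,
            "covariates": list(self.model.covariates),
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "imputation_means": {k: float(v) for k, v in self.model.imputation_means.items()},
            "age_mean": self.model.age_mean,
            "age_sd": self.model.age_sd,
            "threshold": self.threshold,
            "converged": self.converged,
            "ridge_used": self.ridge_used,
            "warning": self.warning,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
        return payload
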
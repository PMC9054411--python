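"""Feature-selection cascade: correlation filter -> t-screen -> LASSO.

The three stages run in a fixed order and each stage only removes columns:

1. redundancy removal — a greedy pass in column order drops any column
   whose absolute Pearson correlation with an already-kept column reaches
   the threshold (default 0.9);
2. univariate screening — a Welch two-sample t-test per column between the
   two response groups, keeping columns with p < alpha (default 0.05), no
   multiple-testing correction;
3. sparse multivariate selection — L1-penalized logistic regression with
   the penalty chosen by cross-validated deviance under the one-standard-
   error rule; the selected features are those with nonzero coefficients.

Standardization for the LASSO is computed on training folds only, so the
cascade can be refit inside outer evaluation splits without leakage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression


@dataclasses.dataclass
class SelectionReport:
    """Full decision trail of one cascade run."""

    dropped_correlated: list[dict]  # {column, partner, abs_r}
    zero_variance: list[str]
    t_stats: dict[str, dict]  # column -> {t, p}
    survivors_after_t: list[str]
    lasso_lambda_grid: list[float]
    lasso_nonzero_per_lambda: list[int]
    lasso_lambda_chosen: float | None
    selected: dict[str, float]  # column -> coefficient

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def drop_correlated(
    X: pd.DataFrame, threshold: float = 0.9
) -> tuple[pd.DataFrame, list[dict], list[str]]:
    """Greedy redundancy removal by absolute Pearson correlation.

    Columns are visited in table order; a column is dropped when its |r|
    with any already-kept column is >= threshold (the earlier column is
    kept, deterministically). Zero-variance columns correlate with nothing
    (|r| treated as 0): kept, but flagged.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need at least 2 columns and 3 rows")
    vals = X.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    zero_var = [c for c, s in zip(X.columns, sd) if s == 0]
    kept_idx: list[int] = []
    dropped: list[dict] = []
    for j, col in enumerate(X.columns):
        if sd[j] == 0:
            kept_idx.append(j)
            continue
        partner = None
        for k in kept_idx:
            if sd[k] == 0:
                continue
            r = np.corrcoef(vals[:, j], vals[:, k])[0, 1]
            if abs(r) >= threshold:
                partner = (X.columns[k], abs(float(r)))
                break
        if partner is None:
            kept_idx.append(j)
        else:
            dropped.append({"column": col, "partner": partner[0], "abs_r": partner[1]})
    return X.iloc[:, kept_idx], dropped, zero_var


def t_screen(
    X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Welch two-sample t-test per column; keep columns with p < alpha."""
    y = np.asarray(y)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a = X.to_numpy(dtype=float)[y == groups[0]]
    b = X.to_numpy(dtype=float)[y == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 cases")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance-in-both-groups: keep nothing
    report = {c: {"t": float(ti), "p": float(pi)} for c, ti, pi in zip(X.columns, t, p)}
    keep = [c for c, pi in zip(X.columns, p) if pi < alpha]
    return X[keep], report


def _logistic_deviance(p: np.ndarray, y01: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y01 * np.log(p) + (1 - y01) * np.log(1 - p)))


def default_lambda_grid(X: np.ndarray, y01: np.ndarray, n_lambda: int = 40) -> np.ndarray:
    """Log-spaced grid from lambda_max (all coefficients zero) down 3 decades."""
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    lam_max = np.abs(Xs.T @ (y01 - y01.mean())).max() / len(y01)
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max * 1.05), np.log10(lam_max * 1e-3), n_lambda)


def _fit_l1(Xs: np.ndarray, y01: np.ndarray, lam: float) -> LogisticRegression:
    # liblinear minimizes C * sum(log-loss) + ||w||_1, so C = 1/(n*lambda)
    C = 1.0 / (len(y01) * lam)
    clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000,
                             tol=1e-6, random_state=0)
    clf.fit(Xs, y01)
    return clf


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict[str, float], dict]:
    """L1-penalized logistic selection with CV deviance and the 1-SE rule.

    Returns (selected column -> coefficient, diagnostics). Coefficients
    are on the standardized scale of the final full-data fit at the
    chosen penalty.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y01 = (y == classes.max()).astype(float)
    vals = X.to_numpy(dtype=float)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(vals, y01)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    folds = min(folds, int(np.bincount(y01.astype(int)).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(lambda_grid)))
    for f, (tr, va) in enumerate(skf.split(vals, y01)):
        mu, sd = vals[tr].mean(axis=0), vals[tr].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr, Xva = (vals[tr] - mu) / sd, (vals[va] - mu) / sd
        for i, lam in enumerate(lambda_grid):
            clf = _fit_l1(Xtr, y01[tr], lam)
            dev[f, i] = _logistic_deviance(clf.predict_proba(Xva)[:, 1], y01[va])
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(mean_dev))
    # 1-SE rule: sparsest (largest) lambda within one SE of the minimum
    within = np.nonzero(mean_dev <= mean_dev[i_min] + se_dev[i_min])[0]
    i_1se = int(within.min())  # grid is descending, so min index = largest lambda
    lam_chosen = float(lambda_grid[i_1se])

    mu, sd = vals.mean(axis=0), vals.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (vals - mu) / sd
    nonzero_per_lambda = []
    for lam in lambda_grid:
        nonzero_per_lambda.append(int(np.sum(np.abs(_fit_l1(Xs, y01, lam).coef_[0]) > 1e-10)))
    coef = _fit_l1(Xs, y01, lam_chosen).coef_[0]
    selected = {
        c: float(w) for c, w in zip(X.columns, coef) if abs(w) > 1e-10
    }
    diagnostics = {
        "lambda_grid": [float(v) for v in lambda_grid],
        "mean_deviance": mean_dev.tolist(),
        "se_deviance": se_dev.tolist(),
        "nonzero_per_lambda": nonzero_per_lambda,
        "lambda_min": float(lambda_grid[i_min]),
        "lambda_chosen": lam_chosen,
    }
    return selected, diagnostics


def run_cascade(
    X: pd.DataFrame,
    y: np.ndarray,
    corr_threshold: float = 0.9,
    alpha: float = 0.05,
    lambda_grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Run the full cascade and return the selected table plus its report."""
    X1, dropped, zero_var = drop_correlated(X, corr_threshold)
    X2, t_report = t_screen(X1, y, alpha)
    if X2.shape[1] == 0:
        report = SelectionReport(
            dropped_correlated=dropped, zero_variance=zero_var, t_stats=t_report,
            survivors_after_t=[], lasso_lambda_grid=[], lasso_nonzero_per_lambda=[],
            lasso_lambda_chosen=None, selected={},
        )
        return X2, report
    selected, diag = lasso_select(X2, y, lambda_grid=lambda_grid, folds=folds, seed=seed)
    report = SelectionReport(
        dropped_correlated=dropped,
        zero_variance=zero_var,
        t_stats=t_report,
        survivors_after_t=list(X2.columns),
        lasso_lambda_grid=diag["lambda_grid"],
        lasso_nonzero_per_lambda=diag["nonzero_per_lambda"],
        lasso_lambda_chosen=diag["lambda_chosen"],
        selected=selected,
    )
    cols = list(selected) if selected else list(X2.columns)
    return X2[cols], report
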
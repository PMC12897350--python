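"""Calibration statistics and leave-one-out cross-validation.

The panel of statistics reported for each calibration model mirrors the
standard chemometric summary: calibration residual SD, mean absolute error
and multiple correlation coefficient R, plus four leave-one-out (LOO)
quantities built from the PRESS statistic (sum of squared LOO prediction
residuals): residual variance % = 100 * PRESS / SS_tot, explained variance %
as its exact complement, a LOO residual SD, and the LOO mean (absolute)
prediction error.

Two LOO modes exist. ``scaling='refit'`` (default) re-fits the column
autoscaling inside every fold, so no information from the held-out sample
leaks into preprocessing; it is computed by explicit refits.
``scaling='fixed'`` keeps the full-data scaling and uses the exact
hat-matrix shortcut ``d_i = e_i / (1 - h_ii)``. Because ordinary least
squares with an intercept is equivariant under per-column affine maps, the
two modes produce identical held-out predictions up to round-off; both are
kept so the equivalence is checkable rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .select import SelectionTrace

__all__ = ["ModelStats", "calibration_stats", "loo_predictions", "loo_stats",
           "choose_model_size", "selection_loo"]


@dataclass
class ModelStats:
    """The seven-statistic performance panel of a calibration model."""

    sd_error: float                    # calibration residual SD, response units
    mae: float                         # mean absolute calibration error
    r: float                           # multiple correlation coefficient, [0, 1]
    loo_residual_variance_pct: float   # 100 * PRESS / SS_tot
    loo_residual_sd: float
    loo_explained_variance_pct: float  # exact complement of the residual %
    loo_mean_prediction_error: float   # mean |LOO residual|
    r_degenerate: bool = False         # True when R was undefined (constant fit)

    def to_dict(self) -> dict:
        return asdict(self)

    LABELS = (
        ("sd_error", "Standard Deviation of the Error"),
        ("mae", "Mean Absolute Error (MAE)"),
        ("r", "Multiple Correlation Coefficient (R)"),
        ("loo_residual_variance_pct", "Leave-One-Out Residual Variance (%)"),
        ("loo_residual_sd", "Leave-One-Out Residual Standard Deviation"),
        ("loo_explained_variance_pct", "Leave-One-Out Explained Variance (%)"),
        ("loo_mean_prediction_error", "Leave-One-Out Mean Prediction Error"),
    )


def calibration_stats(y, y_fit, p: int) -> dict:
    """Calibration-side statistics for a fit with ``p`` predictors.

    ``sd_error = sqrt(SS_res / (n - p - 1))``; R is the Pearson correlation
    between observed and fitted values, reported as 0 (with a degeneracy
    flag) when the fitted values are constant.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_fit = np.asarray(y_fit, dtype=float).ravel()
    if y.size != y_fit.size:
        raise ValueError("y and y_fit must have equal length")
    n = y.size
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    resid = y - y_fit
    ss_res = float(resid @ resid)
    sd_error = float(np.sqrt(ss_res / (n - p - 1)))
    mae = float(np.mean(np.abs(resid)))
    degenerate = np.std(y_fit) <= 0 or np.std(y) <= 0
    if degenerate:
        r = 0.0
    else:
        r = float(np.corrcoef(y, y_fit)[0, 1])
        r = float(np.clip(abs(r), 0.0, 1.0))
    return {"sd_error": sd_error, "mae": mae, "r": r, "r_degenerate": bool(degenerate)}


def _ols_fit_predict(X_tr, y_tr, X_te):
    """Least-squares fit with intercept on X_tr, predictions for X_te."""
    A = np.column_stack([np.ones(X_tr.shape[0]), X_tr])
    beta, *_ = np.linalg.lstsq(A, y_tr, rcond=None)
    return np.column_stack([np.ones(X_te.shape[0]), X_te]) @ beta


def loo_predictions(X, y, *, scaling: str = "refit") -> np.ndarray:
    """Leave-one-out predictions of an OLS fit with intercept on ``X``.

    ``X`` holds only the selected channels (raw or pre-scaled; the
    predictions are invariant to that choice). See module docstring for the
    two scaling modes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"LOO needs n > p + 2 (n={n}, p={p})")
    if scaling == "fixed":
        A = np.column_stack([np.ones(n), X])
        Q, _ = np.linalg.qr(A)
        h = np.einsum("ij,ij->i", Q, Q)
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        e = y - A @ beta
        denom = 1.0 - h
        if np.any(denom <= 1e-12):
            i = int(np.argmin(denom))
            raise ValueError(f"leverage ~1 at left-out row {i}; LOO fit is degenerate")
        return y - e / denom
    if scaling != "refit":
        raise ValueError("scaling must be 'refit' or 'fixed'")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr = X[mask]
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0, ddof=1)
        sd = np.where(sd <= 0, 1.0, sd)
        try:
            preds[i] = _ols_fit_predict((X_tr - mu) / sd, y[mask], (X[i:i + 1] - mu) / sd)[0]
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"rank-deficient LOO refit leaving out row {i}") from exc
    return preds


def loo_stats(
    X_sel,
    y,
    *,
    p: int | None = None,
    scaling: str = "refit",
    sd_denominator: str = "n-p-1",
) -> ModelStats:
    """Full seven-statistic panel for an OLS model on the given channels.

    Parameters
    ----------
    X_sel : (n, p) array
        The selected channel columns only.
    y : (n,) array
        Response.
    scaling : {'refit', 'fixed'}
        LOO preprocessing mode (see module docstring).
    sd_denominator : {'n-p-1', 'n'}
        Denominator of the LOO residual SD; ``n-p-1`` mirrors the
        calibration SD and is the default.
    """
    X_sel = np.asarray(X_sel, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if p is None:
        p = X_sel.shape[1]
    y_fit = _ols_fit_predict(X_sel, y, X_sel)
    cal = calibration_stats(y, y_fit, p)
    d = y - loo_predictions(X_sel, y, scaling=scaling)
    press = float(d @ d)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("constant response: LOO variance ratios are undefined")
    resid_pct = 100.0 * press / ss_tot
    denom = (n - p - 1) if sd_denominator == "n-p-1" else n
    if denom <= 0:
        raise ValueError("non-positive denominator for the LOO residual SD")
    return ModelStats(
        sd_error=cal["sd_error"],
        mae=cal["mae"],
        r=cal["r"],
        loo_residual_variance_pct=resid_pct,
        loo_residual_sd=float(np.sqrt(press / denom)),
        loo_explained_variance_pct=100.0 - resid_pct,
        loo_mean_prediction_error=float(np.mean(np.abs(d))),
        r_degenerate=cal["r_degenerate"],
    )


def choose_model_size(
    Xs,
    y,
    trace: SelectionTrace,
    *,
    scaling: str = "refit",
) -> tuple[int, np.ndarray]:
    """Pick the nested-prefix model size minimizing the LOO prediction error.

    Evaluates the prefixes ``k = 1..len(trace)`` of the selection trace,
    computing the LOO mean prediction error of each; returns the smallest
    ``k`` attaining the minimum together with the full ``(k, error)`` curve
    as an ``(len(trace), 2)`` array. Prefixes too large for LOO
    (``n <= k + 2``) are not evaluated.
    """
    Xs = np.asarray(Xs, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(trace) < 1:
        raise ValueError("empty selection trace")
    n = y.size
    cols = [i - 1 for i in trace.indices]
    errs = []
    for k in range(1, len(trace) + 1):
        if n <= k + 2:
            break
        d = y - loo_predictions(Xs[:, cols[:k]], y, scaling=scaling)
        errs.append(float(np.mean(np.abs(d))))
    if not errs:
        raise ValueError("no prefix size admits leave-one-out validation")
    curve = np.column_stack([np.arange(1, len(errs) + 1), errs])
    k_star = int(np.argmin(errs)) + 1  # argmin -> smallest k on ties
    return k_star, curve


def selection_loo(
    Xs,
    y,
    *,
    k_max: int = 30,
    r_min: float = 0.05,
    tol_var: float = 1e-6,
    grid=None,
    excluded=None,
):
    """Nested LOO in which the variable selection is re-run inside each fold.

    The fixed-trace LOO of :func:`loo_stats` conditions on a selection made
    from all samples; with hundreds of candidate channels that conditioning
    is optimistic (the selection has already seen the held-out sample), and
    on a pure-noise response it can report large spurious explained
    variance. Re-running SELECT on each fold's n-1 samples removes that
    bias, at the price of a possibly different channel subset per fold; it
    is the right tool for permutation/negative controls and for an unbiased
    generalization estimate of the whole procedure.

    Returns a dict with the honest per-size error curve (sizes up to the
    shortest per-fold trace), the size ``k`` minimizing it, and PRESS /
    explained variance / mean absolute prediction error at that size.
    """
    from .select import run_select
    from .spectra import STUDY_GRID

    if grid is None:
        grid = STUDY_GRID
    Xs = np.asarray(Xs, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    preds = []  # per fold: vector of predictions for k = 1..len(trace_i)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        trace_i = run_select(Xs[mask], y[mask], k_max=k_max, r_min=r_min,
                             tol_var=tol_var, grid=grid, excluded=excluded)
        cols = [j - 1 for j in trace_i.indices]
        fold_preds = np.empty(len(cols))
        for k in range(1, len(cols) + 1):
            fold_preds[k - 1] = _ols_fit_predict(
                Xs[mask][:, cols[:k]], y[mask], Xs[i:i + 1, cols[:k]])[0]
        preds.append(fold_preds)
    k_common = min(len(p) for p in preds)
    P = np.vstack([p[:k_common] for p in preds])  # (n, k_common)
    D = y[:, None] - P
    curve = np.abs(D).mean(axis=0)
    k_star = int(np.argmin(curve)) + 1
    press_by_k = np.einsum("ij,ij->j", D, D)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    explained_by_k = 100.0 * (1.0 - press_by_k / ss_tot)
    return {
        "k": k_star,
        "curve": np.column_stack([np.arange(1, k_common + 1), curve]),
        "press": float(press_by_k[k_star - 1]),
        "explained_pct": float(explained_by_k[k_star - 1]),
        "explained_by_k": explained_by_k,
        "mean_abs_error": float(curve[k_star - 1]),
    }
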
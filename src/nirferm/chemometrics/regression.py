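"""MLR and NIPALS PLS1 regression with leave-one-out PRESS selection."""

from __future__ import annotations

import numpy as np

from .model import CalibrationModel
from .pretreat import PretreatmentSpec
from .stats import calibration_stats

__all__ = ["FitError", "fit_mlr", "fit_pls", "press_select"]


class FitError(RuntimeError):
    pass


def _default_columns(p: int) -> np.ndarray:
    return np.arange(p)


def fit_mlr(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray | None = None,
    feature_columns: np.ndarray | None = None,
    analyte: str = "",
    instrument: str = "",
) -> CalibrationModel:
    """Ordinary least squares with intercept on all channels.

    Refuses under-determined problems (n <= p + 1) and rank-deficient
    designs rather than falling back to a pseudo-inverse.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise FitError(f"MLR needs n > p + 1 samples (got n={n}, p={p})")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        raise FitError("rank-deficient design matrix; refusing to fit")
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    b, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    yhat = ym + Xc @ b
    stats = calibration_stats(yhat, y, df_model=p, role="calibration")
    if wavelengths is None:
        wavelengths = np.arange(p, dtype=float)
    if feature_columns is None:
        feature_columns = _default_columns(p)
    return CalibrationModel(
        method="MLR",
        analyte=analyte,
        pretreatment=PretreatmentSpec(kind="none"),
        wavelengths=wavelengths,
        feature_columns=feature_columns,
        x_mean=xm,
        y_mean=ym,
        coefficients=b,
        training_range=(float(y.min()), float(y.max())),
        training_stats=stats,
        instrument=instrument,
    )


def _nipals_path(
    Xc: np.ndarray, yc: np.ndarray, n_factors: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """NIPALS PLS1 factor extraction on centered data.

    Returns (W, P, q, a_eff): weights, x-loadings, y-loadings and the number
    of factors actually extracted (may stop early when X or the covariance
    with y is exhausted).
    """
    n, p = Xc.shape
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    Xd = Xc.copy()
    yd = yc.copy()
    a_eff = 0
    for a in range(n_factors):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pa)
        yd -= qa * t
        W[:, a] = w
        P[:, a] = pa
        q[a] = qa
        a_eff = a + 1
    return W[:, :a_eff], P[:, :a_eff], q[:a_eff], a_eff


def _pls_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, f: int) -> np.ndarray:
    """Regression vector using the first f factors: b = W (P'W)^-1 q.

    Slices are copied to contiguous arrays so that truncating a longer
    factor path is bitwise identical to refitting with f factors.
    """
    Wf = np.ascontiguousarray(W[:, :f])
    Pf = np.ascontiguousarray(P[:, :f])
    return Wf @ np.linalg.solve(Pf.T @ Wf, np.ascontiguousarray(q[:f]))


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    wavelengths: np.ndarray | None = None,
    feature_columns: np.ndarray | None = None,
    pretreatment: PretreatmentSpec | None = None,
    analyte: str = "",
    instrument: str = "",
) -> CalibrationModel:
    """NIPALS PLS1 on (optionally pretreated) spectra.

    ``X`` is the feature matrix the model will see at prediction time; the
    ``pretreatment``/``wavelengths``/``feature_columns`` arguments only
    record how to reproduce those features from raw spectra.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= n_factors <= min(n - 1, p):
        raise FitError(
            f"n_factors must lie in [1, {min(n - 1, p)}] for n={n}, p={p}"
        )
    xm = X.mean(axis=0)
    ym = float(y.mean())
    W, P, q, a_eff = _nipals_path(X - xm, y - ym, n_factors)
    if a_eff == 0:
        raise FitError("y carries no covariance with X; cannot extract a factor")
    b = _pls_coefficients(W, P, q, a_eff)
    yhat = ym + (X - xm) @ b
    stats = calibration_stats(yhat, y, df_model=a_eff, role="calibration")
    if wavelengths is None:
        wavelengths = np.arange(p, dtype=float)
    if feature_columns is None:
        feature_columns = _default_columns(p)
    if pretreatment is None:
        pretreatment = PretreatmentSpec(kind="none")
    return CalibrationModel(
        method="PLS",
        analyte=analyte,
        pretreatment=pretreatment,
        wavelengths=wavelengths,
        feature_columns=feature_columns,
        x_mean=xm,
        y_mean=ym,
        coefficients=b,
        n_factors=a_eff,
        training_range=(float(y.min()), float(y.max())),
        training_stats=stats,
        instrument=instrument,
        loadings={"W": W, "P": P, "q": q},
    )


def press_select(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int,
    cv_scheme: str | int = "loo",
) -> tuple[int, np.ndarray, np.ndarray]:
    """Choose the PLS factor count by minimum cross-validated PRESS.

    Returns ``(n_factors, press, secv)`` where ``press[f-1]`` is the sum of
    squared left-out prediction errors with f factors and ``secv`` =
    sqrt(press / n).  Ties resolve to the smallest factor count.  Each fold
    is re-centered and refit, so the leave-one-out curve equals an explicit
    per-sample refit loop exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= max_factors <= min(n - 2, p):
        raise FitError(
            f"max_factors must lie in [1, {min(n - 2, p)}] for n={n}, p={p}"
        )
    if cv_scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif isinstance(cv_scheme, int):
        if not 2 <= cv_scheme <= n:
            raise FitError("k-fold scheme needs 2 <= k <= n")
        folds = [f for f in np.array_split(np.arange(n), cv_scheme) if len(f)]
    else:
        raise FitError(f"unknown cv scheme {cv_scheme!r}")

    press = np.zeros(max_factors)
    for held in folds:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        Xt, yt = X[mask], y[mask]
        xm = Xt.mean(axis=0)
        ym = yt.mean()
        W, P, q, a_eff = _nipals_path(Xt - xm, yt - ym, max_factors)
        Xh = X[held] - xm
        for f in range(1, max_factors + 1):
            fe = min(f, a_eff)
            if fe == 0:
                pred = np.full(len(held), ym)
            else:
                pred = ym + Xh @ _pls_coefficients(W, P, q, fe)
            press[f - 1] += float(np.sum((y[held] - pred) ** 2))
    best = int(np.argmin(press)) + 1  # argmin takes the first (smallest) index
    secv = np.sqrt(press / n)
    return best, press, secv
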
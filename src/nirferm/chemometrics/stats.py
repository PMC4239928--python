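"""Calibration/validation error statistics and the paired NIR-vs-lab test."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["ValidationStats", "calibration_stats", "paired_nir_lab_test"]


@dataclass
class ValidationStats:
    """Accuracy summary in concentration units (g/L).

    ``SEP`` is bias-corrected (residual sd about the mean error); ``RMSEC``
    / ``RMSEP`` are raw root-mean-square errors on the calibration /
    prediction set; ``SEC`` divides by n - df_model - 1.
    """

    n: int
    R2: float
    bias: float
    SEC: float | None = None
    SECV: float | None = None
    SEP: float | None = None
    RMSEC: float | None = None
    RMSEP: float | None = None
    PRESS: float | None = None
    t_stat: float | None = None
    p_value: float | None = None
    y_range: tuple[float, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("SEC", "SECV", "SEP", "RMSEC", "RMSEP", "PRESS"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, tuple):
                v = list(v)
            out[k] = v
        return out


def calibration_stats(
    pred: np.ndarray,
    ref: np.ndarray,
    df_model: int,
    role: str = "prediction",
) -> ValidationStats:
    """Compute bias, RMSE, bias-corrected SEP, df-adjusted SEC and R^2.

    ``role`` selects whether the RMSE is reported as RMSEC (calibration
    set) or RMSEP (prediction set); all other quantities are identical.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("pred and ref must be equal-length 1-D arrays")
    n = len(pred)
    if n < 3:
        raise ValueError("need at least 3 samples for statistics")
    if role not in ("calibration", "prediction"):
        raise ValueError(f"unknown role {role!r}")
    if np.var(ref) == 0:
        raise ValueError("reference values have zero variance; R2 undefined")
    e = pred - ref
    bias = float(e.mean())
    rmse = float(np.sqrt(np.mean(e**2)))
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    sec = None
    if n - df_model - 1 > 0:
        sec = float(np.sqrt(np.sum(e**2) / (n - df_model - 1)))
    r = np.corrcoef(pred, ref)[0, 1] if np.var(pred) > 0 else 0.0
    return ValidationStats(
        n=n,
        R2=float(r**2),
        bias=bias,
        SEC=sec,
        SEP=sep,
        RMSEC=rmse if role == "calibration" else None,
        RMSEP=rmse if role == "prediction" else None,
        y_range=(float(ref.min()), float(ref.max())),
    )


def paired_nir_lab_test(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Classical paired t test of NIR predictions against lab references.

    Returns (t statistic, two-sided p value).  Zero-variance differences are
    handled explicitly: identical series give (0, 1); a constant nonzero
    offset gives (+/-inf, 0).
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("pred and ref must be equal-length 1-D arrays")
    n = len(pred)
    if n < 2:
        raise ValueError("paired test needs at least 2 pairs")
    d = pred - ref
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        return float(np.sign(mean)) * float("inf"), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p)
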
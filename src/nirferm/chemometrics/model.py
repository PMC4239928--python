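"""Calibration model container, prediction path, and JSON round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .pretreat import PretreatmentSpec, norris_second_derivative
from .stats import ValidationStats

__all__ = ["CalibrationModel", "PredictionResult", "predict"]


@dataclass
class CalibrationModel:
    """A fitted MLR or PLS calibration for one analyte.

    ``feature_columns`` indexes into the pretreated feature vector (the raw
    channels for MLR, the retained second-derivative points for PLS) after
    removal of saturated channels.  Prediction of the training mean spectrum
    returns the training mean reference by construction (centered model).
    """

    method: str  # MLR | PLS
    analyte: str
    pretreatment: PretreatmentSpec
    wavelengths: np.ndarray  # full instrument grid, nm
    feature_columns: np.ndarray  # columns of the pretreated matrix used
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray  # regression vector over feature columns
    n_factors: int | None = None
    training_range: tuple[float, float] = (0.0, 0.0)
    training_stats: ValidationStats | None = None
    instrument: str = ""
    loadings: dict = field(default_factory=dict)  # PLS W/P/q for audit
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("MLR", "PLS"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "PLS" and (self.n_factors is None or self.n_factors < 1):
            raise ValueError("PLS model needs n_factors >= 1")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.feature_columns = np.asarray(self.feature_columns, dtype=int)
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "analyte": self.analyte,
            "pretreatment": {
                "kind": self.pretreatment.kind,
                "segment": self.pretreatment.segment,
                "gap": self.pretreatment.gap,
            },
            "wavelengths": self.wavelengths.tolist(),
            "feature_columns": self.feature_columns.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "coefficients": self.coefficients.tolist(),
            "n_factors": self.n_factors,
            "training_range": list(self.training_range),
            "instrument": self.instrument,
            "loadings": {k: np.asarray(v).tolist() for k, v in self.loadings.items()},
            "metadata": self.metadata,
        }
        if self.training_stats is not None:
            d["training_stats"] = self.training_stats.to_dict()
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        stats = None
        if "training_stats" in d:
            sd = dict(d["training_stats"])
            if sd.get("y_range") is not None:
                sd["y_range"] = tuple(sd["y_range"])
            stats = ValidationStats(**sd)
        return cls(
            method=d["method"],
            analyte=d["analyte"],
            pretreatment=PretreatmentSpec(**d["pretreatment"]),
            wavelengths=np.asarray(d["wavelengths"], dtype=float),
            feature_columns=np.asarray(d["feature_columns"], dtype=int),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=d["y_mean"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            n_factors=d.get("n_factors"),
            training_range=tuple(d["training_range"]),
            training_stats=stats,
            instrument=d.get("instrument", ""),
            loadings={k: np.asarray(v) for k, v in d.get("loadings", {}).items()},
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, text_or_path: str) -> "CalibrationModel":
        text = text_or_path
        if "{" not in text_or_path:
            with open(text_or_path, encoding="utf-8") as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))


@dataclass
class PredictionResult:
    values: np.ndarray  # g/L
    out_of_range: np.ndarray  # True where outside training range +/- 10%

    def __iter__(self):
        return iter(self.values)


def features_from_matrix(model: CalibrationModel, raw: np.ndarray) -> np.ndarray:
    """Pretreat a raw spectra matrix and select the model's feature columns."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[1] != len(model.wavelengths):
        raise ValueError(
            f"grid mismatch: model expects {len(model.wavelengths)} channels, "
            f"got {raw.shape[1]}"
        )
    pretreated, _ = norris_second_derivative(raw, model.pretreatment)
    return pretreated[:, model.feature_columns]


def predict(
    model: CalibrationModel,
    spectra,
    grid: np.ndarray | None = None,
) -> PredictionResult:
    """Predict concentrations from spectra on the model's instrument grid.

    ``spectra`` may be a Spectrum, a list of Spectrum, or a raw absorbance
    matrix (then ``grid`` is checked if given).  The model's pretreatment is
    applied internally.
    """
    raw, in_grid = _as_matrix(spectra, grid)
    if in_grid is not None and not np.array_equal(in_grid, model.wavelengths):
        raise ValueError("spectra grid does not match the model's grid")
    F = features_from_matrix(model, raw)
    yhat = model.y_mean + (F - model.x_mean) @ model.coefficients
    lo, hi = model.training_range
    margin = 0.1 * (hi - lo)
    flags = (yhat < lo - margin) | (yhat > hi + margin)
    return PredictionResult(values=yhat, out_of_range=flags)


def _as_matrix(spectra, grid):
    from ..spectra import Spectrum  # local import to avoid a cycle

    if isinstance(spectra, Spectrum):
        return spectra.absorbance[None, :], spectra.wavelength_grid
    if isinstance(spectra, (list, tuple)) and spectra and isinstance(
        spectra[0], Spectrum
    ):
        g = spectra[0].wavelength_grid
        for s in spectra[1:]:
            if not np.array_equal(s.wavelength_grid, g):
                raise ValueError("spectra in the batch are on different grids")
        return np.vstack([s.absorbance for s in spectra]), g
    return np.atleast_2d(np.asarray(spectra, dtype=float)), grid
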
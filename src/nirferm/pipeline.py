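"""Study orchestration: build, validate and transfer calibrations.

Two default studies mirror the experimental setups: an on-line 19-filter
MLR study on homolactic broths (45 calibration + 30 validation samples)
and an in-line full-spectrum-probe PLS study on heterolactic broths
(80 + 30) with Norris second-derivative pretreatment, PCA/Mahalanobis
sample screening and LOO-PRESS factor selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chemometrics import (
    CalibrationModel,
    PretreatmentSpec,
    calibration_stats,
    fit_mlr,
    fit_pls,
    paired_nir_lab_test,
    pca_mahalanobis_screen,
    predict,
    press_select,
)
from .chemometrics.pretreat import norris_second_derivative
from .chemometrics.stats import ValidationStats
from .simulate import (
    ANALYTES,
    AssayNoiseModel,
    OrganismProfile,
    cluster_profile,
    design_calibration_states,
    homolactic_profile,
    reference_assay,
)
from .spectra import (
    HydrodynamicState,
    InstrumentSpec,
    filter19_instrument,
    generate_spectrum,
    probe_instrument,
)

__all__ = [
    "StudyConfig",
    "PipelineError",
    "TransferError",
    "DiscriminationResult",
    "default_homolactic_study",
    "default_heterolactic_study",
    "build_calibration",
    "build_all_calibrations",
    "external_validation",
    "transfer_model",
    "discriminate_mean_spectra",
    "generate_dataset",
    "study_report",
]


class PipelineError(RuntimeError):
    pass


class TransferError(RuntimeError):
    pass


@dataclass
class StudyConfig:
    organism: OrganismProfile
    instrument: InstrumentSpec
    n_calibration: int
    n_validation: int
    method: str  # MLR | PLS
    noise: AssayNoiseModel = field(default_factory=AssayNoiseModel)
    seed: int = 0
    hydro: HydrodynamicState = field(default_factory=HydrodynamicState)
    pretreatment: PretreatmentSpec = field(
        default_factory=lambda: PretreatmentSpec(kind="norris_d2", segment=5, gap=5)
    )
    max_factors: int = 12
    md_limit: float = 3.0
    retained_variance: float = 0.99

    def __post_init__(self) -> None:
        if self.method not in ("MLR", "PLS"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_calibration < 10 or self.n_validation < 3:
            raise ValueError("calibration/validation set sizes too small")


def default_homolactic_study(seed: int = 0) -> StudyConfig:
    """On-line filter-wheel MLR study: 45 calibration + 30 validation."""
    return StudyConfig(
        organism=homolactic_profile(),
        instrument=filter19_instrument(),
        n_calibration=45,
        n_validation=30,
        method="MLR",
        noise=AssayNoiseModel(),
        seed=seed,
        hydro=HydrodynamicState(stirring=120.0, airflow=0.0),
        pretreatment=PretreatmentSpec(kind="none"),
    )


def default_heterolactic_study(seed: int = 0) -> StudyConfig:
    """In-line immersion-probe PLS study: 80 calibration + 30 validation."""
    return StudyConfig(
        organism=cluster_profile(),
        instrument=probe_instrument(),
        n_calibration=80,
        n_validation=30,
        method="PLS",
        noise=AssayNoiseModel(),
        seed=seed,
        hydro=HydrodynamicState(stirring=400.0, airflow=0.5),
        pretreatment=PretreatmentSpec(kind="norris_d2", segment=5, gap=5),
    )


# dataset keys keep calibration, validation and transfer draws disjoint
_DATASET_KEYS = {"calibration": 11, "validation": 23, "transfer": 37}


def generate_dataset(
    config: StudyConfig,
    n: int,
    purpose: str = "calibration",
    organism: OrganismProfile | None = None,
    seed: int | None = None,
):
    """Simulate n broth states, their spectra matrix and reference assays.

    Returns ``(states, raw_matrix, saturated_any, refs)`` where ``refs`` is
    an (n, 4) array in the analyte order glucose/lactate/acetate/biomass.
    All randomness descends from ``(seed or config.seed, purpose)``.
    """
    organism = organism or config.organism
    root = seed if seed is not None else config.seed
    ss = np.random.SeedSequence([int(root), _DATASET_KEYS[purpose]])
    design_ss, spectra_ss, assay_ss = ss.spawn(3)
    states = design_calibration_states(n, organism, seed=design_ss)
    rng = np.random.default_rng(spectra_ss)
    spectra = [
        generate_spectrum(
            s,
            config.instrument,
            config.hydro,
            rng=rng,
            scatter_coefficient=organism.scatter_coefficient,
            library=organism.chromophore_set,
        )
        for s in states
    ]
    raw = np.vstack([s.absorbance for s in spectra])
    saturated_any = np.any(np.vstack([s.saturated for s in spectra]), axis=0)
    noise = replace(config.noise, seed=int(assay_ss.generate_state(1)[0]))
    refs = np.array([reference_assay(s, noise) for s in states])
    return states, raw, saturated_any, refs


def _saturation_safe_columns(
    saturated_any: np.ndarray, retained: np.ndarray, pre: PretreatmentSpec
) -> np.ndarray:
    """Pretreated columns whose stencil avoids every saturated raw channel."""
    if pre.kind == "none":
        return np.flatnonzero(~saturated_any)
    edge = pre.edge_width()
    bad = np.flatnonzero(saturated_any)
    cols = []
    for j, idx in enumerate(retained):
        if not np.any((bad >= idx - edge) & (bad <= idx + edge)):
            cols.append(j)
    return np.asarray(cols, dtype=int)


def build_calibration(config: StudyConfig, analyte: str) -> CalibrationModel:
    """Full calibration pipeline for one analyte.

    MLR route: raw filter absorbances -> OLS.  PLS route: Norris second
    derivative -> saturation masking -> Mahalanobis screening -> LOO-PRESS
    factor selection -> NIPALS fit.  Aborts if screening removes more than
    20% of the samples (a design problem, not an outlier problem).
    """
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}")
    states, raw, saturated_any, refs = generate_dataset(
        config, config.n_calibration, "calibration"
    )
    y = refs[:, ANALYTES.index(analyte)]
    grid = config.instrument.wavelength_grid
    meta = {
        "seed": config.seed,
        "organism": config.organism.name,
        "chromophore_set": config.organism.chromophore_set,
        "n_designed": len(states),
    }

    if config.method == "MLR":
        cols = np.flatnonzero(~saturated_any)
        model = fit_mlr(
            raw[:, cols],
            y,
            wavelengths=grid,
            feature_columns=cols,
            analyte=analyte,
            instrument=config.instrument.geometry,
        )
        model.metadata.update(meta)
        return model

    pretreated, retained = norris_second_derivative(raw, config.pretreatment)
    cols = _saturation_safe_columns(saturated_any, retained, config.pretreatment)
    X = pretreated[:, cols]
    inliers, outliers, _ = pca_mahalanobis_screen(
        X, md_limit=config.md_limit, retained_variance=config.retained_variance
    )
    if len(outliers) > 0.2 * len(y):
        raise PipelineError(
            f"screening flagged {len(outliers)}/{len(y)} samples; "
            "the calibration design is unsound"
        )
    X, y = X[inliers], y[inliers]
    n_factors, press, secv = press_select(X, y, config.max_factors, "loo")
    model = fit_pls(
        X,
        y,
        n_factors,
        wavelengths=grid,
        feature_columns=cols,
        pretreatment=config.pretreatment,
        analyte=analyte,
        instrument=config.instrument.geometry,
    )
    model.training_stats.SECV = float(secv[n_factors - 1])
    model.training_stats.PRESS = float(press[n_factors - 1])
    meta.update(
        {
            "n_outliers_removed": int(len(outliers)),
            "press_curve": press.tolist(),
            "secv_curve": secv.tolist(),
        }
    )
    model.metadata.update(meta)
    return model


def build_all_calibrations(config: StudyConfig) -> dict[str, CalibrationModel]:
    """One model per analyte; homolactic studies skip the absent acetate."""
    analytes = [
        a
        for a in ANALYTES
        if config.organism.analyte_ranges.get(a, (0, 1))[1] > 0
    ]
    return {a: build_calibration(config, a) for a in analytes}


def external_validation(
    model: CalibrationModel,
    config: StudyConfig,
    n: int | None = None,
    seed: int | None = None,
) -> ValidationStats:
    """Validate on freshly generated, never-seen states and spectra."""
    n = n if n is not None else config.n_validation
    if n < 3:
        raise ValueError("validation set too small")
    if model.instrument and model.instrument != config.instrument.geometry:
        raise PipelineError(
            f"instrument mismatch: model built on {model.instrument!r}, "
            f"config uses {config.instrument.geometry!r}"
        )
    states, raw, _, refs = generate_dataset(config, n, "validation", seed=seed)
    y = refs[:, ANALYTES.index(model.analyte)]
    pred = predict(model, raw).values
    df = model.n_factors if model.method == "PLS" else len(model.coefficients)
    stats = calibration_stats(pred, y, df_model=df, role="prediction")
    stats.t_stat, stats.p_value = paired_nir_lab_test(pred, y)
    stats.seed = int(seed if seed is not None else config.seed)
    return stats


def transfer_model(
    model: CalibrationModel,
    target: OrganismProfile,
    config: StudyConfig,
    n_val: int = 20,
    seed: int | None = None,
    force: bool = False,
) -> ValidationStats:
    """Apply a calibration unchanged to broths of a different organism.

    Refuses when the organisms do not share a chromophore library (the
    transfer premise) unless ``force`` is set, which is only useful to
    demonstrate the failure mode.
    """
    source_set = model.metadata.get("chromophore_set", "standard")
    if target.chromophore_set != source_set and not force:
        raise TransferError(
            f"target library {target.chromophore_set!r} differs from the "
            f"model's {source_set!r}; transfer premise violated"
        )
    states, raw, _, refs = generate_dataset(
        config, n_val, "transfer", organism=target, seed=seed
    )
    y = refs[:, ANALYTES.index(model.analyte)]
    pred = predict(model, raw).values
    df = model.n_factors if model.method == "PLS" else len(model.coefficients)
    stats = calibration_stats(pred, y, df_model=df, role="prediction")
    stats.t_stat, stats.p_value = paired_nir_lab_test(pred, y)
    stats.seed = int(seed if seed is not None else config.seed)
    return stats


@dataclass
class DiscriminationResult:
    difference: np.ndarray  # mean(A) - mean(B) per wavelength
    band: np.ndarray  # +/- 3 pooled standard errors
    max_abs_difference: float
    argmax_index: int
    verdict: str  # indistinguishable | distinguishable


def discriminate_mean_spectra(
    setA: np.ndarray, setB: np.ndarray
) -> DiscriminationResult:
    """Subtract mean spectra of two sample sets and judge the difference.

    Verdict is "indistinguishable" iff the difference curve stays within
    +/-3 pooled standard errors of the means at every wavelength.
    """
    A = np.atleast_2d(np.asarray(setA, dtype=float))
    B = np.atleast_2d(np.asarray(setB, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("spectra sets are on different grids")
    if len(A) < 20 or len(B) < 20:
        raise ValueError("need at least 20 spectra per set")
    diff = A.mean(axis=0) - B.mean(axis=0)
    se = np.sqrt(A.var(axis=0, ddof=1) / len(A) + B.var(axis=0, ddof=1) / len(B))
    band = 3.0 * se
    inside = np.all(np.abs(diff) <= band)
    j = int(np.argmax(np.abs(diff)))
    return DiscriminationResult(
        difference=diff,
        band=band,
        max_abs_difference=float(np.abs(diff[j])),
        argmax_index=j,
        verdict="indistinguishable" if inside else "distinguishable",
    )


def study_report(config: StudyConfig) -> str:
    """Calibration + external-validation table for every analyte."""
    models = build_all_calibrations(config)
    lines = [
        f"Study: {config.organism.name} / {config.instrument.geometry} / "
        f"{config.method} (seed {config.seed})",
        f"{'Analyte':<12}{'Range (g/L)':<14}{'R2 cal':<9}{'SEC':<8}"
        f"{'SECV':<8}{'R2 val':<9}{'SEP':<8}{'RMSEP':<8}{'Factors':<8}",
    ]
    for analyte, model in models.items():
        val = external_validation(model, config)
        ts = model.training_stats
        rng = model.training_range
        lines.append(
            f"{analyte:<12}{f'{rng[0]:.0f}-{rng[1]:.0f}':<14}"
            f"{ts.R2:<9.4f}{_fmt(ts.SEC):<8}{_fmt(ts.SECV):<8}"
            f"{val.R2:<9.4f}{_fmt(val.SEP):<8}{_fmt(val.RMSEP):<8}"
            f"{model.n_factors if model.n_factors else '-':<8}"
        )
    return "\n".join(lines)


def _fmt(v) -> str:
    return f"{v:.2f}" if v is not None else "-"
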
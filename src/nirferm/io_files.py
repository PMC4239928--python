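"""File formats, configuration documents, and run manifests.

All artifacts are UTF-8 text with dot decimal separators: spectra matrices
and trajectories as CSV, models as JSON, configs as YAML.  Floats are
written with shortest round-trip repr, so write/read cycles are bitwise
lossless.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import __version__
from .chemometrics import PretreatmentSpec
from .pipeline import (
    StudyConfig,
    default_heterolactic_study,
    default_homolactic_study,
)
from .simulate import (
    AssayNoiseModel,
    DEFAULT_PROFILES,
    KineticParams,
    Trajectory,
)
from .spectra import (
    HydrodynamicState,
    filter19_instrument,
    fullspectrum_instrument,
    probe_instrument,
)

__all__ = [
    "SpectraFormatError",
    "EmptyInputError",
    "GridMonotonicityError",
    "RaggedRowsError",
    "NonNumericCellError",
    "ConfigError",
    "RunManifest",
    "read_spectra_csv",
    "write_spectra_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_eventlog_csv",
    "load_study_config",
    "config_hash",
]


class SpectraFormatError(ValueError):
    pass


class EmptyInputError(SpectraFormatError):
    pass


class GridMonotonicityError(SpectraFormatError):
    pass


class RaggedRowsError(SpectraFormatError):
    pass


class NonNumericCellError(SpectraFormatError):
    pass


class ConfigError(ValueError):
    pass


def _fmt(v: float) -> str:
    return repr(float(v))


def write_spectra_csv(
    matrix: np.ndarray,
    grid: np.ndarray,
    path: str,
    sample_ids: list[str] | None = None,
) -> None:
    """First row: sample_id + wavelengths (nm); one row per sample."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if matrix.shape[1] != len(grid):
        raise SpectraFormatError("matrix width does not match the grid")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(matrix))]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id," + ",".join(_fmt(w) for w in grid) + "\n")
        for sid, row in zip(sample_ids, matrix):
            fh.write(str(sid) + "," + ",".join(_fmt(v) for v in row) + "\n")


def read_spectra_csv(path: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Returns (matrix, grid, sample_ids); raises a distinct error per defect."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty spectra file")
    header = lines[0].split(",")
    try:
        grid = np.array([float(v) for v in header[1:]])
    except ValueError as e:
        raise NonNumericCellError(f"{path}: non-numeric wavelength header: {e}")
    if len(grid) == 0:
        raise EmptyInputError(f"{path}: header carries no wavelengths")
    if np.any(np.diff(grid) <= 0):
        raise GridMonotonicityError(
            f"{path}: wavelength header is not strictly increasing"
        )
    ids, rows = [], []
    for k, ln in enumerate(lines[1:], start=2):
        cells = ln.split(",")
        if len(cells) != len(grid) + 1:
            raise RaggedRowsError(
                f"{path}: row {k} has {len(cells) - 1} values, expected {len(grid)}"
            )
        ids.append(cells[0])
        try:
            rows.append([float(v) for v in cells[1:]])
        except ValueError as e:
            raise NonNumericCellError(f"{path}: row {k}: {e}")
    if not rows:
        raise EmptyInputError(f"{path}: no sample rows")
    return np.array(rows), grid, ids


_TRAJ_HEADER = "time_h,glucose_gL,lactate_gL,acetate_gL,biomass_gL,volume_L,event"


def write_trajectory_csv(traj: Trajectory, path: str) -> None:
    events = dict()
    for t, kind in traj.events:
        events.setdefault(round(t, 9), []).append(kind)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_TRAJ_HEADER + "\n")
        for i in range(len(traj)):
            ev = ";".join(events.get(round(float(traj.times[i]), 9), []))
            fh.write(
                ",".join(
                    [
                        _fmt(traj.times[i]),
                        _fmt(traj.glucose[i]),
                        _fmt(traj.lactate[i]),
                        _fmt(traj.acetate[i]),
                        _fmt(traj.biomass[i]),
                        _fmt(traj.volume[i]),
                        ev,
                    ]
                )
                + "\n"
            )


def read_trajectory_csv(path: str) -> Trajectory:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or lines[0] != _TRAJ_HEADER:
        raise SpectraFormatError(f"{path}: not a trajectory CSV")
    data = []
    events = []
    for ln in lines[1:]:
        cells = ln.split(",")
        data.append([float(v) for v in cells[:6]])
        if len(cells) > 6 and cells[6]:
            for kind in cells[6].split(";"):
                events.append((float(cells[0]), kind))
    arr = np.array(data)
    return Trajectory(
        times=arr[:, 0],
        glucose=arr[:, 1],
        lactate=arr[:, 2],
        acetate=arr[:, 3],
        biomass=arr[:, 4],
        volume=arr[:, 5],
        events=events,
    )


def write_eventlog_csv(events, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_h,event,volume_L,trigger_analyte,predicted_value_gL\n")
        for e in events:
            fh.write(
                f"{_fmt(e.time)},{e.kind},{_fmt(e.volume)},"
                f"{e.trigger_analyte},{_fmt(e.predicted_value)}\n"
            )


# ---------------------------------------------------------------------------
# configuration documents


_INSTRUMENTS = {
    "filter19": filter19_instrument,
    "fullspectrum": fullspectrum_instrument,
    "probe": probe_instrument,
}

_STUDIES = {
    "homolactic": default_homolactic_study,
    "heterolactic": default_heterolactic_study,
}


def load_study_config(path: str, seed: int | None = None) -> StudyConfig:
    """Build a StudyConfig from a single YAML document.

    The document either names a default ``study`` (homolactic/heterolactic)
    and overrides scalars, or assembles organism/instrument/method from
    scratch.  ``seed`` (e.g. a CLI flag) overrides the document's seed.
    """
    try:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: invalid YAML: {e}")
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return _config_from_dict(doc, seed)
    except (KeyError, TypeError, ValueError) as e:
        if isinstance(e, ConfigError):
            raise
        raise ConfigError(f"{path}: {e}")


def _config_from_dict(doc: dict, seed: int | None) -> StudyConfig:
    if "study" in doc:
        name = doc["study"]
        if name not in _STUDIES:
            raise ConfigError(f"unknown study {name!r}; use one of {list(_STUDIES)}")
        config = _STUDIES[name]()
    else:
        organism = doc.get("organism", "hetero_cluster")
        if organism not in DEFAULT_PROFILES:
            raise ConfigError(f"unknown organism {organism!r}")
        instrument = doc.get("instrument", "probe")
        if instrument not in _INSTRUMENTS:
            raise ConfigError(f"unknown instrument {instrument!r}")
        config = StudyConfig(
            organism=DEFAULT_PROFILES[organism](),
            instrument=_INSTRUMENTS[instrument](),
            n_calibration=doc.get("n_calibration", 80),
            n_validation=doc.get("n_validation", 30),
            method=doc.get("method", "PLS"),
        )
    for key in ("n_calibration", "n_validation", "method", "max_factors",
                "md_limit", "retained_variance", "seed"):
        if key in doc:
            setattr(config, key, doc[key])
    if "organism" in doc and "study" in doc:
        if doc["organism"] not in DEFAULT_PROFILES:
            raise ConfigError(f"unknown organism {doc['organism']!r}")
        config.organism = DEFAULT_PROFILES[doc["organism"]]()
    if "kinetics" in doc:
        config.organism = replace(
            config.organism,
            kinetics=replace(config.organism.kinetics, **doc["kinetics"]),
        )
    if "noise" in doc:
        config.noise = AssayNoiseModel(**doc["noise"])
    if "hydro" in doc:
        config.hydro = HydrodynamicState(**doc["hydro"])
    if "pretreatment" in doc:
        config.pretreatment = PretreatmentSpec(**doc["pretreatment"])
    if seed is not None:
        config.seed = int(seed)
    config.__post_init__()
    return config


def config_hash(config: StudyConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return {k: _jsonable(v) for k, v in vars(obj).items() if not k.startswith("_")}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class RunManifest:
    """Audit record written next to every CLI output artifact."""

    config_hash: str
    seeds: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)
    version: str = __version__
    log: list = field(default_factory=list)

    def add(self, path: str) -> None:
        self.artifacts.append(str(path))

    def note(self, **kv) -> None:
        self.log.append(kv)

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seeds": self.seeds,
                    "artifacts": self.artifacts,
                    "version": self.version,
                    "log": self.log,
                },
                fh,
                indent=1,
            )
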
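"""Synthetic NIR spectra for fermentation broths.

Both instrument geometries reduce to an effective-path Beer-Lambert model:
absorbance is the path-weighted sum of Gaussian pure-component bands plus
the water background, a cell-scattering offset, a bubble-induced baseline
driven by stirring/aeration, and photometric noise, compressed smoothly
above the instrument's 4 AU linearity limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import BrothState, ReactorConfig

__all__ = [
    "InstrumentSpec",
    "HydrodynamicState",
    "Spectrum",
    "filter19_instrument",
    "fullspectrum_instrument",
    "probe_instrument",
    "pure_component_spectrum",
    "analyte_matrix",
    "generate_spectrum",
    "bubble_baseline",
    "saturate",
    "flow_cell_residence_time",
    "CHROMOPHORE_LIBRARIES",
    "ABSORBANCE_CAP",
]

ABSORBANCE_CAP = 4.0  # AU; linearity limit of the spectrometer
SATURATION_SCALE = 0.5  # AU; compression scale above the cap

COMPONENTS = ("glucose", "lactate", "acetate", "biomass_chromophore", "water")

# Band library: component -> list of (center nm, width nm, height AU L/(g mm)).
# Analyte bands sit in the CH-overtone (1625-1800 nm) and COOH/OH combination
# (2200-2300 nm) windows; water carries the dominant 1450 and 1940 nm bands
# plus an elevated 1850-2050 nm continuum.  Heights are per mm of path.
CHROMOPHORE_LIBRARIES: dict[str, dict[str, list[tuple[float, float, float]]]] = {
    "standard": {
        "glucose": [(1688.0, 24.0, 0.0048), (2272.0, 28.0, 0.0060)],
        "lactate": [(1726.0, 22.0, 0.0052), (2242.0, 26.0, 0.0046)],
        "acetate": [(1758.0, 20.0, 0.0046), (2296.0, 24.0, 0.0052)],
        "biomass_chromophore": [(1650.0, 55.0, 0.0024), (2210.0, 40.0, 0.0020)],
        "water": [
            (1450.0, 45.0, 1.5),
            (1940.0, 55.0, 3.0),
            (1950.0, 140.0, 0.8),  # broad continuum shoulder 1850-2050 nm
        ],
    },
    # Deliberately displaced analyte bands; used only to demonstrate the
    # failure mode of transferring a calibration across libraries.
    "shifted": {
        "glucose": [(1660.0, 24.0, 0.0048), (2230.0, 28.0, 0.0060)],
        "lactate": [(1700.0, 22.0, 0.0052), (2270.0, 26.0, 0.0046)],
        "acetate": [(1780.0, 20.0, 0.0046), (2255.0, 24.0, 0.0052)],
        "biomass_chromophore": [(1690.0, 55.0, 0.0024), (2250.0, 40.0, 0.0020)],
        "water": [
            (1450.0, 45.0, 1.5),
            (1940.0, 55.0, 3.0),
            (1950.0, 140.0, 0.8),
        ],
    },
}

WATER_CONTINUUM = 0.05  # AU/mm flat background across the NIR


@dataclass(frozen=True)
class InstrumentSpec:
    geometry: str  # filter19 | fullspectrum | probe
    wavelength_grid: np.ndarray  # nm, ascending
    optical_path: float  # mm (effective, double-pass included)
    mode: str  # reflectance | transflectance
    absorbance_cap: float = ABSORBANCE_CAP
    photometric_noise_sd: float = 0.001  # AU

    def __post_init__(self) -> None:
        grid = np.asarray(self.wavelength_grid, dtype=float)
        object.__setattr__(self, "wavelength_grid", grid)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.geometry == "filter19":
            if len(grid) != 19 or grid.min() < 1445 or grid.max() > 2348:
                raise ValueError("filter19 grid: 19 wavelengths in [1445, 2348] nm")
        elif self.geometry == "fullspectrum":
            if grid.min() < 700 or grid.max() > 2500:
                raise ValueError("fullspectrum grid must lie in [700, 2500] nm")
        elif self.geometry == "probe":
            if grid.min() < 700 or grid.max() > 1800:
                raise ValueError("probe grid must lie in [700, 1800] nm")
            if self.optical_path != 2.0:
                raise ValueError("probe optical path is fixed at 2 mm")
        else:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.mode not in ("reflectance", "transflectance"):
            raise ValueError(f"unknown mode {self.mode!r}")


def filter19_instrument(
    wavelengths: np.ndarray | None = None, photometric_noise_sd: float = 0.002
) -> InstrumentSpec:
    """19-filter reflectance analyzer on the external circulation loop.

    The filter positions are evenly spaced over 1445-2348 nm by default
    (only the range is documented for the real filter wheel) and can be
    overridden.  Effective path 0.4 mm: double pass through the 0.2 mm cell.
    """
    if wavelengths is None:
        wavelengths = np.linspace(1445.0, 2348.0, 19)
    return InstrumentSpec(
        geometry="filter19",
        wavelength_grid=np.asarray(wavelengths, dtype=float),
        optical_path=0.4,
        mode="reflectance",
        photometric_noise_sd=photometric_noise_sd,
    )


def fullspectrum_instrument(step: float = 2.0) -> InstrumentSpec:
    """Full-range scanning spectrometer, 700-2500 nm."""
    grid = np.arange(700.0, 2500.0 + step / 2, step)
    return InstrumentSpec(
        geometry="fullspectrum",
        wavelength_grid=grid,
        optical_path=2.0,
        mode="transflectance",
        photometric_noise_sd=0.001,
    )


def probe_instrument(step: float = 2.0) -> InstrumentSpec:
    """Transflectance immersion probe; fiber attenuation caps the grid at 1800 nm."""
    grid = np.arange(700.0, 1800.0 + step / 2, step)
    return InstrumentSpec(
        geometry="probe",
        wavelength_grid=grid,
        optical_path=2.0,
        mode="transflectance",
        photometric_noise_sd=0.001,
    )


@dataclass(frozen=True)
class HydrodynamicState:
    stirring: float = 120.0  # rpm
    airflow: float = 0.0  # L/min

    def __post_init__(self) -> None:
        # same admissible envelope as the reactor
        ReactorConfig(stirring=self.stirring, airflow=self.airflow)


@dataclass
class Spectrum:
    wavelength_grid: np.ndarray  # nm
    absorbance: np.ndarray  # AU
    instrument: str
    acquisition_time: float = 0.0  # h
    saturated: np.ndarray = field(default=None)  # channels with pre-cap A > 4

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelength_grid.shape != self.absorbance.shape:
            raise ValueError("grid and absorbance must have equal length")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.saturated is None:
            self.saturated = np.zeros(len(self.absorbance), dtype=bool)


def pure_component_spectrum(
    component: str, grid: np.ndarray, library: str = "standard"
) -> np.ndarray:
    """Extinction curve (AU L/g per mm path) of one component on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted ascending")
    try:
        bands = CHROMOPHORE_LIBRARIES[library][component]
    except KeyError:
        raise ValueError(f"unknown component or library: {component!r}/{library!r}")
    out = np.zeros_like(grid)
    for center, width, height in bands:
        out += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    if component == "water":
        out += WATER_CONTINUUM
    return out


def analyte_matrix(grid: np.ndarray, library: str = "standard") -> np.ndarray:
    """Columns = extinction curves of the four analytes (for identifiability)."""
    return np.column_stack(
        [
            pure_component_spectrum(c, grid, library)
            for c in ("glucose", "lactate", "acetate", "biomass_chromophore")
        ]
    )


def saturate(A: np.ndarray | float, cap: float = ABSORBANCE_CAP) -> np.ndarray | float:
    """Identity below the cap; smooth bounded compression above it.

    f(A) = cap + kappa tanh((A-cap)/kappa) for A > cap, which is C1 at the
    cap (unit slope) and bounded by cap + kappa.
    """
    A = np.asarray(A, dtype=float)
    out = np.where(
        A <= cap, A, cap + SATURATION_SCALE * np.tanh((A - cap) / SATURATION_SCALE)
    )
    return out if out.ndim else float(out)


def bubble_baseline(
    hydro: HydrodynamicState,
    X: float,
    grid: np.ndarray,
    k_rpm: float = 0.35,
    k_q: float = 0.30,
    X_att: float = 7.0,
) -> np.ndarray:
    """Additive baseline from the suspended-bubble population.

    Monotone in stirring and airflow with stirring dominant, attenuated in
    biomass (cells mask the bubble effect as their own scatter grows), with
    a smooth scattering-like 1/wavelength shape.
    """
    if X < 0:
        raise ValueError("biomass must be nonnegative")
    grid = np.asarray(grid, dtype=float)
    # bubble entrainment grows superlinearly with stirring (smaller bubbles
    # reach the probe gap); quadratic keeps it monotone and negligible at
    # the gentle constant stirring used for the on-line loop
    g = (hydro.stirring / 1000.0) ** 2
    h = hydro.airflow
    amplitude = k_rpm * g * (1.0 + k_q * h) * np.exp(-X / X_att)
    return amplitude * (1000.0 / grid)


def generate_spectrum(
    state: BrothState,
    instrument: InstrumentSpec,
    hydro: HydrodynamicState,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    scatter_coefficient: float = 0.010,
    library: str = "standard",
) -> Spectrum:
    """One acquisition: Beer-Lambert mixture + artifacts + photometric noise.

    Pass ``rng`` to draw noise from a shared seeded stream, or ``seed`` for
    a one-off acquisition; with neither, the spectrum is noise-free.
    """
    grid = instrument.wavelength_grid
    path = instrument.optical_path
    conc = {
        "glucose": state.glucose,
        "lactate": state.lactate,
        "acetate": state.acetate,
        "biomass_chromophore": state.biomass,
    }
    A = path * pure_component_spectrum("water", grid, library)
    for comp, c in conc.items():
        if c > 0:
            A = A + path * c * pure_component_spectrum(comp, grid, library)
    A = A + scatter_coefficient * state.biomass * (1000.0 / grid)
    A = A + bubble_baseline(hydro, state.biomass, grid)
    saturated = A > instrument.absorbance_cap
    A = saturate(A, instrument.absorbance_cap)
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    if rng is not None and instrument.photometric_noise_sd > 0:
        A = A + rng.normal(0.0, instrument.photometric_noise_sd, size=len(grid))
    return Spectrum(
        wavelength_grid=grid,
        absorbance=A,
        instrument=instrument.geometry,
        acquisition_time=state.time,
        saturated=saturated,
    )


def flow_cell_residence_time(volume_mm3: float, flow_ml_min: float) -> float:
    """Mean residence time (s) of broth in the circulation-loop flow cell."""
    if volume_mm3 <= 0 or flow_ml_min <= 0:
        raise ValueError("volume and flow rate must be positive")
    volume_ml = volume_mm3 / 1000.0
    return volume_ml / flow_ml_min * 60.0
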
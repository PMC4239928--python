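"""Fermentation kinetics, reactor mass balances and noisy reference assays.

Growth follows Monod kinetics with a product-inhibition ceiling, product
formation follows Luedeking-Piret split between lactate and acetate, and
substrate consumption accounts for growth yield plus maintenance.  A fixed
step 4th-order Runge-Kutta integrator is used so that runs are bitwise
reproducible; accuracy is guarded by a step-halving check in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "KineticParams",
    "BrothState",
    "ReactorConfig",
    "Trajectory",
    "AssayNoiseModel",
    "OrganismProfile",
    "SimulationError",
    "VolumeBoundsError",
    "simulate_batch",
    "simulate_open_loop",
    "reference_assay",
    "design_calibration_states",
    "homolactic_profile",
    "cluster_profile",
    "rod_profile",
    "sphere_profile",
    "DEFAULT_DT",
]

DEFAULT_DT = 0.05  # h

ANALYTES = ("glucose", "lactate", "acetate", "biomass")


class SimulationError(RuntimeError):
    """Integration produced a non-finite state (parameter blow-up)."""


class VolumeBoundsError(RuntimeError):
    """Culture volume left its admissible interval."""

    def __init__(self, time_h: float, volume: float, bounds: tuple[float, float]):
        self.time_h = time_h
        self.volume = volume
        super().__init__(
            f"volume {volume:.4g} L outside [{bounds[0]:g}, {bounds[1]:g}] L "
            f"at t = {time_h:.4g} h"
        )


@dataclass(frozen=True)
class KineticParams:
    """Phenomenological lactic-fermentation kinetics.

    Units: ``mu_max`` 1/h, ``Ks`` g/L, ``P_max`` g/L, ``Y_xs`` g biomass per
    g glucose, ``alpha`` g product per g biomass, ``beta`` g product per
    (g biomass h), ``maintenance`` g glucose per (g biomass h).
    ``acetate_fraction`` splits total product between lactate and acetate;
    0 means homolactic.
    """

    mu_max: float
    Ks: float
    P_max: float
    Y_xs: float
    alpha: float
    beta: float
    acetate_fraction: float = 0.0
    maintenance: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_max", "Ks", "P_max", "Y_xs", "alpha", "beta", "maintenance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.acetate_fraction <= 1.0:
            raise ValueError("acetate_fraction must lie in [0, 1]")
        if self.Y_xs > 1.0:
            raise ValueError("Y_xs must not exceed 1 g/g")


@dataclass(frozen=True)
class BrothState:
    """Broth composition (g/L), volume (L) and time (h) at one instant."""

    glucose: float
    lactate: float
    acetate: float
    biomass: float
    volume: float = 2.0
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("glucose", "lactate", "acetate", "biomass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be nonnegative")
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    def concentrations(self) -> np.ndarray:
        return np.array([self.glucose, self.lactate, self.acetate, self.biomass])


@dataclass(frozen=True)
class ReactorConfig:
    mode: str = "batch"  # batch | fed | continuous
    feed_concentration: float = 100.0  # g/L glucose in feed
    working_volume: float = 2.0  # L
    stirring: float = 120.0  # rpm
    airflow: float = 0.0  # L/min

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "fed", "continuous"):
            raise ValueError(f"unknown reactor mode {self.mode!r}")
        if not 0.0 <= self.stirring <= 1000.0:
            raise ValueError("stirring must lie in [0, 1000] rpm")
        if not 0.0 <= self.airflow <= 1.5:
            raise ValueError("airflow must lie in [0, 1.5] L/min")
        if self.working_volume <= 0:
            raise ValueError("working_volume must be positive")


@dataclass
class Trajectory:
    """Time series of broth states at fixed step, plus event annotations."""

    times: np.ndarray  # h, strictly increasing
    glucose: np.ndarray
    lactate: np.ndarray
    acetate: np.ndarray
    biomass: np.ndarray
    volume: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.times)

    def state(self, i: int) -> BrothState:
        return BrothState(
            glucose=float(self.glucose[i]),
            lactate=float(self.lactate[i]),
            acetate=float(self.acetate[i]),
            biomass=float(self.biomass[i]),
            volume=float(self.volume[i]),
            time=float(self.times[i]),
        )

    def states(self) -> list[BrothState]:
        return [self.state(i) for i in range(len(self))]


@dataclass
class AssayNoiseModel:
    """Additive zero-mean Gaussian reference-assay noise, truncated at 0.

    Dry-weight biomass is deliberately the noisiest assay relative to its
    attainable range; HPLC analytes share one absolute level.
    """

    sd_glucose: float = 1.0
    sd_lactate: float = 1.0
    sd_acetate: float = 1.0
    sd_biomass: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_glucose", "sd_lactate", "sd_acetate", "sd_biomass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        self._rng = np.random.default_rng(self.seed)

    def sds(self) -> np.ndarray:
        return np.array(
            [self.sd_glucose, self.sd_lactate, self.sd_acetate, self.sd_biomass]
        )

    def reset(self) -> None:
        self._rng = np.random.default_rng(self.seed)


@dataclass(frozen=True)
class OrganismProfile:
    """An organism's kinetics, optical scatter, and attainable ranges.

    ``chromophore_set`` names the shared pure-component band library; the
    three default heterolactic profiles reference the same library, encoding
    the observed absence of shape-specific spectral features.
    """

    name: str
    shape: str  # cluster | rod | sphere
    kinetics: KineticParams
    scatter_coefficient: float  # AU L/g at the 1000 nm reference
    chromophore_set: str = "standard"
    analyte_ranges: dict = field(default_factory=dict)  # analyte -> (lo, hi) g/L
    initial_glucose: float = 46.0
    initial_biomass: float = 0.25
    batch_horizon: float = 30.0  # h, long enough to exhaust glucose
    s0_jitter: tuple[float, float] = (0.85, 1.2)  # initial-glucose spread

    def __post_init__(self) -> None:
        if self.shape not in ("cluster", "rod", "sphere"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def initial_state(self, volume: float = 2.0) -> BrothState:
        return BrothState(
            glucose=self.initial_glucose,
            lactate=0.0,
            acetate=0.0,
            biomass=self.initial_biomass,
            volume=volume,
        )


def homolactic_profile() -> OrganismProfile:
    """Anaerobic homolactic fermenter on 100 g/L glucose medium."""
    return OrganismProfile(
        name="homolactic",
        shape="rod",
        kinetics=KineticParams(
            mu_max=0.42,
            Ks=0.5,
            P_max=105.0,
            Y_xs=0.15,
            alpha=5.5,
            beta=0.3,
            acetate_fraction=0.0,
            maintenance=0.02,
        ),
        scatter_coefficient=0.010,
        analyte_ranges={
            "glucose": (0.0, 87.0),
            "lactate": (0.0, 98.0),
            "acetate": (0.0, 0.0),
            "biomass": (0.0, 16.0),
        },
        initial_glucose=100.0,
        initial_biomass=0.2,
        batch_horizon=40.0,
        s0_jitter=(0.8, 1.0),  # medium glucose never exceeds 100 g/L
    )


_HETERO_RANGES = {
    "glucose": (0.0, 58.0),
    "lactate": (0.0, 23.0),
    "acetate": (0.0, 19.0),
    "biomass": (0.0, 16.0),
}


def cluster_profile() -> OrganismProfile:
    """Aerobic heterolactic fermenter, cluster-forming cells, 46 g/L glucose."""
    return OrganismProfile(
        name="hetero_cluster",
        shape="cluster",
        kinetics=KineticParams(
            mu_max=0.50,
            Ks=0.4,
            P_max=40.0,
            Y_xs=0.35,
            alpha=1.9,
            beta=0.14,
            acetate_fraction=0.45,
            maintenance=0.02,
        ),
        scatter_coefficient=0.010,
        analyte_ranges=dict(_HETERO_RANGES),
        initial_glucose=46.0,
        initial_biomass=0.25,
        batch_horizon=30.0,
    )


def rod_profile() -> OrganismProfile:
    """Rod-shaped heterolactic fermenter sharing the cluster chromophores."""
    base = cluster_profile()
    return replace(
        base,
        name="hetero_rod",
        shape="rod",
        kinetics=replace(base.kinetics, mu_max=0.55, alpha=1.8, beta=0.12),
        scatter_coefficient=0.011,
        analyte_ranges={
            "glucose": (0.0, 56.0),
            "lactate": (0.0, 22.0),
            "acetate": (0.0, 15.0),
            "biomass": (0.0, 16.0),
        },
    )


def sphere_profile() -> OrganismProfile:
    """Spherical heterolactic fermenter sharing the cluster chromophores."""
    base = cluster_profile()
    return replace(
        base,
        name="hetero_sphere",
        shape="sphere",
        kinetics=replace(base.kinetics, mu_max=0.45, alpha=2.0, beta=0.13),
        scatter_coefficient=0.0095,
        analyte_ranges={
            "glucose": (0.0, 50.0),
            "lactate": (0.0, 24.0),
            "acetate": (0.0, 8.0),
            "biomass": (0.0, 12.0),
        },
    )


DEFAULT_PROFILES = {
    "homolactic": homolactic_profile,
    "hetero_cluster": cluster_profile,
    "hetero_rod": rod_profile,
    "hetero_sphere": sphere_profile,
}


def reaction_rates(
    S: float, PL: float, PA: float, X: float, k: KineticParams
) -> tuple[float, float, float, float]:
    """Specific reaction terms (dS, dPL, dPA, dX)/dt for a closed broth.

    Non-growth production and maintenance are gated by the same Monod
    factor as growth so that everything stops when glucose is exhausted.
    """
    mon = S / (k.Ks + S) if S > 0 else 0.0
    inhib = max(0.0, 1.0 - PL / k.P_max) if k.P_max > 0 else 1.0
    mu = k.mu_max * mon * inhib
    # non-growth production is gated by substrate availability and product
    # inhibition alike, so the broth comes to rest at exhaustion or at P_max
    qp = (k.alpha * mu + k.beta * mon * inhib) * X
    dX = mu * X
    dS = -(mu / k.Y_xs) * X - k.maintenance * mon * X
    dPL = (1.0 - k.acetate_fraction) * qp
    dPA = k.acetate_fraction * qp
    return dS, dPL, dPA, dX


def _derivatives(
    t: float,
    y: np.ndarray,
    k: KineticParams,
    feed_rate: Callable[[float], float] | None,
    withdraw_rate: Callable[[float], float] | None,
    feed_conc: float,
) -> np.ndarray:
    S, PL, PA, X, V = y
    dS, dPL, dPA, dX = reaction_rates(S, PL, PA, X, k)
    f_in = feed_rate(t) if feed_rate is not None else 0.0
    f_out = withdraw_rate(t) if withdraw_rate is not None else 0.0
    dV = f_in - f_out
    if f_in > 0.0 and V > 0.0:
        d = f_in / V
        dS += d * (feed_conc - S)
        dPL -= d * PL
        dPA -= d * PA
        dX -= d * X
    return np.array([dS, dPL, dPA, dX, dV])


def _rk4_step(t: float, y: np.ndarray, dt: float, deriv) -> np.ndarray:
    k1 = deriv(t, y)
    k2 = deriv(t + dt / 2.0, y + dt / 2.0 * k1)
    k3 = deriv(t + dt / 2.0, y + dt / 2.0 * k2)
    k4 = deriv(t + dt, y + dt * k3)
    out = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    # concentrations and volume cannot go negative
    out[:4] = np.maximum(out[:4], 0.0)
    return out


def simulate_open_loop(
    kinetics: KineticParams,
    init: BrothState,
    reactor: ReactorConfig,
    feed_profile: Callable[[float], float] | None = None,
    withdrawal_profile: Callable[[float], float] | None = None,
    horizon: float = 24.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    v_min: float = 0.1,
) -> Trajectory:
    """Integrate the broth under time-varying feed/withdrawal flows (L/h).

    With both profiles absent or zero this reduces exactly to a batch run.
    ``seed`` is accepted for interface symmetry; the dynamics themselves are
    deterministic.
    """
    if horizon <= 0 or dt <= 0:
        raise ValueError("horizon and dt must be positive")
    n = int(round(horizon / dt))
    deriv = lambda t, y: _derivatives(
        t, y, kinetics, feed_profile, withdrawal_profile, reactor.feed_concentration
    )
    y = np.array(
        [init.glucose, init.lactate, init.acetate, init.biomass, init.volume]
    )
    times = init.time + dt * np.arange(n + 1)
    out = np.empty((n + 1, 5))
    out[0] = y
    bounds = (v_min, reactor.working_volume)
    for i in range(n):
        y = _rk4_step(times[i], y, dt, deriv)
        if not np.all(np.isfinite(y)):
            raise SimulationError(
                f"non-finite state at t = {times[i + 1]:.4g} h; "
                "check kinetic parameters"
            )
        if not bounds[0] - 1e-9 <= y[4] <= bounds[1] + 1e-9:
            raise VolumeBoundsError(float(times[i + 1]), float(y[4]), bounds)
        out[i + 1] = y
    return Trajectory(
        times=times,
        glucose=out[:, 0],
        lactate=out[:, 1],
        acetate=out[:, 2],
        biomass=out[:, 3],
        volume=out[:, 4],
    )


def simulate_batch(
    kinetics: KineticParams,
    init: BrothState,
    horizon: float = 24.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
) -> Trajectory:
    """Closed-vessel fermentation: the open-loop integrator with zero flows."""
    reactor = ReactorConfig(
        mode="batch", working_volume=max(init.volume, 2.0), stirring=120.0
    )
    return simulate_open_loop(
        kinetics, init, reactor, None, None, horizon=horizon, dt=dt, seed=seed
    )


def reference_assay(
    state: BrothState, noise: AssayNoiseModel
) -> tuple[float, float, float, float]:
    """Off-line measurement of (glucose, lactate, acetate, biomass) in g/L.

    Unbiased additive Gaussian noise per analyte, truncated at zero.
    Repeated calls advance the model's seeded stream.
    """
    true = state.concentrations()
    noisy = true + noise._rng.normal(0.0, 1.0, size=4) * noise.sds()
    noisy = np.maximum(noisy, 0.0)
    return tuple(float(v) for v in noisy)


def _jittered_kinetics(k: KineticParams, rng: np.random.Generator) -> KineticParams:
    j = lambda: rng.uniform(0.8, 1.2)
    return replace(
        k,
        mu_max=k.mu_max * j(),
        Ks=k.Ks * j(),
        alpha=k.alpha * j(),
        beta=k.beta * j(),
        Y_xs=min(k.Y_xs * j(), 1.0),
    )


def design_calibration_states(
    n: int,
    organism: OrganismProfile,
    seed: int = 0,
    n_trajectories: int = 12,
    dt: float = DEFAULT_DT,
) -> list[BrothState]:
    """Sample calibration states from simulated batches, not uniform draws.

    ``n_trajectories`` batches are run with +/-20% jitter on the kinetic
    parameters and a stratified +/-20% spread on initial glucose, and states
    are taken at equally spaced time points of each run.  This preserves the
    substrate-product correlation a real fermentation data set carries.
    A warning is recorded when an analyte's sampled span covers less than
    90% of the organism's attainable range.
    """
    if n < 10:
        raise ValueError("need at least 10 calibration states")
    if not 9 <= n_trajectories <= 16:
        raise ValueError("n_trajectories must lie in [9, 16]")
    rng = np.random.default_rng(seed)
    # stratified initial-glucose multipliers guarantee the top of the range
    s0_mult = np.linspace(*organism.s0_jitter, n_trajectories)
    rng.shuffle(s0_mult)

    counts = np.full(n_trajectories, n // n_trajectories)
    counts[: n % n_trajectories] += 1

    states: list[BrothState] = []
    for i in range(n_trajectories):
        if counts[i] == 0:
            continue
        kin = _jittered_kinetics(organism.kinetics, rng)
        init = BrothState(
            glucose=organism.initial_glucose * s0_mult[i],
            lactate=0.0,
            acetate=0.0,
            biomass=organism.initial_biomass,
            volume=2.0,
        )
        traj = simulate_batch(kin, init, horizon=organism.batch_horizon, dt=dt)
        if counts[i] == 1:
            # stagger lone picks across the fermentation course so tiny
            # designs still span early, mid and late broth compositions
            idx = np.array([round((i + 0.5) / n_trajectories * (len(traj) - 1))])
        else:
            idx = np.linspace(0, len(traj) - 1, int(counts[i])).round().astype(int)
        states.extend(traj.state(int(j)) for j in idx)

    _check_coverage(states, organism)
    return states


def _check_coverage(states: Sequence[BrothState], organism: OrganismProfile) -> None:
    arr = np.array([s.concentrations() for s in states])
    for j, analyte in enumerate(ANALYTES):
        lo, hi = organism.analyte_ranges.get(analyte, (0.0, 0.0))
        span = hi - lo
        if span <= 0:
            continue
        covered = arr[:, j].max() - arr[:, j].min()
        if covered < 0.9 * span:
            warnings.warn(
                f"calibration design covers only {covered:.1f} of the "
                f"{span:.1f} g/L {analyte} range for {organism.name}",
                stacklevel=2,
            )
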
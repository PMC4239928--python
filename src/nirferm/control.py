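"""Closed-loop fermentation strategies driven by NIR-predicted values.

The controller sees only concentrations predicted from synthetic spectra of
the true broth state (plus the reactor's weight/volume signal); the true
composition is never on its information set.  Five strategies are
implemented: repeated batch (RBC), repeated fed-batch (RFBC), turbidostat,
chemostat, and RBC with product removal by cell-retaining microfiltration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .chemometrics import CalibrationModel, predict
from .pipeline import StudyConfig
from .simulate import (
    BrothState,
    Trajectory,
    VolumeBoundsError,
    reaction_rates,
    DEFAULT_DT,
)
from .spectra import generate_spectrum

__all__ = [
    "RBCStrategy",
    "RFBCStrategy",
    "TurbidostatStrategy",
    "ChemostatStrategy",
    "RBCMicrofiltrationStrategy",
    "Event",
    "EventLog",
    "ControlError",
    "ControlTimeoutError",
    "ClosedLoopResult",
    "PerfectSensor",
    "run_closed_loop",
    "steady_state_detect",
]

RAMP_FLOW = 20.0  # L/h for discharge/refill: a fast ramp, < 0.1 h per 1.5 L


class ControlError(RuntimeError):
    pass


class ControlTimeoutError(ControlError):
    """A strategy phase could not complete (e.g. unreachable threshold)."""


@dataclass(frozen=True)
class Event:
    time: float  # h
    kind: str
    volume: float  # L
    trigger_analyte: str = ""
    predicted_value: float = float("nan")  # g/L


EventLog = list  # list[Event], chronologically ordered


@dataclass
class RBCStrategy:
    """Repeated batch: harvest on predicted lactate, then refill."""

    lactate_trigger: float  # g/L
    V_low: float = 1.0  # L
    V_work: float = 2.0  # L
    kind: str = "rbc"
    reads = ("lactate",)

    def __post_init__(self) -> None:
        if self.lactate_trigger <= 0:
            raise ValueError("lactate_trigger must be positive")
        if not 0 < self.V_low < self.V_work:
            raise ValueError("need 0 < V_low < V_work")


@dataclass
class RFBCStrategy:
    """Repeated fed-batch with preset initial/final volume and feed rate.

    NIR only monitors; the cycle itself is volume-programmed.  End-of-cycle
    states can be read off the event log to examine cycle convergence.
    """

    V0: float = 1.0  # L
    Vf: float = 2.0  # L
    feed_rate: float = 0.1  # L/h
    kind: str = "rfbc"
    reads: tuple = ()

    def __post_init__(self) -> None:
        if not 0 < self.V0 < self.Vf:
            raise ValueError("need 0 < V0 < Vf")
        if self.feed_rate <= 0:
            raise ValueError("feed_rate must be positive")


@dataclass
class TurbidostatStrategy:
    """Constant-volume continuous culture holding predicted biomass."""

    X_set: float  # g/L
    X_set2: float | None = None  # optional second setpoint
    switch_time: float | None = None  # h; when X_set2 takes over
    Kp: float = 0.10  # (1/h)/(g/L)
    Ki: float = 0.06
    ema: float = 0.35  # smoothing of the noisy predicted error
    D_max: float = 0.8  # 1/h
    kind: str = "turbidostat"
    reads = ("biomass",)

    def __post_init__(self) -> None:
        if self.X_set <= 0:
            raise ValueError("X_set must be positive")

    def setpoint(self, t: float) -> float:
        if self.X_set2 is not None and self.switch_time is not None:
            if t >= self.switch_time:
                return self.X_set2
        return self.X_set


@dataclass
class ChemostatStrategy:
    """Constant-volume continuous culture holding predicted glucose."""

    S_set: float  # g/L
    Kp: float = 0.04
    Ki: float = 0.04
    ema: float = 0.35  # smoothing of the noisy predicted error
    D_max: float = 0.8  # 1/h
    kind: str = "chemostat"
    reads = ("glucose",)

    def __post_init__(self) -> None:
        if self.S_set <= 0:
            raise ValueError("S_set must be positive")


@dataclass
class RBCMicrofiltrationStrategy:
    """Fully automated RBC with product removal by microfiltration.

    Cycle: predicted lactate >= B starts filtration (cells retained,
    product-rich permeate removed, biomass concentrates); predicted biomass
    >= A discharges broth down to volume D; refill with fresh medium to the
    working level C; idle until lactate crosses B again.
    """

    A: float  # g/L biomass threshold
    B: float  # g/L lactate threshold
    C: float = 2.0  # L working level
    D: float = 1.0  # L residual volume after discharge
    permeate_flow: float = 1.0  # L/h during filtration
    max_filtration_h: float = 30.0  # timeout for an unreachable A
    kind: str = "rbc_microfiltration"
    reads = ("lactate", "biomass")

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.D < self.C:
            raise ValueError("need 0 < D < C")


@dataclass(frozen=True)
class PerfectSensor:
    """Diagnostic stand-in for a calibration model: predicts exactly.

    Used to examine the control law in isolation (sensor error zero); the
    production path always senses through spectra and real models.
    """

    analyte: str


@dataclass
class ClosedLoopResult:
    trajectory: Trajectory
    events: EventLog
    control_times: np.ndarray  # h
    predicted: dict  # analyte -> np.ndarray aligned with control_times
    dilution: np.ndarray  # applied D = F_in/V at each control step, 1/h


class _LoopState:
    """Mutable controller bookkeeping between control steps."""

    def __init__(self) -> None:
        self.phase = "idle"
        self.integral = 0.0
        self.err_filtered: float | None = None
        self.f_in = 0.0
        self.f_out = 0.0
        self.f_perm = 0.0
        self.phase_started = 0.0


def _required_models(strategy) -> tuple:
    return tuple(strategy.reads)


def run_closed_loop(
    config: StudyConfig,
    models: dict[str, CalibrationModel],
    strategy,
    horizon: float = 24.0,
    control_dt: float = 0.25,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    init: BrothState | None = None,
    true_state_transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ClosedLoopResult:
    """Simulate a NIR-feedback run: spectrum -> prediction -> actuation.

    Analyte-triggered decisions happen only at NIR sampling times
    (``control_dt``); volume watchers (discharge/refill completion) act on
    the continuous weight signal.  ``true_state_transform`` is a test hook
    applied only to the *recorded* true trajectory, proving that actuation
    depends on predictions alone.
    """
    for analyte in _required_models(strategy):
        if analyte not in models:
            raise ControlError(f"strategy reads {analyte!r} but no model covers it")
    if control_dt < dt:
        raise ControlError("control_dt must be at least the integration step")

    kin = config.organism.kinetics
    feed_conc = config.organism.initial_glucose
    v_work = getattr(strategy, "V_work", None) or getattr(strategy, "C", None) or 2.0
    if strategy.kind == "rfbc":
        v_work = strategy.Vf
    v_floor = min(
        getattr(strategy, "V_low", v_work), getattr(strategy, "D", v_work)
    )
    if strategy.kind in ("turbidostat", "chemostat"):
        v_floor = 0.5 * v_work
    elif strategy.kind == "rfbc":
        v_floor = strategy.V0
    if init is None:
        init = config.organism.initial_state(
            volume=strategy.V0 if strategy.kind == "rfbc" else v_work
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    steps_per_control = int(round(control_dt / dt))
    n_control = int(round(horizon / control_dt))
    n_steps = n_control * steps_per_control

    y = np.array([init.glucose, init.lactate, init.acetate, init.biomass, init.volume])
    times = dt * np.arange(n_steps + 1)
    record = np.empty((n_steps + 1, 5))
    record[0] = y
    events: EventLog = []
    loop = _LoopState()
    control_times = []
    predicted: dict[str, list] = {a: [] for a in models}
    dilution = []

    for i in range(n_steps):
        t = times[i]
        if i % steps_per_control == 0:
            state = BrothState(
                glucose=float(y[0]),
                lactate=float(y[1]),
                acetate=float(y[2]),
                biomass=float(y[3]),
                volume=float(y[4]),
                time=float(t),
            )
            spectrum = generate_spectrum(
                state,
                config.instrument,
                config.hydro,
                rng=rng,
                scatter_coefficient=config.organism.scatter_coefficient,
                library=config.organism.chromophore_set,
            )
            truth = dict(zip(("glucose", "lactate", "acetate", "biomass"), y[:4]))
            pred = {
                a: (
                    float(truth[a])
                    if isinstance(m, PerfectSensor)
                    else max(0.0, float(predict(m, spectrum).values[0]))
                )
                for a, m in models.items()
            }
            for a in models:
                predicted[a].append(pred[a])
            control_times.append(float(t))
            _decide(strategy, loop, pred, float(y[4]), float(t), control_dt, events)
            dilution.append(loop.f_in / y[4] if y[4] > 0 else 0.0)

        y = _advance(y, t, dt, kin, loop, feed_conc)
        if not np.all(np.isfinite(y)):
            raise ControlError(f"non-finite state at t = {t + dt:.3g} h")
        _volume_watch(strategy, loop, y, float(times[i + 1]), events)
        if not v_floor - 1e-6 <= y[4] <= v_work + 1e-6:
            raise VolumeBoundsError(float(times[i + 1]), float(y[4]), (v_floor, v_work))
        record[i + 1] = y

    if true_state_transform is not None:
        record[:, :4] = true_state_transform(record[:, :4])
    traj = Trajectory(
        times=times,
        glucose=record[:, 0],
        lactate=record[:, 1],
        acetate=record[:, 2],
        biomass=record[:, 3],
        volume=record[:, 4],
        events=[(e.time, e.kind) for e in events],
    )
    return ClosedLoopResult(
        trajectory=traj,
        events=events,
        control_times=np.asarray(control_times),
        predicted={a: np.asarray(v) for a, v in predicted.items()},
        dilution=np.asarray(dilution),
    )


def _advance(y, t, dt, kin, loop: _LoopState, feed_conc):
    """One RK4 step including feed, withdrawal and cell-retaining filtration."""

    def deriv(_t, yy):
        S, PL, PA, X, V = yy
        dS, dPL, dPA, dX = reaction_rates(S, PL, PA, X, kin)
        dV = loop.f_in - loop.f_out - loop.f_perm
        if loop.f_in > 0 and V > 0:
            d = loop.f_in / V
            dS += d * (feed_conc - S)
            dPL -= d * PL
            dPA -= d * PA
            dX -= d * X
        if loop.f_perm > 0 and V > 0:
            # permeate carries solutes at broth concentration, cells stay
            dX += loop.f_perm * X / V
        return np.array([dS, dPL, dPA, dX, dV])

    k1 = deriv(t, y)
    k2 = deriv(t + dt / 2, y + dt / 2 * k1)
    k3 = deriv(t + dt / 2, y + dt / 2 * k2)
    k4 = deriv(t + dt, y + dt * k3)
    out = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    out[:4] = np.maximum(out[:4], 0.0)
    return out


def _decide(strategy, loop, pred, V, t, control_dt, events):
    kind = strategy.kind
    if kind == "rbc":
        if loop.phase == "idle" and pred["lactate"] >= strategy.lactate_trigger:
            loop.phase = "harvest"
            loop.f_out = RAMP_FLOW
            events.append(Event(t, "harvest", V, "lactate", pred["lactate"]))
    elif kind == "rfbc":
        if loop.phase == "idle":
            loop.phase = "feeding"
            loop.f_in = strategy.feed_rate
            events.append(Event(t, "feed_start", V))
    elif kind in ("turbidostat", "chemostat"):
        if kind == "turbidostat":
            err = pred["biomass"] - strategy.setpoint(t)
        else:
            err = strategy.S_set - pred["glucose"]
        if loop.err_filtered is None:
            loop.err_filtered = err
        else:
            loop.err_filtered += strategy.ema * (err - loop.err_filtered)
        err = loop.err_filtered
        # anti-windup: the integral term alone must stay inside the
        # realisable dilution range [0, D_max]
        loop.integral = float(
            np.clip(loop.integral + err * control_dt, 0.0,
                    strategy.D_max / strategy.Ki)
        )
        D = float(np.clip(strategy.Kp * err + strategy.Ki * loop.integral,
                          0.0, strategy.D_max))
        loop.f_in = D * V
        loop.f_out = loop.f_in  # weight control keeps the volume constant
    elif kind == "rbc_microfiltration":
        if loop.phase == "idle" and pred["lactate"] >= strategy.B:
            loop.phase = "filtering"
            loop.phase_started = t
            loop.f_perm = strategy.permeate_flow
            events.append(Event(t, "filtration_start", V, "lactate", pred["lactate"]))
        elif loop.phase == "filtering":
            if pred["biomass"] >= strategy.A:
                loop.f_perm = 0.0
                loop.phase = "discharging"
                events.append(
                    Event(t, "filtration_stop", V, "biomass", pred["biomass"])
                )
                events.append(Event(t, "discharge", V, "biomass", pred["biomass"]))
                loop.f_out = RAMP_FLOW
            elif t - loop.phase_started > strategy.max_filtration_h:
                raise ControlTimeoutError(
                    f"biomass threshold A={strategy.A} g/L not reached after "
                    f"{strategy.max_filtration_h} h of filtration; "
                    "thresholds are inconsistent"
                )
    else:
        raise ControlError(f"unknown strategy kind {kind!r}")


def _volume_watch(strategy, loop, y, t, events):
    """Continuous weight-signal actions: stop discharges/refills on target."""
    kind = strategy.kind
    V = y[4]
    if kind == "rbc":
        if loop.phase == "harvest" and V <= strategy.V_low:
            y[4] = strategy.V_low
            loop.f_out = 0.0
            loop.f_in = RAMP_FLOW
            loop.phase = "refill"
        elif loop.phase == "refill" and V >= strategy.V_work:
            y[4] = strategy.V_work
            loop.f_in = 0.0
            loop.phase = "idle"
            events.append(Event(t, "refill", strategy.V_work))
    elif kind == "rfbc":
        if loop.phase == "feeding" and V >= strategy.Vf:
            y[4] = strategy.Vf
            loop.f_in = 0.0
            loop.phase = "draining"
            events.append(Event(t, "feed_stop", strategy.Vf))
            loop.f_out = RAMP_FLOW
        elif loop.phase == "draining" and V <= strategy.V0:
            y[4] = strategy.V0
            loop.f_out = 0.0
            loop.phase = "idle"
            events.append(Event(t, "discharge", strategy.V0))
    elif kind == "rbc_microfiltration":
        if loop.phase == "filtering" and V <= strategy.D:
            raise ControlTimeoutError(
                f"volume hit the residual level D={strategy.D} L during "
                "filtration before the biomass threshold was reached"
            )
        if loop.phase == "discharging" and V <= strategy.D:
            y[4] = strategy.D
            loop.f_out = 0.0
            loop.f_in = RAMP_FLOW
            loop.phase = "refilling"
        elif loop.phase == "refilling" and V >= strategy.C:
            y[4] = strategy.C
            loop.f_in = 0.0
            loop.phase = "idle"
            events.append(Event(t, "refill", strategy.C))


def steady_state_detect(
    traj: Trajectory,
    residence_time: float,
    tolerance: float = 0.05,
    monitored: tuple = ("glucose", "lactate", "acetate", "biomass"),
    abs_floor: float = 0.5,
) -> float | None:
    """Earliest time from which every monitored concentration stays within
    +/- tolerance of its window mean over two residence times, or None.

    The tolerance is relative to the window mean with an absolute floor so
    that identically-zero channels count as steady.
    """
    if residence_time <= 0:
        raise ValueError("residence_time must be positive")
    window = 2.0 * residence_time
    t = traj.times
    if t[-1] - t[0] < window:
        raise ValueError("trajectory shorter than two residence times")
    series = [getattr(traj, name) for name in monitored]
    for i in range(len(t)):
        if t[i] + window > t[-1] + 1e-9:
            break
        j = int(np.searchsorted(t, t[i] + window, side="right"))
        ok = True
        for x in series:
            w = x[i:j]
            m = w.mean()
            if np.max(np.abs(w - m)) > tolerance * max(abs(m), abs_floor):
                ok = False
                break
        if ok:
            return float(t[i])
    return None
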
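"""Closed-loop pneumatic pressure control driven by decoded motor intent.

The controller realizes a simple bang-bang law around a safe pressure band:
when the decoder reports "close hand" (``s_t = 1``) and the current pressure
sits inside ``(P_min, P_max)``, the pressurizing pump inflates the glove by
``delta_P`` per step; once pressure reaches ``P_max`` the vacuum pump pulls
it back down, so a sustained intent holds the glove in a regulation band
just under ``P_max``.  At rest (``s_t = 0``) the pumps stay off (or the
system vents, configurable).  A safety layer runs after the intent branch:
pressure strictly above ``P_max`` triggers the vent valve and an absorbing
stop that only an explicit :func:`reset` clears; pressure below ``P_min``
opens the vent to stabilize back toward ambient.

The physical plant (pumps, valves, tubing, sensor) is replaced by a
first-order simulator: each commanded step changes pressure by ``gain``
kPa, a leak pulls toward ambient, venting relaxes exponentially toward
ambient, and the sensor adds Gaussian noise.  The control step is one
decoder epoch hop (0.25 s); pressure units are kPa throughout the
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ControllerConfig", "ControllerState", "PumpCommand", "PlantParams",
    "control_step", "plant_step", "simulate_session", "reset",
]


@dataclass(frozen=True)
class ControllerConfig:
    P_max: float = 50.0          # kPa, pre-defined upper limit
    P_min: float = 0.0           # kPa, initialized from first sensor reading
    delta_P: float = 5.0         # kPa commanded per step
    threshold: float = 0.5       # decode threshold on P(fist)
    rest_behavior: str = "hold"  # "hold" (pumps off) or "vent"

    def __post_init__(self) -> None:
        if not self.P_min < self.P_max:
            raise ValueError("require P_min < P_max")
        if self.delta_P <= 0:
            raise ValueError("delta_P must be positive")
        if self.rest_behavior not in ("hold", "vent"):
            raise ValueError("rest_behavior must be 'hold' or 'vent'")


@dataclass(frozen=True)
class PumpCommand:
    pump1_pressurize: bool = False
    pump2_vacuum: bool = False
    vent_valve: bool = False

    def __post_init__(self) -> None:
        if self.pump1_pressurize and self.pump2_vacuum:
            raise ValueError("pressurize and vacuum pumps are mutually "
                             "exclusive within a step")


ALL_OFF = PumpCommand()

MODES = ("idle", "pressurizing", "vacuuming", "vented_stopped")


@dataclass(frozen=True)
class ControllerState:
    P_t: float                   # current (sensed) pressure, kPa
    mode: str = "idle"
    last_command: PumpCommand = ALL_OFF

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass(frozen=True)
class PlantParams:
    gain: float = 2.0            # kPa per commanded pump step
    leak_rate: float = 0.05      # kPa/step toward ambient
    sensor_noise_sd: float = 0.0 # kPa
    ambient_P: float = 0.0       # kPa (gauge)
    vent_retain: float = 0.5     # fraction of overpressure kept per vent step

    def __post_init__(self) -> None:
        if self.leak_rate < 0:
            raise ValueError("leak_rate must be >= 0")
        if not (0 <= self.vent_retain < 1):
            raise ValueError("vent_retain must lie in [0, 1)")


def control_step(state: ControllerState, s_t: int,
                 config: ControllerConfig) -> tuple[PumpCommand, ControllerState]:
    """One discrete control step.

    The intent branch runs first (pressurize below ``P_max``, vacuum at or
    above it, hold/vent at rest), then the safety check overrides: pressure
    strictly above ``P_max`` vents and stops (absorbing until reset);
    pressure below ``P_min`` opens the vent to stabilize.
    """
    if s_t not in (0, 1):
        raise ValueError(f"s_t must be 0 or 1, got {s_t!r}")
    if state.mode == "vented_stopped":
        return ALL_OFF, state

    p = state.P_t
    if s_t == 1:
        # lower bound inclusive: P_min is the initial sensor reading, so a
        # strict comparison would deadlock the loop in its starting state
        if config.P_min <= p < config.P_max:
            command = PumpCommand(pump1_pressurize=True)
            mode = "pressurizing"
        elif p >= config.P_max:
            command = PumpCommand(pump2_vacuum=True)
            mode = "vacuuming"
        else:  # p <= P_min: no intent branch applies; safety handles it
            command = ALL_OFF
            mode = "idle"
    else:
        command = (PumpCommand(vent_valve=True)
                   if config.rest_behavior == "vent" else ALL_OFF)
        mode = "idle"

    # safety check, layered after the intent branch
    if p > config.P_max:
        command = PumpCommand(vent_valve=True)
        mode = "vented_stopped"
    elif p < config.P_min:
        command = replace(command, vent_valve=True,
                          pump1_pressurize=False, pump2_vacuum=False)
        mode = "idle"
    return command, ControllerState(p, mode, command)


def plant_step(pressure: float, command: PumpCommand, params: PlantParams,
               rng: np.random.Generator) -> tuple[float, float]:
    """Advance the simulated plant one step.

    Returns ``(true_pressure, sensor_reading)``.  Venting relaxes
    exponentially toward ambient and overrides pump action; otherwise the
    commanded pump moves pressure by ``gain`` and the leak pulls toward
    ambient by at most ``leak_rate``.
    """
    if not np.isfinite(pressure):
        raise ValueError("pressure must be finite")
    if command.vent_valve:
        pressure = params.ambient_P + (pressure - params.ambient_P) * \
            params.vent_retain
    else:
        pressure += params.gain * (int(command.pump1_pressurize)
                                   - int(command.pump2_vacuum))
        drift = pressure - params.ambient_P
        pressure -= np.sign(drift) * min(params.leak_rate, abs(drift))
    reading = pressure + rng.normal(0.0, params.sensor_noise_sd) \
        if params.sensor_noise_sd > 0 else pressure
    return float(pressure), float(reading)


def reset(state: ControllerState,
          sensor_reading: float | None = None) -> tuple[ControllerState,
                                                        float]:
    """Return to idle after a safety stop.

    ``P_min`` is re-derived from the sensor reading at reset time (the
    "initial reading" rule); the new minimum is returned alongside the
    idle state.  Resetting an idle state is a no-op on the mode.
    """
    p = state.P_t if sensor_reading is None else float(sensor_reading)
    return ControllerState(p, "idle", ALL_OFF), p


def simulate_session(decoder, feature_stream: Iterable,
                     config: ControllerConfig, params: PlantParams,
                     seed: int = 0) -> pd.DataFrame:
    """Run decode -> control -> plant over a stream of spectral features.

    Stops at stream end or on an absorbing safety stop.  Returns the full
    trajectory with one row per step: intent, P(fist), pump commands, true
    pressure, sensor reading, controller mode.
    """
    from .model import decode_intent

    rng = np.random.default_rng(seed)
    features = list(feature_stream)
    if not features:
        raise ValueError("feature stream is empty")
    pressure = params.ambient_P
    reading = pressure
    state = ControllerState(P_t=reading)
    rows = []
    for step, feat in enumerate(features):
        s_t, proba = decode_intent(decoder, feat, threshold=config.threshold)
        command, state = control_step(state, s_t, config)
        pressure, reading = plant_step(pressure, command, params, rng)
        rows.append({
            "step": step, "s_t": s_t, "p_fist": float(proba[1]),
            "pump1": command.pump1_pressurize,
            "pump2": command.pump2_vacuum,
            "vent": command.vent_valve,
            "pressure": pressure, "sensor_reading": reading,
            "mode": state.mode,
        })
        state = ControllerState(reading, state.mode, command)
        if state.mode == "vented_stopped":
            break
    return pd.DataFrame(rows)
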
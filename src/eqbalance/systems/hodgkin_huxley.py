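"""Conductance-based neuron models with an arbitrary set of ionic currents.

Under space clamp the membrane voltage obeys the current balance

    C_M dV/dt = -sum_j I_j + I_stim,

with each ionic current I_j = g_j * (gating product) * (V - E_j) in uA/cm^2,
gating variables relaxing to voltage-dependent steady states, and optionally
an intracellular calcium pool modulating calcium-activated conductances.
The framework is current-count-agnostic; two ready-made configurations ship:

- :func:`classic_hh_config`: the classic squid-axon model (Na, K, leak).
- :func:`bursting_config`: a five-current calcium-mediated burster in the
  style of reduced R15 *Aplysia* models (fast Na and delayed-rectifier K for
  spikes; a slow inward current, a calcium-activated K current, and a leak
  driving the slow burst envelope).  Parameters follow the classic reduced
  R15 literature, not any particular published ten-current parameterisation.

Voltage in mV, time in ms, conductance in mS/cm^2, capacitance in uF/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from ..exceptions import ConfigurationError, IntegrationError
from .base import SimulationResult

__all__ = [
    "Gate",
    "IonCurrent",
    "CalciumPool",
    "HHConfig",
    "classic_hh_config",
    "bursting_config",
    "simulate_hodgkin_huxley",
]


def _vtrap(x, y):
    """x / (exp(x/y) - 1), safe at the removable singularity x -> 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    with np.errstate(over="ignore"):
        out = np.where(small, y - x / 2.0, x / np.expm1(np.clip(x / y, -500, 500)))
    return out


@dataclass(frozen=True)
class Gate:
    """A gating variable: dx/dt = (inf(V) - x) / tau(V); tau=None => instantaneous."""

    name: str
    inf: Callable[[np.ndarray], np.ndarray]
    tau: Callable[[np.ndarray], np.ndarray] | None = None


@dataclass(frozen=True)
class IonCurrent:
    """I = g_max * prod(gate^exponent) * ca_factor(Ca) * (V - e_rev)."""

    name: str
    g_max: float  # mS/cm^2
    e_rev: float  # mV
    gates: tuple[tuple[str, int], ...] = ()
    ca_activation: Callable[[np.ndarray], np.ndarray] | None = None
    label: str = ""

    def conductance(self, gate_values: dict, ca: np.ndarray | None):
        g = self.g_max
        for gname, expo in self.gates:
            g = g * gate_values[gname] ** expo
        if self.ca_activation is not None:
            g = g * self.ca_activation(ca)
        return g


@dataclass(frozen=True)
class CalciumPool:
    """dCa/dt = rho * (k_c * driver_gate * (e_ca - V) - Ca)."""

    rho: float  # 1/ms
    k_c: float  # 1/mV
    e_ca: float  # mV
    driver_gate: str
    ca0: float = 0.5


@dataclass
class HHConfig:
    """Configuration of a generalized conductance-based neuron."""

    c_m: float  # uF/cm^2
    currents: tuple[IonCurrent, ...]
    gates: dict  # name -> Gate
    i_stim: Callable[[float], float] | float = 0.0
    calcium: CalciumPool | None = None
    t_span: tuple[float, float] = (0.0, 100.0)
    dt: float = 0.05  # output sampling step, ms
    v0: float = -65.0
    gate_init: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ConfigurationError("membrane capacitance must be positive")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        for c in self.currents:
            if c.g_max < 0:
                raise ConfigurationError(f"conductance of {c.name} must be >= 0")
        names = [c.name for c in self.currents]
        if len(set(names)) != len(names):
            raise ConfigurationError("current names must be unique")

    def stim(self, t):
        return self.i_stim(t) if callable(self.i_stim) else float(self.i_stim)

    def dynamic_gate_names(self) -> list[str]:
        return [g.name for g in self.gates.values() if g.tau is not None]


# --------------------------------------------------------------------------- #
# ready-made configurations
# --------------------------------------------------------------------------- #
def classic_hh_config(
    i_stim=0.0,
    t_span=(0.0, 100.0),
    dt=0.05,
    v0=-65.0,
) -> HHConfig:
    """The classic squid-axon model: fast Na, delayed-rectifier K, leak."""

    gates = {
        "m": Gate(
            "m",
            inf=lambda v: _am(v) / (_am(v) + _bm(v)),
            tau=lambda v: 1.0 / (_am(v) + _bm(v)),
        ),
        "h": Gate(
            "h",
            inf=lambda v: _ah(v) / (_ah(v) + _bh(v)),
            tau=lambda v: 1.0 / (_ah(v) + _bh(v)),
        ),
        "n": Gate(
            "n",
            inf=lambda v: _an(v) / (_an(v) + _bn(v)),
            tau=lambda v: 1.0 / (_an(v) + _bn(v)),
        ),
    }
    currents = (
        IonCurrent("I_Na", 120.0, 50.0, (("m", 3), ("h", 1)), label="I_Na"),
        IonCurrent("I_K", 36.0, -77.0, (("n", 4),), label="I_K"),
        IonCurrent("I_L", 0.3, -54.387, (), label="I_leak"),
    )
    cfg = HHConfig(
        c_m=1.0, currents=currents, gates=gates, i_stim=i_stim,
        t_span=t_span, dt=dt, v0=v0,
    )
    cfg.gate_init = {g: gates[g].inf(np.asarray(v0)).item() for g in ("m", "h", "n")}
    return cfg


def _am(v):
    return 0.1 * _vtrap(-(v + 40.0), 10.0)


def _bm(v):
    return 4.0 * np.exp(-(v + 65.0) / 18.0)


def _ah(v):
    return 0.07 * np.exp(-(v + 65.0) / 20.0)


def _bh(v):
    return 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))


def _an(v):
    return 0.01 * _vtrap(-(v + 55.0), 10.0)


def _bn(v):
    return 0.125 * np.exp(-(v + 65.0) / 80.0)


def bursting_config(
    t_span=(0.0, 60000.0),
    dt=2.0,
    i_stim=0.0,
) -> HHConfig:
    """Five-current calcium-mediated burster (reduced R15-style).

    Squid-like fast kinetics are mapped onto the burster's voltage range via
    the affine change of variable Vs = (127 V + 8265) / 105 used throughout
    the reduced R15 literature.  The slow inward gate x (time constant 235 ms)
    and the calcium pool (rate 3e-4 / ms) set the ~10 s burst period.
    """

    def vs(v):
        return (127.0 * v + 8265.0) / 105.0

    def am(v):
        return 0.1 * _vtrap(50.0 - vs(v), 10.0)

    def bm(v):
        return 4.0 * np.exp((25.0 - vs(v)) / 18.0)

    def ah(v):
        return 0.07 * np.exp((25.0 - vs(v)) / 20.0)

    def bh(v):
        return 1.0 / (1.0 + np.exp((55.0 - vs(v)) / 10.0))

    def an(v):
        return 0.01 * _vtrap(55.0 - vs(v), 10.0)

    def bn(v):
        return 0.125 * np.exp((45.0 - vs(v)) / 80.0)

    gates = {
        "m": Gate("m", inf=lambda v: am(v) / (am(v) + bm(v)), tau=None),
        "h": Gate(
            "h",
            inf=lambda v: ah(v) / (ah(v) + bh(v)),
            tau=lambda v: 12.5 / (ah(v) + bh(v)),
        ),
        "n": Gate(
            "n",
            inf=lambda v: an(v) / (an(v) + bn(v)),
            tau=lambda v: 12.5 / (an(v) + bn(v)),
        ),
        "x": Gate(
            "x",
            inf=lambda v: 1.0 / (1.0 + np.exp(0.15 * (-v - 50.0))),
            tau=lambda v: 235.0 * np.ones_like(np.asarray(v, dtype=float)),
        ),
    }
    currents = (
        IonCurrent("I_Na", 4.0, 30.0, (("m", 3), ("h", 1)), label="I_Na (fast inward)"),
        IonCurrent("I_K", 0.3, -75.0, (("n", 4),), label="I_K (delayed rectifier)"),
        IonCurrent("I_SI", 0.01, 30.0, (("x", 1),), label="I_SI (slow inward)"),
        IonCurrent(
            "I_KCa",
            0.03,
            -75.0,
            (),
            ca_activation=lambda ca: ca / (0.5 + ca),
            label="I_KCa (Ca-activated K)",
        ),
        IonCurrent("I_L", 0.003, -40.0, (), label="I_leak"),
    )
    calcium = CalciumPool(rho=3e-4, k_c=0.0085, e_ca=140.0, driver_gate="x", ca0=0.6)
    cfg = HHConfig(
        c_m=1.0, currents=currents, gates=gates, i_stim=i_stim,
        calcium=calcium, t_span=t_span, dt=dt, v0=-50.0,
    )
    cfg.gate_init = {
        "h": gates["h"].inf(np.asarray(-50.0)).item(),
        "n": gates["n"].inf(np.asarray(-50.0)).item(),
        "x": gates["x"].inf(np.asarray(-50.0)).item(),
    }
    return cfg


# --------------------------------------------------------------------------- #
# simulation
# --------------------------------------------------------------------------- #
def simulate_hodgkin_huxley(config: HHConfig) -> SimulationResult:
    """Integrate the current-balance equation and return per-term arrays.

    Uses a stiff-capable adaptive integrator (LSODA).  The capacitive term
    C_M dV/dt is recorded from the right-hand side of the ODE, not by finite
    differencing the trajectory, so the signed term arrays
    (-C_M dV/dt, -I_j ..., +I_stim) sum to zero exactly at every output time.
    """
    dyn_gates = config.dynamic_gate_names()
    n_gates = len(dyn_gates)
    has_ca = config.calcium is not None

    def unpack(y):
        v = y[0]
        gvals = {}
        for i, gname in enumerate(dyn_gates):
            gvals[gname] = y[1 + i]
        for gname, gate in config.gates.items():
            if gate.tau is None:
                gvals[gname] = gate.inf(v)
        ca = y[1 + n_gates] if has_ca else None
        return v, gvals, ca

    def currents_of(v, gvals, ca):
        return {c.name: c.conductance(gvals, ca) * (v - c.e_rev) for c in config.currents}

    def rhs(t, y):
        v, gvals, ca = unpack(y)
        itot = sum(currents_of(v, gvals, ca).values())
        dv = (-itot + config.stim(t)) / config.c_m
        dy = [dv]
        for gname in dyn_gates:
            gate = config.gates[gname]
            dy.append((gate.inf(v) - gvals[gname]) / gate.tau(v))
        if has_ca:
            cp = config.calcium
            dy.append(cp.rho * (cp.k_c * gvals[cp.driver_gate] * (cp.e_ca - v) - ca))
        return dy

    y0 = [config.v0]
    for gname in dyn_gates:
        y0.append(config.gate_init.get(gname, config.gates[gname].inf(np.asarray(config.v0)).item()))
    if has_ca:
        y0.append(config.calcium.ca0)

    t_eval = np.arange(config.t_span[0], config.t_span[1] + 0.5 * config.dt, config.dt)
    sol = solve_ivp(
        rhs,
        config.t_span,
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-8,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    v = sol.y[0]
    if np.abs(v).max() > 500.0:
        raise IntegrationError(
            f"trajectory diverged: |V| reached {np.abs(v).max():.1f} mV > 500 mV"
        )

    gvals = {}
    for i, gname in enumerate(dyn_gates):
        gvals[gname] = sol.y[1 + i]
    for gname, gate in config.gates.items():
        if gate.tau is None:
            gvals[gname] = gate.inf(v)
    ca = sol.y[1 + n_gates] if has_ca else None

    stim = np.array([config.stim(t) for t in sol.t])
    cur = {c.name: c.conductance(gvals, ca) * (v - c.e_rev) for c in config.currents}
    cap = -sum(cur.values()) + stim  # C_M dV/dt from the RHS

    # implicit form: -C_M dV/dt - sum_j I_j + I_stim = 0
    term_arrays = {"dVdt": (cap, -1, "C_M dV/dt")}
    for c in config.currents:
        term_arrays[c.name] = (cur[c.name], -1, c.label or c.name)
    term_arrays["I_stim"] = (stim, +1, "I_stim")

    states = {"V": v, **gvals}
    if has_ca:
        states["Ca"] = ca
    return SimulationResult(
        coords=sol.t[:, None],
        states=states,
        term_arrays=term_arrays,
        metadata={
            "model": "hodgkin_huxley",
            "n_currents": len(config.currents),
            "c_m": config.c_m,
            "dt": config.dt,
            "t_span": list(config.t_span),
            "solver": "LSODA rtol=1e-8 atol=1e-8",
        },
    )
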
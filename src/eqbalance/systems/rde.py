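"""Burgers-type reactive analog of a rotating detonation engine (RDE).

On a periodic domain, an abstract energy-like scalar u(x, t) and a combustion
progress variable lambda(x, t) evolve as

    u_t + u u_x = q (1 - lambda) omega(u) + eps * xi(u)
    lambda_t    = (1 - lambda) omega(u) - beta(u) lambda

with submodels (all overridable through :class:`RDEConfig`):

    omega(u) = exp((u - u_c) / a_k)            reaction kinetics
    xi(u)    = -u^2                            exhaust dissipation (eps >= 0
                                               is the loss coefficient, so xi
                                               is negative-definite)
    beta(u)  = s * u_p / (1 + exp(r (u - u_p)))  injection / gain recovery

The self-steepening Burgers advection plus reactive gain supports persistent
traveling detonation-like waves; behind each front, lambda -> 1 shuts off the
gain (refractory period) until injection recovers it.

Numerics: finite-volume Godunov upwinding for the Burgers flux u^2/2 with
explicit SSP-RK2 time stepping under a CFL constraint.  Term arrays at the
output snapshots are computed with the same discrete operators, and u_t and
lambda_t are taken from the semi-discrete right-hand sides, so the implicit
form closes exactly on the stored snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..exceptions import ConfigurationError, IntegrationError
from .base import SimulationResult

__all__ = ["RDEConfig", "simulate_rde_analog", "two_pulse_initial_condition"]


def two_pulse_initial_condition(x: np.ndarray, amplitude: float = 1.5) -> np.ndarray:
    """Two localized pulses half a domain apart (seeds two traveling waves)."""
    L = x[-1] + (x[1] - x[0])
    return amplitude * (
        1.0 / np.cosh(3.0 * (x - 0.25 * L)) ** 2
        + 1.0 / np.cosh(3.0 * (x - 0.75 * L)) ** 2
    )


@dataclass
class RDEConfig:
    """Physical and numerical parameters of the detonation analog."""

    q: float = 1.0  # energy release
    epsilon_loss: float = 0.15  # loss coefficient eps
    u_p: float = 0.5  # injection sensitivity cutoff
    s: float = 7.0  # injection timescale (default sits in the two-wave regime)
    r: float = 5.0  # injection cutoff steepness
    u_c: float = 1.1  # kinetics activation threshold
    a_k: float = 0.3  # kinetics steepness
    L: float = 2 * np.pi  # periodic domain length
    M: int = 256  # grid cells
    t_span: tuple[float, float] = (0.0, 100.0)
    cfl: float = 0.5
    n_snapshots: int = 201
    u0: Callable[[np.ndarray], np.ndarray] | np.ndarray | None = None
    lam0: Callable[[np.ndarray], np.ndarray] | np.ndarray | float = 0.0
    omega: Callable | None = None  # omega(u); default exponential kinetics
    xi: Callable | None = None  # xi(u); default -u^2
    beta: Callable | None = None  # beta(u); default logistic injection

    def __post_init__(self) -> None:
        if self.q < 0 or self.epsilon_loss < 0:
            raise ConfigurationError("q and epsilon_loss must be >= 0")
        if self.M < 64:
            raise ConfigurationError("grid size M must be >= 64")
        if not (0 < self.cfl <= 1):
            raise ConfigurationError("CFL number must lie in (0, 1]")

    def grid(self) -> np.ndarray:
        dx = self.L / self.M
        return np.arange(self.M) * dx + dx / 2

    def omega_of(self, u):
        if self.omega is not None:
            return self.omega(u)
        return np.exp(np.clip((u - self.u_c) / self.a_k, -500, 50))

    def xi_of(self, u):
        if self.xi is not None:
            return self.xi(u)
        return -(u**2)

    def beta_of(self, u):
        if self.beta is not None:
            return self.beta(u)
        return self.s * self.u_p / (1.0 + np.exp(np.clip(self.r * (u - self.u_p), -500, 500)))


def _godunov_flux(u: np.ndarray) -> np.ndarray:
    """Godunov interface fluxes for the Burgers flux f(u) = u^2 / 2 (periodic).

    Returns F[i] = flux through the interface between cells i-1 and i.
    """
    ul = np.roll(u, 1)
    ur = u
    fl, fr = 0.5 * ul**2, 0.5 * ur**2
    shock_speed = 0.5 * (ul + ur)
    shock = np.where(shock_speed > 0, fl, fr)
    raref = np.where(ul > 0, fl, np.where(ur < 0, fr, 0.0))
    return np.where(ul > ur, shock, raref)


def _advection(u: np.ndarray, dx: float) -> np.ndarray:
    """Discrete u u_x (conservative Godunov flux divergence)."""
    flux = _godunov_flux(u)
    return (np.roll(flux, -1) - flux) / dx


def simulate_rde_analog(config: RDEConfig) -> SimulationResult:
    """Integrate the detonation analog and return snapshots with term arrays.

    The coordinates of the result are (x, t) pairs, flattened with x fastest,
    for ``n_snapshots`` uniformly spaced output times.
    """
    x = config.grid()
    dx = config.L / config.M
    if config.u0 is None:
        u = two_pulse_initial_condition(x)
    elif callable(config.u0):
        u = np.asarray(config.u0(x), dtype=float)
    else:
        u = np.asarray(config.u0, dtype=float).copy()
    if callable(config.lam0):
        lam = np.asarray(config.lam0(x), dtype=float)
    else:
        lam = np.full(config.M, float(np.max(config.lam0))) if np.isscalar(config.lam0) \
            else np.asarray(config.lam0, dtype=float).copy()
    if u.shape != x.shape or lam.shape != x.shape:
        raise ConfigurationError("initial conditions must match the grid size")

    def rhs(u, lam):
        gain = config.q * (1.0 - lam) * config.omega_of(u)
        loss = config.epsilon_loss * config.xi_of(u)
        du = -_advection(u, dx) + gain + loss
        dlam = (1.0 - lam) * config.omega_of(u) - config.beta_of(u) * lam
        return du, dlam

    t0, t1 = config.t_span
    t_out = np.linspace(t0, t1, config.n_snapshots)
    snaps_u = np.empty((config.n_snapshots, config.M))
    snaps_lam = np.empty((config.n_snapshots, config.M))
    snaps_u[0], snaps_lam[0] = u, lam

    t = t0
    k_out = 1
    max_dt = config.cfl * dx  # also bounds the explicit source update
    while k_out < config.n_snapshots:
        speed = max(float(np.abs(u).max()), 1e-12)
        dt = min(config.cfl * dx / speed, max_dt)
        if t + dt > t_out[k_out]:
            dt = t_out[k_out] - t
        # SSP-RK2 (Heun)
        du1, dl1 = rhs(u, lam)
        u1, lam1 = u + dt * du1, lam + dt * dl1
        du2, dl2 = rhs(u1, lam1)
        u = u + 0.5 * dt * (du1 + du2)
        lam = lam + 0.5 * dt * (dl1 + dl2)
        lam = np.clip(lam, 0.0, 1.0)
        t += dt
        if not np.isfinite(u).all() or not np.isfinite(lam).all():
            raise IntegrationError(f"NaN/Inf state at t = {t:.4f}")
        if t >= t_out[k_out] - 1e-12:
            snaps_u[k_out], snaps_lam[k_out] = u, lam
            k_out += 1

    # term arrays on snapshots; u_t and lambda_t from the discrete RHS
    U, LAM = snaps_u, snaps_lam
    uux = np.vstack([_advection(row, dx) for row in U])
    gain = config.q * (1.0 - LAM) * config.omega_of(U)
    loss = config.epsilon_loss * config.xi_of(U)
    u_t = -uux + gain + loss
    lam_gain = (1.0 - LAM) * config.omega_of(U)
    lam_loss = config.beta_of(U) * LAM
    lam_t = lam_gain - lam_loss

    xx, tt = np.meshgrid(x, t_out)  # rows = times
    coords = np.column_stack([xx.ravel(), tt.ravel()])
    term_arrays = {
        # implicit form of the u equation: -u_t - u u_x + gain + eps xi = 0
        "u_t": (u_t.ravel(), -1, "u_t"),
        "u_ux": (uux.ravel(), -1, "u u_x"),
        "gain": (gain.ravel(), +1, "q(1-λ)ω(u)"),
        "loss": (loss.ravel(), +1, "ε ξ(u)"),
        # implicit form of the progress-variable equation
        "lam_t": (lam_t.ravel(), -1, "λ_t"),
        "lam_gain": (lam_gain.ravel(), +1, "(1-λ)ω(u)"),
        "lam_loss": (lam_loss.ravel(), -1, "β λ"),
    }
    return SimulationResult(
        coords=coords,
        states={"u": U, "lambda": LAM, "x": x, "t": t_out},
        term_arrays=term_arrays,
        metadata={
            "model": "rde_analog",
            "M": config.M,
            "L": config.L,
            "cfl": config.cfl,
            "t_span": list(config.t_span),
            "q": config.q,
            "epsilon_loss": config.epsilon_loss,
            "scheme": "Godunov FV + SSP-RK2",
        },
    )


U_EQUATION_TERMS = ["u_t", "u_ux", "gain", "loss"]
LAMBDA_EQUATION_TERMS = ["lam_t", "lam_gain", "lam_loss"]
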
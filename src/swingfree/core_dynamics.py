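"""Cart-pendulum and coupled hand-object dynamics.

The manipulated object is a cart (the "cup") of mass ``m_c`` carrying a
pendulum (the "ball") of mass ``m_p`` and length ``l``.  The hand couples to
the cart through a spring-damper impedance (stiffness ``K``, damping ``B``)
in parallel with a feedforward force.  This module provides:

* fixed-step RK4 simulation of the bare object (nonlinear and linearized),
* simulation of the coupled hand-object system (linear and nonlinear plant),
* the 4x4 state matrix of the coupled linear system and its modal
  decomposition into a slow and a fast underdamped mode.

All angles are radians internally; state ordering is ``(x, xd, phi, phid)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _integrators
from .errors import DegenerateModeError, IntegrationError

__all__ = [
    "SystemParams",
    "ImpedanceParams",
    "State",
    "StateTrajectory",
    "ModeSpec",
    "DEFAULT_STEP",
    "simulate_nonlinear",
    "simulate_linearized",
    "simulate_coupled",
    "coupled_linear_matrix",
    "modal_decomposition",
    "pendulum_mode",
    "mechanical_energy",
]

#: Default internal integration step (s).  1/960 s so that the 120 Hz
#: experimental grid is an exact subsampling (every 8th point).
DEFAULT_STEP = 1.0 / 960.0


@dataclass(frozen=True)
class SystemParams:
    """Physical constants of the cart-pendulum object."""

    m_c: float = 1.9   # cart (cup) mass, kg
    m_p: float = 1.1   # pendulum (ball) mass, kg
    l: float = 0.5     # pendulum length, m
    g: float = 9.81    # gravitational acceleration, m/s^2

    def __post_init__(self):
        for name in ("m_c", "m_p", "l", "g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"SystemParams.{name} must be strictly positive")

    @property
    def total_mass(self) -> float:
        return self.m_c + self.m_p


@dataclass(frozen=True)
class ImpedanceParams:
    """Hand impedance coupling the commanded trajectory to the cart."""

    K: float  # stiffness, N/m
    B: float  # damping, Ns/m

    def __post_init__(self):
        if self.K < 0 or self.B < 0:
            raise ValueError("impedance parameters must be non-negative")


@dataclass(frozen=True)
class State:
    """Instantaneous state (x, xd, phi, phid) of the cart-pendulum."""

    x: float = 0.0
    x_dot: float = 0.0
    phi: float = 0.0
    phi_dot: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.x_dot, self.phi, self.phi_dot])


@dataclass
class StateTrajectory:
    """Sampled trajectory of the (possibly coupled) cart-pendulum system.

    Accelerations are recomputed from the equations of motion at every
    sample, never finite-differenced.  ``F`` is the total applied force and
    ``F_ball`` the reaction force of the ball on the cart.
    """

    t: np.ndarray
    x: np.ndarray
    x_dot: np.ndarray
    x_ddot: np.ndarray
    phi: np.ndarray
    phi_dot: np.ndarray
    phi_ddot: np.ndarray
    F: np.ndarray
    F_ball: np.ndarray

    def __post_init__(self):
        n = len(self.t)
        for name in ("x", "x_dot", "x_ddot", "phi", "phi_dot", "phi_ddot",
                     "F", "F_ball"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch in field {name!r}")

    @property
    def step(self) -> float:
        return float(self.t[1] - self.t[0])

    def state_at(self, i: int) -> State:
        return State(float(self.x[i]), float(self.x_dot[i]),
                     float(self.phi[i]), float(self.phi_dot[i]))

    @property
    def final_state(self) -> State:
        return self.state_at(len(self.t) - 1)


@dataclass(frozen=True)
class ModeSpec:
    """One underdamped oscillatory mode: (omega_n, zeta, T_d)."""

    omega_n: float          # undamped natural frequency, rad/s
    zeta: float             # damping ratio
    T_d: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.omega_n > 0:
            raise ValueError("omega_n must be positive")
        if not (0 <= self.zeta < 1):
            raise DegenerateModeError(
                f"mode with zeta = {self.zeta} is not underdamped")
        td = 2.0 * math.pi / (self.omega_n * math.sqrt(1.0 - self.zeta ** 2))
        if self.T_d is None:
            object.__setattr__(self, "T_d", td)
        elif abs(self.T_d - td) > 1e-12 * td:
            raise ValueError("T_d inconsistent with omega_n and zeta")

    @property
    def T_n(self) -> float:
        """Undamped natural period, s."""
        return 2.0 * math.pi / self.omega_n

    @property
    def omega_d(self) -> float:
        """Damped natural frequency, rad/s."""
        return self.omega_n * math.sqrt(1.0 - self.zeta ** 2)


def pendulum_mode(params: SystemParams) -> ModeSpec:
    """Undamped mode of the bare pendulum: omega = sqrt(g/l), zeta = 0."""
    return ModeSpec(omega_n=math.sqrt(params.g / params.l), zeta=0.0)


# ---------------------------------------------------------------------------
# Simulation front ends
# ---------------------------------------------------------------------------

def _sample_half_grid(fn_or_arr, t_half: np.ndarray) -> np.ndarray:
    if callable(fn_or_arr):
        out = fn_or_arr(t_half)
        out = np.broadcast_to(np.asarray(out, dtype=float), t_half.shape)
        return np.ascontiguousarray(out)
    arr = np.asarray(fn_or_arr, dtype=float)
    if arr.shape != t_half.shape:
        raise ValueError("force array must be sampled on the half-step grid")
    return np.ascontiguousarray(arr)


def _run_coupled(params: SystemParams, K: float, B: float,
                 x0h: np.ndarray, x0dh: np.ndarray, fffh: np.ndarray,
                 initial: State, n: int, step: float,
                 nonlinear: bool) -> StateTrajectory:
    xs = np.empty(n + 1)
    xds = np.empty(n + 1)
    ps = np.empty(n + 1)
    pds = np.empty(n + 1)
    blow = _integrators.sim_coupled(
        params.m_c, params.m_p, params.l, params.g, K, B,
        x0h, x0dh, fffh, step, n,
        initial.x, initial.x_dot, initial.phi, initial.phi_dot,
        nonlinear, xs, xds, ps, pds)
    if blow >= 0:
        raise IntegrationError(time=blow * step)
    t = np.arange(n + 1) * step
    even = slice(0, 2 * n + 1, 2)
    F = fffh[even] + B * (x0dh[even] - xds) + K * (x0h[even] - xs)
    xdd, pdd = _accelerations(params, xs, ps, pds, F, nonlinear)
    if nonlinear:
        f_ball = params.m_p * params.l * (
            pds ** 2 * np.sin(ps) - pdd * np.cos(ps))
    else:
        f_ball = -params.m_p * params.l * pdd
    return StateTrajectory(t=t, x=xs, x_dot=xds, x_ddot=xdd,
                           phi=ps, phi_dot=pds, phi_ddot=pdd,
                           F=F, F_ball=f_ball)


def _accelerations(params: SystemParams, x: np.ndarray, phi: np.ndarray,
                   phid: np.ndarray, F: np.ndarray, nonlinear: bool):
    """Recompute (xdd, phidd) from the equations of motion."""
    mc, mp, l, g = params.m_c, params.m_p, params.l, params.g
    if nonlinear:
        s = np.sin(phi)
        c = np.cos(phi)
        xdd = (mp * l * phid ** 2 * s + mp * g * s * c + F) / (mc + mp * s * s)
        pdd = -(xdd * c + g * s) / l
    else:
        xdd = (mp * g * phi + F) / mc
        pdd = -(g * phi + xdd) / l
    return xdd, pdd


def _n_steps(duration: float, step: float) -> int:
    n = int(round(duration / step))
    if n < 1 or duration <= 0 or step <= 0:
        raise ValueError("duration and step must be positive")
    return n


def simulate_nonlinear(params: SystemParams,
                       force_profile: Callable[[np.ndarray], np.ndarray],
                       initial: State = State(),
                       duration: float = 1.0,
                       step: float = DEFAULT_STEP) -> StateTrajectory:
    """Integrate the nonlinear cart-pendulum driven by an applied force."""
    n = _n_steps(duration, step)
    t_half = np.arange(2 * n + 1) * (step / 2.0)
    fh = _sample_half_grid(force_profile, t_half)
    zero = np.zeros_like(t_half)
    return _run_coupled(params, 0.0, 0.0, zero, zero, fh, initial, n, step,
                        nonlinear=True)


def simulate_linearized(params: SystemParams,
                        force_profile: Callable[[np.ndarray], np.ndarray],
                        initial: State = State(),
                        duration: float = 1.0,
                        step: float = DEFAULT_STEP) -> StateTrajectory:
    """Integrate the cart-pendulum linearized about phi = 0."""
    n = _n_steps(duration, step)
    t_half = np.arange(2 * n + 1) * (step / 2.0)
    fh = _sample_half_grid(force_profile, t_half)
    zero = np.zeros_like(t_half)
    return _run_coupled(params, 0.0, 0.0, zero, zero, fh, initial, n, step,
                        nonlinear=False)


def simulate_coupled(params: SystemParams,
                     imp: ImpedanceParams,
                     command,
                     F_ff,
                     linear: bool = False,
                     initial: State = State(),
                     duration: float = 2.0,
                     step: float = DEFAULT_STEP,
                     command_delay: float = 0.0) -> StateTrajectory:
    """Integrate the hand-object system driven by a shaped command.

    Parameters
    ----------
    command
        Either an object with an ``evaluate(t) -> (x0, x0d, x0dd)`` method
        (a shaped command) or a pair of callables ``(x0, x0d)``.
    F_ff
        Feedforward force: callable of time or ``None`` for zero.
    command_delay
        Shift the command (and F_ff) to start this many seconds into the
        simulation; the system is at rest before it.
    """
    n = _n_steps(duration, step)
    t_half = np.arange(2 * n + 1) * (step / 2.0) - command_delay
    if hasattr(command, "evaluate"):
        x0h, x0dh, _ = command.evaluate(t_half)
    else:
        x0_fn, x0d_fn = command
        x0h = _sample_half_grid(x0_fn, t_half)
        x0dh = _sample_half_grid(x0d_fn, t_half)
    if F_ff is None:
        fffh = np.zeros_like(t_half)
    else:
        fffh = _sample_half_grid(F_ff, t_half)
    return _run_coupled(params, imp.K, imp.B, np.ascontiguousarray(x0h),
                        np.ascontiguousarray(x0dh), fffh, initial, n, step,
                        nonlinear=not linear)


# ---------------------------------------------------------------------------
# Linear analysis
# ---------------------------------------------------------------------------

def coupled_linear_matrix(params: SystemParams, imp: ImpedanceParams):
    """State matrix and input map of the coupled linear hand-object system.

    Returns ``(A, Bmap)`` for state (x, xd, phi, phid) and inputs
    (x0, x0d, F_ff), with dynamics ``ydot = A y + Bmap u``.
    """
    mc, mp, l, g = params.m_c, params.m_p, params.l, params.g
    K, B = imp.K, imp.B
    A = np.array([
        [0.0, 1.0, 0.0, 0.0],
        [-K / mc, -B / mc, mp * g / mc, 0.0],
        [0.0, 0.0, 0.0, 1.0],
        [K / (l * mc), B / (l * mc), -(g / l) * (1.0 + mp / mc), 0.0],
    ])
    Bmap = np.array([
        [0.0, 0.0, 0.0],
        [K / mc, B / mc, 1.0 / mc],
        [0.0, 0.0, 0.0],
        [-K / (l * mc), -B / (l * mc), -1.0 / (l * mc)],
    ])
    return A, Bmap


def modal_decomposition(matrix: np.ndarray) -> tuple[ModeSpec, ModeSpec]:
    """Split a 4x4 state matrix into its slow and fast underdamped modes.

    Raises
    ------
    DegenerateModeError
        If the matrix does not have two distinct complex-conjugate
        (underdamped) eigenvalue pairs.
    """
    eig = np.linalg.eigvals(np.asarray(matrix, dtype=float))
    upper = sorted((lam for lam in eig if lam.imag > 1e-9),
                   key=lambda lam: abs(lam))
    if len(upper) != 2:
        raise DegenerateModeError(
            f"expected two underdamped eigenvalue pairs, got {eig}")
    modes = []
    for lam in upper:
        omega_n = abs(lam)
        zeta = -lam.real / omega_n
        if not (0 <= zeta < 1):
            raise DegenerateModeError(f"eigenvalue {lam} is not underdamped")
        modes.append(ModeSpec(omega_n=float(omega_n), zeta=float(zeta)))
    slow, fast = modes
    if abs(slow.omega_n - fast.omega_n) < 1e-9 * fast.omega_n:
        raise DegenerateModeError("repeated mode frequencies")
    return slow, fast


def mechanical_energy(params: SystemParams, traj: StateTrajectory) -> np.ndarray:
    """Total mechanical energy of the free nonlinear system at every sample."""
    mc, mp, l, g = params.m_c, params.m_p, params.l, params.g
    xd, phi, phid = traj.x_dot, traj.phi, traj.phi_dot
    kinetic = (0.5 * mc * xd ** 2
               + 0.5 * mp * (xd ** 2 + 2 * l * xd * phid * np.cos(phi)
                             + l ** 2 * phid ** 2))
    potential = mp * g * l * (1.0 - np.cos(phi))
    return kinetic + potential
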
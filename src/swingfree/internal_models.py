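"""Five candidate internal models for planning shaped commands.

Each model plans a transport movement of displacement L and nominal duration
D: it builds an impulse train from its own (simplified) view of the coupled
hand-object dynamics, shapes a minimum-jerk nominal with it, forward-runs the
*internal model* under the shaped command to obtain desired kinematics, and
derives a feedforward force from those kinematics.

Models
------
MULTI_MODE    full 4th-order coupled linear system; convolved two-mode
              shaper; F_ff = m_c*xdd_des - m_p*g*phi_des.
SLOW_MODE     slow mode only, as an effective mass-spring-damper of mass
              m_c; F_ff = m_c*xdd_des.
FAST_MODE     fast mode only, effective mass m_p; F_ff = m_p*xdd_des.
RIGID_BODY    object lumped to a single mass m_c+m_p on the hand spring;
              F_ff = (m_c+m_p)*xdd_des.
NO_IMPEDANCE  bare linearized cart-pendulum, hand impedance ignored;
              F_ff = m_c*xdd_des - m_p*g*phi_des with x_des := x0.

The internal-model forward run uses F_ff = 0 (the model responds to the
shaped command through its impedance coupling alone); F_ff is computed
afterwards from the resulting kinematics.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from . import _integrators
from .core_dynamics import (DEFAULT_STEP, ImpedanceParams, ModeSpec,
                            SystemParams, coupled_linear_matrix,
                            modal_decomposition, pendulum_mode)
from .errors import DegenerateModeError, IntegrationError
from .shaping import ImpulseTrain, ShapedCommand, convolve_trains, min_jerk, \
    shape, zv_impulses

__all__ = [
    "InternalModelKind",
    "EffectiveSystem",
    "PlannedTrial",
    "plan",
    "build_train",
    "rb_mode",
    "effective_system",
    "feedforward",
]


class InternalModelKind(enum.Enum):
    MULTI_MODE = "MM"
    SLOW_MODE = "SM"
    FAST_MODE = "FM"
    RIGID_BODY = "RB"
    NO_IMPEDANCE = "NI"

    @classmethod
    def from_string(cls, s: str) -> "InternalModelKind":
        s = s.strip().upper()
        for kind in cls:
            if s in (kind.name, kind.value):
                return kind
        raise ValueError(f"unknown internal model {s!r}")


@dataclass(frozen=True)
class EffectiveSystem:
    """Single-mode equivalent mass-spring-damper of one oscillatory mode."""

    mass: float
    stiffness: float
    damping: float
    mode: ModeSpec

    def __post_init__(self):
        if not self.mass > 0:
            raise ValueError("mass must be positive")
        k = self.mass * self.mode.omega_n ** 2
        b = 2.0 * self.mass * self.mode.zeta * self.mode.omega_n
        if abs(self.stiffness - k) > 1e-12 * max(k, 1.0):
            raise ValueError("stiffness inconsistent with mode")
        if abs(self.damping - b) > 1e-12 * max(b, 1.0):
            raise ValueError("damping inconsistent with mode")


def effective_system(mode: ModeSpec, mass: float) -> EffectiveSystem:
    """K_eff = mass*omega_n^2, B_eff = 2*mass*zeta*omega_n."""
    return EffectiveSystem(mass=mass,
                           stiffness=mass * mode.omega_n ** 2,
                           damping=2.0 * mass * mode.zeta * mode.omega_n,
                           mode=mode)


def rb_mode(params: SystemParams, imp: ImpedanceParams) -> ModeSpec:
    """Rigid-body mode: omega = sqrt(K/M), zeta = B/(2 sqrt(K M)), M = m_c+m_p."""
    M = params.total_mass
    if imp.K <= 0:
        raise DegenerateModeError("rigid-body mode undefined for K = 0")
    omega = math.sqrt(imp.K / M)
    zeta = imp.B / (2.0 * math.sqrt(imp.K * M))
    if zeta >= 1:
        raise DegenerateModeError(f"rigid-body mode overdamped (zeta={zeta:.3f})")
    return ModeSpec(omega_n=omega, zeta=zeta)


@dataclass
class PlannedTrial:
    """Planned command, desired kinematics and feedforward force.

    All arrays share the time grid ``t``; ``phi_des`` and its derivatives are
    ``None`` for models that do not represent the ball (SM, FM, RB).
    """

    kind: InternalModelKind
    command: ShapedCommand
    t: np.ndarray
    x_des: np.ndarray
    xd_des: np.ndarray
    xdd_des: np.ndarray
    F_ff: np.ndarray
    phi_des: np.ndarray | None = None
    phid_des: np.ndarray | None = None
    phidd_des: np.ndarray | None = None

    def fff_at(self, t) -> np.ndarray:
        """Feedforward force at arbitrary times (zero outside the plan)."""
        return np.interp(np.asarray(t, dtype=float), self.t, self.F_ff,
                         left=0.0, right=0.0)


def _jittered(train: ImpulseTrain, offsets) -> ImpulseTrain:
    """Perturb impulse times (first impulse pinned at 0); used by the
    synthetic-trial generator to emulate command-timing variability."""
    times = np.asarray(train.times, dtype=float).copy()
    offs = np.asarray(offsets, dtype=float)
    if offs.shape != times.shape:
        raise ValueError("need one time offset per impulse")
    times[1:] = times[1:] + offs[1:]
    times[1:] = np.maximum(times[1:], 1e-6)
    order = np.argsort(times, kind="stable")
    return ImpulseTrain(amplitudes=tuple(np.asarray(train.amplitudes)[order]),
                        times=tuple(times[order]))


def build_train(kind: InternalModelKind, params: SystemParams,
                imp: ImpedanceParams) -> ImpulseTrain:
    """Impulse train dictated by the internal model (before shaping)."""
    if kind is InternalModelKind.MULTI_MODE:
        slow, fast = modal_decomposition(coupled_linear_matrix(params, imp)[0])
        return convolve_trains(zv_impulses(slow), zv_impulses(fast))
    if kind is InternalModelKind.SLOW_MODE:
        slow, _ = modal_decomposition(coupled_linear_matrix(params, imp)[0])
        return zv_impulses(slow)
    if kind is InternalModelKind.FAST_MODE:
        _, fast = modal_decomposition(coupled_linear_matrix(params, imp)[0])
        return zv_impulses(fast)
    if kind is InternalModelKind.RIGID_BODY:
        return zv_impulses(rb_mode(params, imp))
    if kind is InternalModelKind.NO_IMPEDANCE:
        return zv_impulses(pendulum_mode(params))
    raise ValueError(f"unknown kind {kind!r}")


def _planning_mode(kind: InternalModelKind, params: SystemParams,
                   imp: ImpedanceParams) -> ModeSpec:
    """Mode whose period sets the settling tail of the planned horizon."""
    if kind in (InternalModelKind.MULTI_MODE, InternalModelKind.SLOW_MODE):
        return modal_decomposition(coupled_linear_matrix(params, imp)[0])[0]
    if kind is InternalModelKind.FAST_MODE:
        return modal_decomposition(coupled_linear_matrix(params, imp)[0])[1]
    if kind is InternalModelKind.RIGID_BODY:
        return rb_mode(params, imp)
    return pendulum_mode(params)


def feedforward(kind: InternalModelKind, params: SystemParams,
                xdd_des: np.ndarray,
                phi_des: np.ndarray | None = None) -> np.ndarray:
    """Per-model feedforward force from desired kinematics (samplewise)."""
    mc, mp = params.m_c, params.m_p
    if kind in (InternalModelKind.MULTI_MODE, InternalModelKind.NO_IMPEDANCE):
        if phi_des is None:
            raise ValueError(f"{kind.name} feedforward requires phi_des")
        return mc * np.asarray(xdd_des) - mp * params.g * np.asarray(phi_des)
    if kind is InternalModelKind.SLOW_MODE:
        return mc * np.asarray(xdd_des)
    if kind is InternalModelKind.FAST_MODE:
        return mp * np.asarray(xdd_des)
    if kind is InternalModelKind.RIGID_BODY:
        return params.total_mass * np.asarray(xdd_des)
    raise ValueError(f"unknown kind {kind!r}")


def plan(kind: InternalModelKind, params: SystemParams, imp: ImpedanceParams,
         D: float, L: float, step: float = DEFAULT_STEP,
         impulse_time_offsets=None) -> PlannedTrial:
    """Plan a transport movement under one internal model.

    Parameters
    ----------
    D : float
        Nominal (minimum-jerk) duration, s.  The total command duration is
        D plus the last impulse time of the model's train.
    impulse_time_offsets
        Optional per-impulse time perturbations (synthetic variability).
    """
    if D <= 0:
        raise ValueError("nominal duration must be positive")
    train = build_train(kind, params, imp)
    if impulse_time_offsets is not None:
        train = _jittered(train, impulse_time_offsets)
    command = shape(min_jerk(D, L, step), train)
    tail = _planning_mode(kind, params, imp).T_n
    n = int(math.ceil((command.duration + tail) / step))
    t = np.arange(n + 1) * step
    t_half = np.arange(2 * n + 1) * (step / 2.0)
    x0h, x0dh, x0ddh = command.evaluate(t_half)
    even = slice(0, 2 * n + 1, 2)

    mc, mp, l, g = params.m_c, params.m_p, params.l, params.g
    phi = phid = phidd = None

    if kind is InternalModelKind.MULTI_MODE:
        xs = np.empty(n + 1)
        xds = np.empty(n + 1)
        ps = np.empty(n + 1)
        pds = np.empty(n + 1)
        blow = _integrators.sim_coupled(
            mc, mp, l, g, imp.K, imp.B, x0h, x0dh, np.zeros_like(x0h),
            step, n, 0.0, 0.0, 0.0, 0.0, False, xs, xds, ps, pds)
        if blow >= 0:
            raise IntegrationError(time=blow * step)
        F = imp.B * (x0dh[even] - xds) + imp.K * (x0h[even] - xs)
        xdd = (mp * g * ps + F) / mc
        x, xd, phi, phid = xs, xds, ps, pds
        phidd = -(g * ps + xdd) / l
    elif kind is InternalModelKind.NO_IMPEDANCE:
        ps = np.empty(n + 1)
        pds = np.empty(n + 1)
        blow = _integrators.sim_pendulum_driven(
            g / l, 1.0 / l, x0ddh, step, n, ps, pds)
        if blow >= 0:
            raise IntegrationError(time=blow * step)
        x, xd, xdd = x0h[even], x0dh[even], x0ddh[even]
        phi, phid = ps, pds
        phidd = -(g * ps + xdd) / l
    else:
        if kind is InternalModelKind.SLOW_MODE:
            slow, _ = modal_decomposition(coupled_linear_matrix(params, imp)[0])
            eff = effective_system(slow, mc)
        elif kind is InternalModelKind.FAST_MODE:
            _, fast = modal_decomposition(coupled_linear_matrix(params, imp)[0])
            eff = effective_system(fast, mp)
        else:  # RIGID_BODY
            eff = EffectiveSystem(mass=params.total_mass, stiffness=imp.K,
                                  damping=imp.B, mode=rb_mode(params, imp))
        xs = np.empty(n + 1)
        xds = np.empty(n + 1)
        blow = _integrators.sim_msd(eff.mass, eff.stiffness, eff.damping,
                                    x0h, x0dh, step, n, xs, xds)
        if blow >= 0:
            raise IntegrationError(time=blow * step)
        x, xd = xs, xds
        xdd = (eff.stiffness * (x0h[even] - xs)
               + eff.damping * (x0dh[even] - xds)) / eff.mass

    F_ff = feedforward(kind, params, xdd, phi)
    return PlannedTrial(kind=kind, command=command, t=t,
                        x_des=x, xd_des=xd, xdd_des=xdd, F_ff=F_ff,
                        phi_des=phi, phid_des=phid, phidd_des=phidd)
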
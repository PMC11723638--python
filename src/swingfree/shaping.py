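"""Input shapers and minimum-jerk command generation.

A zero-vibration (ZV) shaper for an underdamped mode is a two-impulse train
``A1 = 1/(1+C), A2 = C/(1+C), t1 = 0, t2 = T_d/2`` with
``C = exp(-zeta*pi/sqrt(1-zeta^2))``.  Shapers for several modes are combined
by convolution.  Convolving a train with a minimum-jerk nominal profile
yields the shaped command driving the hand-object simulations.

Shaped commands are evaluated *analytically* as a superposition of
time-shifted quintic profiles, so impulse timing carries no grid-snapping
error; sampled arrays are provided for convenience.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .core_dynamics import DEFAULT_STEP, ModeSpec
from .errors import DegenerateModeError

__all__ = [
    "ImpulseTrain",
    "NominalProfile",
    "ShapedCommand",
    "zv_impulses",
    "convolve_trains",
    "min_jerk",
    "shape",
    "duration_sweep",
]

_TIME_MERGE_TOL = 1e-12


@dataclass(frozen=True)
class ImpulseTrain:
    """Unit-sum impulse train (amplitudes A_i at times t_i)."""

    amplitudes: tuple[float, ...]
    times: tuple[float, ...]

    def __post_init__(self):
        a = np.asarray(self.amplitudes, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if a.size != t.size or a.size < 1:
            raise ValueError("amplitudes and times must have equal length >= 1")
        if np.any(np.diff(t) < 0) or t[0] != 0.0:
            raise ValueError("times must be nondecreasing and start at 0")
        if np.any(a <= 0):
            raise ValueError("all amplitudes must be positive")
        if abs(a.sum() - 1.0) > 1e-12:
            raise ValueError(f"amplitudes must sum to 1, got {a.sum()!r}")
        object.__setattr__(self, "amplitudes", tuple(float(v) for v in a))
        object.__setattr__(self, "times", tuple(float(v) for v in t))

    def __len__(self) -> int:
        return len(self.amplitudes)

    @property
    def t_last(self) -> float:
        return self.times[-1]


IDENTITY_TRAIN = ImpulseTrain(amplitudes=(1.0,), times=(0.0,))


def zv_impulses(mode: ModeSpec) -> ImpulseTrain:
    """Two-impulse zero-vibration shaper for one underdamped mode."""
    if not (0 <= mode.zeta < 1):
        raise DegenerateModeError(f"ZV shaper undefined for zeta = {mode.zeta}")
    C = math.exp(-mode.zeta * math.pi / math.sqrt(1.0 - mode.zeta ** 2))
    return ImpulseTrain(amplitudes=(1.0 / (1.0 + C), C / (1.0 + C)),
                        times=(0.0, mode.T_d / 2.0))


def convolve_trains(a: ImpulseTrain, b: ImpulseTrain) -> ImpulseTrain:
    """Convolution of two impulse trains (pairwise products and time sums)."""
    amps = np.multiply.outer(a.amplitudes, b.amplitudes).ravel()
    times = np.add.outer(a.times, b.times).ravel()
    order = np.argsort(times, kind="stable")
    amps, times = amps[order], times[order]
    merged_t: list[float] = []
    merged_a: list[float] = []
    for amp, t in zip(amps, times):
        if merged_t and t - merged_t[-1] <= _TIME_MERGE_TOL:
            merged_a[-1] += amp
        else:
            merged_t.append(t)
            merged_a.append(amp)
    return ImpulseTrain(amplitudes=tuple(merged_a), times=tuple(merged_t))


# ---------------------------------------------------------------------------
# Minimum jerk
# ---------------------------------------------------------------------------

def _mj_pos(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)


def _mj_vel(tau: np.ndarray) -> np.ndarray:
    out = 30.0 * tau ** 2 * (1.0 - tau) ** 2
    return np.where((tau < 0.0) | (tau > 1.0), 0.0, out)


def _mj_acc(tau: np.ndarray) -> np.ndarray:
    out = 60.0 * tau * (1.0 - tau) * (1.0 - 2.0 * tau)
    return np.where((tau < 0.0) | (tau > 1.0), 0.0, out)


@dataclass(frozen=True)
class NominalProfile:
    """Minimum-jerk point-to-point profile of duration D and displacement L."""

    D: float
    L: float
    step: float = DEFAULT_STEP

    def __post_init__(self):
        if not self.D > 0:
            raise ValueError("duration must be positive")

    @cached_property
    def t(self) -> np.ndarray:
        n = max(int(round(self.D / self.step)), 1)
        return np.arange(n + 1) * self.step

    @cached_property
    def position(self) -> np.ndarray:
        return self.pos(self.t)

    @cached_property
    def velocity(self) -> np.ndarray:
        return self.vel(self.t)

    @cached_property
    def acceleration(self) -> np.ndarray:
        return self.acc(self.t)

    def pos(self, t) -> np.ndarray:
        return self.L * _mj_pos(np.asarray(t, dtype=float) / self.D)

    def vel(self, t) -> np.ndarray:
        return (self.L / self.D) * _mj_vel(np.asarray(t, dtype=float) / self.D)

    def acc(self, t) -> np.ndarray:
        return (self.L / self.D ** 2) * _mj_acc(np.asarray(t, dtype=float) / self.D)


def min_jerk(duration: float, displacement: float,
             step: float = DEFAULT_STEP) -> NominalProfile:
    """Minimum-jerk profile x(tau) = L(10 tau^3 - 15 tau^4 + 6 tau^5)."""
    return NominalProfile(D=duration, L=displacement, step=step)


# ---------------------------------------------------------------------------
# Shaped commands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapedCommand:
    """Nominal profile convolved with an impulse train.

    ``duration`` is the nonzero support of the commanded velocity:
    nominal D plus the last impulse time.
    """

    train: ImpulseTrain
    nominal: NominalProfile

    @cached_property
    def t(self) -> np.ndarray:
        n = max(int(math.ceil(self.duration / self.step - 1e-9)), 1)
        return np.arange(n + 1) * self.step

    @cached_property
    def _sampled(self):
        return self.evaluate(self.t)

    @property
    def x0(self) -> np.ndarray:
        return self._sampled[0]

    @property
    def x0_dot(self) -> np.ndarray:
        return self._sampled[1]

    @property
    def x0_ddot(self) -> np.ndarray:
        return self._sampled[2]

    @property
    def duration(self) -> float:
        return self.nominal.D + self.train.t_last

    @property
    def displacement(self) -> float:
        return self.nominal.L

    @property
    def step(self) -> float:
        return self.nominal.step

    def evaluate(self, t):
        """Analytic (x0, x0_dot, x0_ddot) at arbitrary times.

        Outside [0, duration] the command holds its boundary values
        (position 0 before, L after; zero velocity/acceleration).
        """
        t = np.asarray(t, dtype=float)
        pos = np.zeros_like(t)
        vel = np.zeros_like(t)
        acc = np.zeros_like(t)
        for A, ti in zip(self.train.amplitudes, self.train.times):
            shifted = t - ti
            pos += A * self.nominal.pos(shifted)
            vel += A * self.nominal.vel(shifted)
            acc += A * self.nominal.acc(shifted)
        return pos, vel, acc


def shape(nominal: NominalProfile, train: ImpulseTrain) -> ShapedCommand:
    """Convolve a nominal profile with an impulse train."""
    return ShapedCommand(train=train, nominal=nominal)


def duration_sweep(mode: ModeSpec, L: float, n: int,
                   duration_range: tuple[float, float] = (0.75, 1.5),
                   step: float = DEFAULT_STEP) -> list[ShapedCommand]:
    """Shaped commands with total durations spanning multiples of the
    mode's undamped natural period (endpoints inclusive, evenly spaced)."""
    if n < 2:
        raise ValueError("need at least two durations")
    train = zv_impulses(mode)
    totals = np.linspace(duration_range[0] * mode.T_n,
                         duration_range[1] * mode.T_n, n)
    commands = []
    for total in totals:
        D = total - train.t_last
        if D <= 0:
            raise ValueError(
                f"total duration {total:.3f} s shorter than the shaper itself")
        commands.append(shape(min_jerk(D, L, step), train))
    return commands
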
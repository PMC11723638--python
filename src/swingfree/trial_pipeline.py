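"""End-to-end simulated trials and their on-disk format.

A trial plans a movement under an internal model, executes the plan on the
coupled *nonlinear* plant, and samples the result at the experimental rate
(120 Hz).  Records round-trip losslessly through a commented CSV dialect:

    # subject: S1
    # block: 3
    # ...
    t,F,x,xd,xdd,phi,phid,phidd
    0.0,...

Metadata lines are ``# key: value``; columns are matched by name.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_dynamics import (DEFAULT_STEP, ImpedanceParams, State,
                            SystemParams, simulate_coupled)
from .errors import TrialParseError
from .internal_models import InternalModelKind, plan

__all__ = ["TrialRecord", "simulate_trial", "write_trial", "read_trial",
           "DEFAULT_RATE", "SETTLE_TAIL"]

DEFAULT_RATE = 120.0
#: Post-command settling tail (s); covers the experiment's termination
#: window (velocity < 0.10 m/s for at least 1.00 s).
SETTLE_TAIL = 1.5

_COLUMNS = ("t", "F", "x", "xd", "xdd", "phi", "phid", "phidd")


@dataclass
class TrialRecord:
    """Sampled kinematics and force of one transport movement."""

    subject: str
    block: str
    trial_index: int
    rate: float
    t: np.ndarray
    F: np.ndarray
    x: np.ndarray
    xd: np.ndarray
    xdd: np.ndarray
    phi: np.ndarray
    phid: np.ndarray
    phidd: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.t)
        for name in _COLUMNS[1:]:
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has wrong length")
        if n >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.rate, rtol=0, atol=1e-9):
                raise ValueError("time grid must be uniform at 1/rate")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def displacement(self) -> float:
        return float(self.metadata.get("displacement", 0.25))

    def columns(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in _COLUMNS}

    def sliced(self, start: int, stop: int, **meta) -> "TrialRecord":
        """Sub-record over ``[start, stop)`` with time rebased to zero."""
        cols = {name: getattr(self, name)[start:stop].copy()
                for name in _COLUMNS}
        cols["t"] = cols["t"] - cols["t"][0]
        md = dict(self.metadata)
        md.update(meta)
        return TrialRecord(subject=self.subject, block=self.block,
                           trial_index=self.trial_index, rate=self.rate,
                           metadata=md, **cols)


def simulate_trial(kind: InternalModelKind,
                   params: SystemParams,
                   imp: ImpedanceParams,
                   D: float,
                   L: float,
                   extra_T: float = 0.0,
                   rate: float = DEFAULT_RATE,
                   step: float = DEFAULT_STEP,
                   settle: float = SETTLE_TAIL,
                   impulse_time_offsets=None,
                   subject: str = "sim",
                   block: str = "0",
                   trial_index: int = 0) -> TrialRecord:
    """Plan under ``kind`` and execute on the coupled nonlinear plant.

    ``extra_T`` delays the command start (system at rest before it), so the
    horizon is extra_T + command duration + settling tail.  The record is
    untrimmed and deterministic in its inputs.
    """
    if extra_T < 0:
        raise ValueError("extra_T must be non-negative")
    per_sample = 1.0 / (rate * step)
    if abs(per_sample - round(per_sample)) > 1e-9:
        raise ValueError("integration step must subdivide the sample rate")
    per_sample = int(round(per_sample))

    planned = plan(kind, params, imp, D, L, step=step,
                   impulse_time_offsets=impulse_time_offsets)
    horizon = extra_T + planned.command.duration + settle
    n_out = int(math.ceil(horizon * rate))
    horizon = n_out / rate

    traj = simulate_coupled(params, imp, planned.command,
                            lambda t: planned.fff_at(t), linear=False,
                            initial=State(), duration=horizon, step=step,
                            command_delay=extra_T)
    sel = slice(0, n_out * per_sample + 1, per_sample)
    meta = {
        "nominal_duration": D,
        "displacement": L,
        "extra_T": extra_T,
        "model": kind.value,
        "K": imp.K,
        "B": imp.B,
        "command_duration": planned.command.duration,
        "generator": "simulate_trial",
    }
    return TrialRecord(subject=subject, block=block, trial_index=trial_index,
                       rate=rate, t=traj.t[sel], F=traj.F[sel],
                       x=traj.x[sel], xd=traj.x_dot[sel], xdd=traj.x_ddot[sel],
                       phi=traj.phi[sel], phid=traj.phi_dot[sel],
                       phidd=traj.phi_ddot[sel], metadata=meta)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _format_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_trial(record: TrialRecord, path) -> None:
    """Write a record as commented-header CSV (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    buf.write(f"# subject: {record.subject}\n")
    buf.write(f"# block: {record.block}\n")
    buf.write(f"# trial_index: {record.trial_index}\n")
    buf.write(f"# rate: {_format_value(float(record.rate))}\n")
    for key, val in record.metadata.items():
        buf.write(f"# {key}: {_format_value(val)}\n")
    buf.write(",".join(_COLUMNS) + "\n")
    cols = record.columns()
    data = np.column_stack([cols[c] for c in _COLUMNS])
    for row in data:
        buf.write(",".join(repr(float(v)) for v in row) + "\n")
    path.write_text(buf.getvalue())


def _parse_meta_value(s: str):
    s = s.strip()
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def read_trial(path) -> TrialRecord:
    """Parse a trial CSV written by :func:`write_trial`.

    Columns are matched by header name (any order).  Malformed headers,
    missing columns or a non-uniform time grid raise
    :class:`~swingfree.errors.TrialParseError` naming the problem.
    """
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" not in body:
                raise TrialParseError(
                    f"{path.name}:{lineno}: malformed metadata line {line!r}")
            key, _, val = body.partition(":")
            meta[key.strip()] = _parse_meta_value(val)
        elif header is None:
            header = [c.strip() for c in line.split(",")]
        else:
            try:
                rows.append([float(v) for v in line.split(",")])
            except ValueError as exc:
                raise TrialParseError(
                    f"{path.name}:{lineno}: bad data row: {exc}") from None
    if header is None or not rows:
        raise TrialParseError(f"{path.name}: no data found")
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise TrialParseError(
            f"{path.name}: missing column(s) {', '.join(missing)}")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] != len(header):
        raise TrialParseError(f"{path.name}: ragged rows")
    cols = {name: np.ascontiguousarray(data[:, header.index(name)])
            for name in _COLUMNS}
    try:
        subject = str(meta.pop("subject"))
        block = str(meta.pop("block"))
        trial_index = int(meta.pop("trial_index"))
        rate = float(meta.pop("rate"))
    except KeyError as exc:
        raise TrialParseError(
            f"{path.name}: missing metadata key {exc.args[0]!r}") from None
    try:
        return TrialRecord(subject=subject, block=block,
                           trial_index=trial_index, rate=rate,
                           metadata=meta, **cols)
    except ValueError as exc:
        raise TrialParseError(f"{path.name}: {exc}") from None
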
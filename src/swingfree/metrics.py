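"""Per-trial performance measures and the fitting objective.

Trimming reproduces the experimental convention: a trial starts when cup
speed exceeds 0.02 m/s and ends at the first later sample with the cup fully
inside the target region and speed below 0.10 m/s.  Peak metrics, residual
ball angle, VAF and the weighted range-normalized RMSE objective operate on
trimmed records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core_dynamics import SystemParams
from .errors import UntrimmableError, ZeroVarianceError
from .trial_pipeline import TrialRecord

__all__ = [
    "MetricsRecord",
    "ObjectiveConfig",
    "TARGET_WIDTH",
    "CUP_WIDTH",
    "trim_trial",
    "peak_metrics",
    "residual_ball_angle",
    "vaf",
    "rmse_objective",
    "trial_metrics",
]

TARGET_WIDTH = 0.041   # m
CUP_WIDTH = 0.023      # m
START_THRESH = 0.02    # m/s
END_THRESH = 0.10      # m/s

#: Peak-detection prominence, as a fraction of the global velocity maximum.
PEAK_PROMINENCE_FRAC = 0.05


@dataclass
class MetricsRecord:
    """Summary measures of one trimmed trial."""

    duration: float                 # s
    peak1: float | None             # m/s (earlier peak)
    peak2: float | None             # m/s (later peak)
    peak_ratio: float | None        # peak1 / peak2
    interpeak_min: float | None     # m/s
    residual_angle: float           # deg
    trim_start: float               # s, in the untrimmed record's clock
    trim_end: float                 # s
    n_peaks: int = 0

    @property
    def peaks_defined(self) -> bool:
        return self.peak_ratio is not None


@dataclass(frozen=True)
class ObjectiveConfig:
    """Variables and weights entering the fitting objective.

    The main analysis weighs cup and ball kinematics symmetrically; the
    exact weighting used to produce the published fits is a supplementary
    detail, so it is exposed here as configuration.
    """

    weights: dict = field(default_factory=lambda: {
        "x": 1.0, "xd": 1.0, "phi": 1.0, "phid": 1.0})

    def __post_init__(self):
        if not self.weights:
            raise ValueError("need at least one variable")
        for k, w in self.weights.items():
            if not w > 0:
                raise ValueError(f"weight for {k!r} must be positive")


def trim_trial(record: TrialRecord,
               start_thresh: float = START_THRESH,
               end_thresh: float = END_THRESH,
               target_width: float = TARGET_WIDTH,
               cup_width: float = CUP_WIDTH,
               displacement: float | None = None) -> TrialRecord:
    """Trim a record to the movement proper.

    Start: first sample with |xd| > ``start_thresh``.  End: first subsequent
    sample with the cup fully inside the target region
    (|x - L| <= (target_width - cup_width)/2) and |xd| < ``end_thresh``.
    """
    L = record.displacement if displacement is None else displacement
    speed = np.abs(record.xd)
    moving = np.flatnonzero(speed > start_thresh)
    if moving.size == 0:
        raise UntrimmableError("no sample exceeds the start threshold")
    start = int(moving[0])
    half_margin = (target_width - cup_width) / 2.0
    inside = np.abs(record.x - L) <= half_margin
    ok = inside & (speed < end_thresh)
    ok[:start + 1] = False
    ends = np.flatnonzero(ok)
    if ends.size == 0:
        raise UntrimmableError("cup never settles inside the target region")
    end = int(ends[0])
    return record.sliced(start, end + 1,
                         trim_start=float(record.t[start]),
                         trim_end=float(record.t[end]),
                         trimmed=1)


def peak_metrics(record: TrialRecord,
                 prominence_frac: float = PEAK_PROMINENCE_FRAC):
    """Locate the two main velocity peaks and the minimum between them.

    Returns ``(peak1, peak2, ratio, interpeak_min, n_peaks)``; the first
    four are ``None`` when fewer than two peaks are found (flagged, not
    raised).
    """
    v = np.asarray(record.xd, dtype=float)
    vmax = v.max()
    if vmax <= 0:
        return None, None, None, None, 0
    idx, props = find_peaks(v, prominence=prominence_frac * vmax)
    if idx.size < 2:
        return None, None, None, None, int(idx.size)
    top2 = idx[np.argsort(v[idx])[-2:]]
    i1, i2 = int(top2.min()), int(top2.max())
    peak1, peak2 = float(v[i1]), float(v[i2])
    between = v[i1 + 1:i2]
    interpeak = float(between.min()) if between.size else None
    ratio = peak1 / peak2
    return peak1, peak2, ratio, interpeak, int(idx.size)


def residual_ball_angle(phi_f: float, phi_dot_f: float,
                        params: SystemParams,
                        step: float = 1e-3) -> float:
    """Residual ball angle in degrees.

    A free undamped *nonlinear* pendulum is initialized at the end-of-
    movement state and integrated for one small-oscillation period
    T_n = 2*pi*sqrt(l/g); the maximum |phi| attained is returned.
    """
    if not (math.isfinite(phi_f) and math.isfinite(phi_dot_f)):
        raise ValueError("end-of-movement state must be finite")
    g_over_l = params.g / params.l
    T = 2.0 * math.pi * math.sqrt(params.l / params.g)
    n = int(math.ceil(T / step))
    h = T / n
    p, pd = phi_f, phi_dot_f
    max_abs = abs(p)
    for _ in range(n):
        b1 = -g_over_l * math.sin(p)
        p2 = p + 0.5 * h * pd
        pd2 = pd + 0.5 * h * b1
        b2 = -g_over_l * math.sin(p2)
        p3 = p + 0.5 * h * pd2
        pd3 = pd + 0.5 * h * b2
        b3 = -g_over_l * math.sin(p3)
        p4 = p + h * pd3
        pd4 = pd + h * b3
        b4 = -g_over_l * math.sin(p4)
        p = p + (h / 6.0) * (pd + 2.0 * pd2 + 2.0 * pd3 + pd4)
        pd = pd + (h / 6.0) * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        max_abs = max(max_abs, abs(p))
    return math.degrees(max_abs)


def vaf(v_obs, v_sim) -> float:
    """Variance accounted for (percent), mean-removed and clamped at 0."""
    v = np.asarray(v_obs, dtype=float)
    vh = np.asarray(v_sim, dtype=float)
    if v.shape != vh.shape:
        raise ValueError("signals must have equal length")
    denom = np.sum((v - v.mean()) ** 2)
    if denom == 0:
        raise ZeroVarianceError("observed signal is constant; VAF undefined")
    resid = v - vh - v.mean() + vh.mean()
    return 100.0 * max(1.0 - np.sum(resid ** 2) / denom, 0.0)


def _resample(record: TrialRecord, t: np.ndarray, name: str) -> np.ndarray:
    col = getattr(record, name)
    return np.interp(t, record.t, col, left=col[0], right=col[-1])


def rmse_objective(obs: TrialRecord, sim: TrialRecord,
                   cfg: ObjectiveConfig = ObjectiveConfig()) -> float:
    """Weighted range-normalized root-sum-square error between records.

    Per variable: ``w * sqrt(sum((obs - sim)^2)) / (max(obs) - min(obs))``;
    the total is the sum over variables divided by the sum of the square
    roots of the weights.  The simulated record is linearly resampled onto
    the observed grid (edge values held); variables with zero observed range
    are skipped with a warning.
    """
    total = 0.0
    root_sum = 0.0
    for name, w in cfg.weights.items():
        v_obs = np.asarray(getattr(obs, name), dtype=float)
        rng = v_obs.max() - v_obs.min()
        root_sum += math.sqrt(w)
        if rng == 0:
            warnings.warn(f"variable {name!r} has zero range; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        v_sim = _resample(sim, obs.t, name)
        total += w * math.sqrt(np.sum((v_obs - v_sim) ** 2)) / rng
    return total / root_sum


def trial_metrics(record: TrialRecord, params: SystemParams,
                  trimmed: bool = False, **trim_kwargs) -> MetricsRecord:
    """Convenience: trim (unless already trimmed) and compute all measures."""
    rec = record if trimmed else trim_trial(record, **trim_kwargs)
    peak1, peak2, ratio, interpeak, n_peaks = peak_metrics(rec)
    angle = residual_ball_angle(float(rec.phi[-1]), float(rec.phid[-1]), params)
    return MetricsRecord(
        duration=rec.duration,
        peak1=peak1, peak2=peak2, peak_ratio=ratio, interpeak_min=interpeak,
        residual_angle=angle,
        trim_start=float(rec.metadata.get("trim_start", rec.t[0])),
        trim_end=float(rec.metadata.get("trim_end", rec.t[-1])),
        n_peaks=n_peaks)
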
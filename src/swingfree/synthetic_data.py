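"""Surrogate subjects and blocks of trials for end-to-end testing.

Trials are generated by the deterministic simulation pipeline with
human-like variability injected at the command level — per-trial impedance
draws, impulse-time jitter and movement-duration jitter — plus additive
white measurement noise on cup velocity and ball angle.  Every trial's true
generating parameters are stored in its metadata and in a ``truth.csv``
table so downstream parameter-recovery can be scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_dynamics import DEFAULT_STEP, ImpedanceParams, SystemParams
from .internal_models import InternalModelKind, build_train
from .trial_pipeline import TrialRecord, simulate_trial, write_trial

__all__ = ["GeneratorConfig", "generate_trial", "generate_dataset"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Distributional structure of a surrogate dataset.

    ``block_durations`` maps block name to the nominal *total* movement
    duration (s); the defaults mirror the 1.40 s / 1.20 s testing blocks.
    ``stiffness_duration`` optionally couples mean stiffness to the drawn
    duration as K(D) = a*exp(-b*D) (off by default).
    """

    kind: InternalModelKind = InternalModelKind.RIGID_BODY
    mean_K: float = 150.0            # N/m
    mean_B: float = 5.0              # Ns/m
    sigma_KB_frac: float = 0.1       # log-normal spread (fraction)
    time_jitter: float = 0.01        # s, SD of impulse-time jitter
    duration_jitter: float = 0.02    # s, SD of nominal-duration jitter
    noise_xd: float = 0.002          # m/s, white noise SD on cup velocity
    noise_phi: float = 0.002         # rad, white noise SD on ball angle
    L: float = 0.25                  # m
    block_durations: dict = field(
        default_factory=lambda: {"3": 1.40, "4": 1.20})
    trials_per_block: int = 50
    seed: int = 0
    stiffness_duration: tuple[float, float] | None = None  # (a, b)

    def __post_init__(self):
        for name in ("sigma_KB_frac", "time_jitter", "duration_jitter",
                     "noise_xd", "noise_phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(d <= 0 for d in self.block_durations.values()):
            raise ValueError("block durations must be positive")


def _trial_rng(cfg: GeneratorConfig, subject: int, block: str,
               index: int) -> np.random.Generator:
    # counter-based substream: independent of generation order and of the
    # process hash seed (crc32 is stable, str.__hash__ is not)
    block_key = zlib.crc32(str(block).encode())
    return np.random.default_rng([cfg.seed, subject, block_key, index])


def generate_trial(cfg: GeneratorConfig, subject: int, block: str,
                   index: int, params: SystemParams = SystemParams(),
                   step: float = DEFAULT_STEP) -> TrialRecord:
    """Draw per-trial parameters and simulate one noisy trial.

    With all spreads zero the output equals the deterministic
    ``simulate_trial`` record for the configured means.
    """
    rng = _trial_rng(cfg, subject, block, index)
    D_total = cfg.block_durations[str(block)]
    D_total = D_total + cfg.duration_jitter * rng.standard_normal()

    mean_K = cfg.mean_K
    if cfg.stiffness_duration is not None:
        a, b = cfg.stiffness_duration
        mean_K = a * np.exp(-b * D_total)
    sig = cfg.sigma_KB_frac
    K = float(mean_K * np.exp(sig * rng.standard_normal()))
    B = float(cfg.mean_B * np.exp(sig * rng.standard_normal()))
    imp = ImpedanceParams(K=K, B=B)

    train = build_train(cfg.kind, params, imp)
    offsets = cfg.time_jitter * rng.standard_normal(len(train))
    D_nom = max(D_total - train.t_last, 0.3)

    record = simulate_trial(cfg.kind, params, imp, D=D_nom, L=cfg.L,
                            step=step, impulse_time_offsets=offsets,
                            subject=f"S{subject}", block=str(block),
                            trial_index=index)
    if cfg.noise_xd > 0:
        record.xd = record.xd + cfg.noise_xd * rng.standard_normal(len(record.t))
    if cfg.noise_phi > 0:
        record.phi = record.phi + cfg.noise_phi * rng.standard_normal(len(record.t))
    record.metadata.update(
        true_K=K, true_B=B, true_D_total=float(D_total),
        generator="synthetic", root_seed=cfg.seed)
    return record


def generate_dataset(cfg: GeneratorConfig, out_dir, n_subjects: int,
                     trials_per_block: int | None = None,
                     params: SystemParams = SystemParams(),
                     step: float = DEFAULT_STEP) -> pd.DataFrame:
    """Write ``data/<subject>/<block>/trial_<n>.csv`` plus ``truth.csv``.

    Returns the truth table (one row per trial with true K, B, duration and
    model kind).  Byte-identical across runs with the same configuration.
    """
    out_dir = Path(out_dir)
    n_trials = cfg.trials_per_block if trials_per_block is None \
        else trials_per_block
    rows = []
    for s in range(1, n_subjects + 1):
        for block in cfg.block_durations:
            for i in range(n_trials):
                rec = generate_trial(cfg, s, block, i, params=params,
                                     step=step)
                rel = Path(f"S{s}") / str(block) / f"trial_{i}.csv"
                write_trial(rec, out_dir / rel)
                rows.append({
                    "subject": f"S{s}", "block": str(block),
                    "trial_index": i, "file": str(rel),
                    "model": cfg.kind.value,
                    "true_K": rec.metadata["true_K"],
                    "true_B": rec.metadata["true_B"],
                    "true_D_total": rec.metadata["true_D_total"],
                })
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return truth
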
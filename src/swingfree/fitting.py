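"""Fit internal models to trials by derivative-free global optimization.

Free parameters per trial x model are hand stiffness K, damping B and the
extra duration T (ms) restoring the command time lost to threshold trimming:
a candidate command lasts (observed trimmed duration + T), is executed from
rest on the nonlinear plant, trimmed with the same thresholds as the data,
and scored with the weighted range-normalized RMSE objective.

The optimizer is a controlled random search (CRS2) with local mutation,
re-implemented here; any minimizer honouring the same contract can be
substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_dynamics import DEFAULT_STEP, ImpedanceParams, SystemParams
from .errors import (DegenerateModeError, FitFailureError, IntegrationError,
                     SwingfreeError, UntrimmableError)
from .internal_models import InternalModelKind, build_train
from .metrics import ObjectiveConfig, rmse_objective, trim_trial, vaf
from .trial_pipeline import TrialRecord, simulate_trial

__all__ = ["FitBounds", "FitResult", "crs2_minimize", "fit_trial",
           "fit_dataset"]

_PENALTY = 1.0e6
_MIN_NOMINAL = 0.05  # s; shortest admissible min-jerk duration


@dataclass(frozen=True)
class FitBounds:
    """Box bounds and initial guesses for the fit parameters."""

    B_range: tuple[float, float] = (0.0, 100.0)     # Ns/m
    K_range: tuple[float, float] = (0.0, 1000.0)    # N/m
    T_range: tuple[float, float] = (0.0, 1000.0)    # ms
    init_B: float = 10.0
    init_K: float = 100.0

    def as_arrays(self):
        lo = np.array([self.K_range[0], self.B_range[0], self.T_range[0]])
        hi = np.array([self.K_range[1], self.B_range[1], self.T_range[1]])
        return lo, hi


@dataclass
class FitResult:
    """Best-fit parameters for one trial under one internal model."""

    kind: InternalModelKind
    K: float               # N/m
    B: float               # Ns/m
    T: float               # ms
    objective: float
    vaf: float             # percent, cup velocity
    evaluations: int
    seed: object

    def __post_init__(self):
        if not np.isfinite(self.objective):
            raise ValueError("objective must be finite")


def crs2_minimize(objective, lower, upper, budget: int, seed,
                  ftol: float = 1e-6, pop_factor: int = 10):
    """Controlled random search (CRS2) with local mutation.

    Population of ``pop_factor*(n+1)`` points uniform in the box.  Each
    iteration reflects a random simplex through the centroid of n points
    anchored at the best point; rejected trial points are retried with a
    random coordinate-wise mutation pulled toward the best point.  Stops at
    the evaluation budget or when the population's objective spread falls
    below ``ftol`` relative to the best value.

    Returns ``(x_best, f_best, evaluations)``; deterministic given ``seed``.
    """
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    if lo.shape != hi.shape or np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)):
        raise ValueError("bounds must be finite arrays of equal shape")
    n = lo.size
    pop_size = pop_factor * (n + 1)
    if budget < pop_size:
        raise ValueError(
            f"budget {budget} below population size {pop_size}")
    rng = np.random.default_rng(seed)
    pop = lo + rng.random((pop_size, n)) * (hi - lo)
    fvals = np.array([float(objective(p)) for p in pop])
    evals = pop_size

    while evals < budget:
        i_best = int(np.argmin(fvals))
        i_worst = int(np.argmax(fvals))
        spread = fvals[i_worst] - fvals[i_best]
        if spread <= ftol * max(abs(fvals[i_best]), 1e-12):
            break
        # simplex: best point plus n distinct others
        others = rng.choice(pop_size - 1, size=n, replace=False)
        others = np.where(others >= i_best, others + 1, others)
        simplex = np.vstack([pop[i_best], pop[others]])
        centroid = simplex[:n].mean(axis=0)
        trial = 2.0 * centroid - simplex[n]
        accepted = False
        if np.all(trial >= lo) and np.all(trial <= hi):
            f_trial = float(objective(trial))
            evals += 1
            if f_trial < fvals[i_worst]:
                pop[i_worst] = trial
                fvals[i_worst] = f_trial
                accepted = True
        if not accepted and evals < budget:
            # local mutation toward the best point
            omega = rng.random(n)
            mutant = (1.0 + omega) * pop[i_best] - omega * trial
            mutant = np.clip(mutant, lo, hi)
            f_mut = float(objective(mutant))
            evals += 1
            if f_mut < fvals[i_worst]:
                pop[i_worst] = mutant
                fvals[i_worst] = f_mut

    i_best = int(np.argmin(fvals))
    return pop[i_best].copy(), float(fvals[i_best]), evals


def _candidate_trial(theta, obs: TrialRecord, kind: InternalModelKind,
                     params: SystemParams, step: float):
    """Simulate and trim one candidate; raises on degenerate/failed cases."""
    K, B, T_ms = float(theta[0]), float(theta[1]), float(theta[2])
    imp = ImpedanceParams(K=K, B=B)
    train = build_train(kind, params, imp)
    D_nom = obs.duration + T_ms / 1000.0 - train.t_last
    if D_nom < _MIN_NOMINAL:
        raise DegenerateModeError("candidate command shorter than its shaper")
    sim = simulate_trial(kind, params, imp, D=D_nom, L=obs.displacement,
                         rate=obs.rate, step=step)
    return trim_trial(sim, displacement=obs.displacement)


def fit_trial(obs: TrialRecord, kind: InternalModelKind,
              params: SystemParams,
              bounds: FitBounds = FitBounds(),
              cfg: ObjectiveConfig = ObjectiveConfig(),
              budget: int = 3000,
              seed=0,
              step: float = DEFAULT_STEP) -> FitResult:
    """Fit (K, B, T) of one internal model to one trimmed trial."""
    if not obs.metadata.get("trimmed"):
        raise ValueError("observed record must be trimmed first")
    failures = {"degenerate": 0, "untrimmable": 0, "integration": 0}

    def objective(theta) -> float:
        try:
            sim = _candidate_trial(theta, obs, kind, params, step)
        except DegenerateModeError:
            failures["degenerate"] += 1
            return _PENALTY
        except UntrimmableError:
            failures["untrimmable"] += 1
            return _PENALTY
        except IntegrationError:
            failures["integration"] += 1
            return _PENALTY
        return rmse_objective(obs, sim, cfg)

    lo, hi = bounds.as_arrays()
    best, f_best, evals = crs2_minimize(objective, lo, hi, budget, seed)
    if f_best >= _PENALTY:
        raise FitFailureError(
            f"all candidates failed for model {kind.value}",
            diagnostics=failures)
    sim_best = _candidate_trial(best, obs, kind, params, step)
    v_sim = np.interp(obs.t, sim_best.t, sim_best.xd,
                      left=sim_best.xd[0], right=sim_best.xd[-1])
    return FitResult(kind=kind, K=float(best[0]), B=float(best[1]),
                     T=float(best[2]), objective=f_best,
                     vaf=vaf(obs.xd, v_sim), evaluations=evals, seed=seed)


def fit_dataset(trials, kinds, params: SystemParams,
                bounds: FitBounds = FitBounds(),
                cfg: ObjectiveConfig = ObjectiveConfig(),
                budget: int = 3000,
                root_seed: int = 0,
                step: float = DEFAULT_STEP) -> pd.DataFrame:
    """Fit every model in ``kinds`` to every trial.

    Seeds are derived per (trial, model) by counter so results do not depend
    on iteration order.  Per-trial failures are recorded as rows with
    ``status != "ok"`` rather than aborting the sweep.
    """
    kinds = list(kinds)
    rows = []
    for ti, obs in enumerate(trials):
        for ki, kind in enumerate(kinds):
            seed = [root_seed, ti, ki]
            row = {
                "subject": obs.subject, "block": obs.block,
                "trial_index": obs.trial_index, "model": kind.value,
                "duration": obs.duration,
            }
            try:
                res = fit_trial(obs, kind, params, bounds=bounds, cfg=cfg,
                                budget=budget, seed=seed, step=step)
                row.update(status="ok", K=res.K, B=res.B, T=res.T,
                           objective=res.objective, vaf=res.vaf,
                           evaluations=res.evaluations)
            except (FitFailureError, SwingfreeError, ValueError) as exc:
                row.update(status=type(exc).__name__, K=np.nan, B=np.nan,
                           T=np.nan, objective=np.nan, vaf=np.nan,
                           evaluations=0)
            rows.append(row)
    return pd.DataFrame(rows)
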
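"""Fitting signalling-threshold parameters to observed first-arrest data.

The fit minimises a rank-ordered squared-error objective: order the n
first-arrest generations of each of N simulation replicates and compare
them, rank by rank, with the ordered experimental generations,

    e(theta) = sum_j sum_i (G(i, j; theta) - Gbar(i))^2,

where G(i, j) is the i-th smallest simulated arrest generation of replicate
j and Gbar(i) the i-th smallest experimental one.

Telomere length paths do not depend on the signalling parameters, so one
frozen block of N x n simulated trajectories (with per-division uniforms)
serves every candidate evaluation — common random numbers turn the
stochastic objective into a deterministic surface suitable for a
derivative-free global optimizer (differential evolution, multiple
restarts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .stats import rank_envelope
from .telomeres import (
    DeterministicThreshold,
    ProbabilisticThreshold,
    TelomereModelParams,
    simulate_length_paths,
)

__all__ = [
    "FitObjectiveConfig",
    "ThresholdFitResult",
    "PathBank",
    "build_path_bank",
    "trigger_generations",
    "objective_e",
    "fit_deterministic",
    "fit_probabilistic",
    "envelope_comparison",
]


@dataclass(frozen=True)
class FitObjectiveConfig:
    """Objective configuration: N simulation replicates of n lineages each,
    evaluated with common random numbers by default."""

    N: int = 1000
    n: int = 115
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.N < 1 or self.n < 1:
            raise ValueError("N and n must be >= 1")


@dataclass(frozen=True)
class ThresholdFitResult:
    params: dict
    objective: float
    n_evaluations: int
    trace: tuple[float, ...]  # best-so-far objective values
    seed: int | None = None
    config: FitObjectiveConfig = field(default=FitObjectiveConfig(), compare=False)


@dataclass(frozen=True)
class PathBank:
    """Frozen block of N*n shortest/second-shortest telomere trajectories."""

    l1: np.ndarray  # (N*n, T)
    l2: np.ndarray
    u: np.ndarray
    N: int
    n: int


def build_path_bank(
    model_params: TelomereModelParams,
    config: FitObjectiveConfig,
    seed: int | np.random.Generator | None,
) -> PathBank:
    rng = np.random.default_rng(seed)
    l1, l2, u = simulate_length_paths(model_params, config.N * config.n, rng)
    return PathBank(l1=l1, l2=l2, u=u, N=config.N, n=config.n)


def trigger_generations(bank: PathBank, threshold) -> np.ndarray:
    """First-trigger generation per path under a candidate threshold,
    shaped (N, n) and sorted ascending within each replicate."""
    if isinstance(threshold, DeterministicThreshold):
        cond = bank.l1 + threshold.alpha * bank.l2 <= threshold.l_min
    elif isinstance(threshold, ProbabilisticThreshold):
        p = threshold.amplitude_b * np.exp(-threshold.decay_a * bank.l1)
        cond = (bank.u < p) | (bank.l1 <= 0.0)
    else:
        raise TypeError(f"unknown threshold type {type(threshold)!r}")
    any_hit = cond.any(axis=1)
    gens = np.where(any_hit, cond.argmax(axis=1) + 1, bank.l1.shape[1] + 1)
    out = gens.reshape(bank.N, bank.n).astype(float)
    out.sort(axis=1)
    return out


def objective_e(
    sim_ordered_sets: np.ndarray | Sequence[Sequence[float]],
    experimental_ordered: Sequence[float],
) -> float:
    """Sum over replicates and ranks of squared rank-wise differences."""
    sims = np.asarray(sim_ordered_sets, dtype=float)
    if sims.ndim == 1:
        sims = sims[None, :]
    exp = np.asarray(experimental_ordered, dtype=float)
    if sims.shape[1] != exp.size:
        raise ValueError(
            f"length mismatch: simulations have n={sims.shape[1]}, "
            f"experimental has n={exp.size}"
        )
    return float(((sims - exp[None, :]) ** 2).sum())


def _fit(
    make_threshold,
    experimental_ordered: Sequence[float],
    model_params: TelomereModelParams,
    bounds: Sequence[tuple[float, float]],
    config: FitObjectiveConfig,
    seed: int | None,
    n_restarts: int = 3,
) -> ThresholdFitResult:
    exp = np.sort(np.asarray(experimental_ordered, dtype=float))
    if exp.size != config.n:
        config = FitObjectiveConfig(
            N=config.N, n=exp.size, common_random_numbers=config.common_random_numbers
        )
    bank = build_path_bank(model_params, config, seed)

    evals = {"count": 0}
    trace: list[float] = []

    def objective(theta: np.ndarray) -> float:
        theta = np.clip(theta, [b[0] for b in bounds], [b[1] for b in bounds])
        thr = make_threshold(theta)
        if not config.common_random_numbers:
            local = build_path_bank(
                model_params, config, None if seed is None else seed + evals["count"]
            )
            val = objective_e(trigger_generations(local, thr), exp)
        else:
            val = objective_e(trigger_generations(bank, thr), exp)
        evals["count"] += 1
        if not trace or val < trace[-1]:
            trace.append(val)
        else:
            trace.append(trace[-1])
        return val

    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.allclose(lo, hi):
        val = objective(lo)
        thr = make_threshold(lo)
        return ThresholdFitResult(
            params=_threshold_params(thr), objective=val,
            n_evaluations=evals["count"], trace=tuple(trace), seed=seed, config=config,
        )

    best_x, best_val = None, np.inf
    for r in range(n_restarts):
        rseed = None if seed is None else (seed + 7919 * (r + 1)) % (2**31)
        sol = optimize.differential_evolution(
            objective,
            bounds=list(bounds),
            seed=rseed,
            maxiter=40,
            popsize=12,
            tol=1e-6,
            polish=False,
            init="sobol",
        )
        if sol.fun < best_val:
            best_val, best_x = float(sol.fun), np.asarray(sol.x)
    thr = make_threshold(best_x)
    return ThresholdFitResult(
        params=_threshold_params(thr),
        objective=best_val,
        n_evaluations=evals["count"],
        trace=tuple(trace),
        seed=seed,
        config=config,
    )


def _threshold_params(thr) -> dict:
    if isinstance(thr, DeterministicThreshold):
        return {"alpha": thr.alpha, "l_min": thr.l_min}
    return {"decay_a": thr.decay_a, "amplitude_b": thr.amplitude_b}


def fit_deterministic(
    experimental_ordered: Sequence[float],
    model_params: TelomereModelParams | None = None,
    bounds: Sequence[tuple[float, float]] = ((0.0, 2.0), (0.0, 200.0)),
    config: FitObjectiveConfig | None = None,
    seed: int | None = None,
) -> ThresholdFitResult:
    """Fit (alpha, L_min) of the deterministic shortest-telomere threshold."""
    model_params = model_params or TelomereModelParams()
    config = config or FitObjectiveConfig()
    return _fit(
        lambda th: DeterministicThreshold(alpha=float(th[0]), l_min=float(th[1])),
        experimental_ordered, model_params, bounds, config, seed,
    )


def fit_probabilistic(
    experimental_ordered: Sequence[float],
    model_params: TelomereModelParams | None = None,
    bounds: Sequence[tuple[float, float]] = ((1e-4, 0.2), (1e-4, 1.0 - 1e-9)),
    config: FitObjectiveConfig | None = None,
    seed: int | None = None,
) -> ThresholdFitResult:
    """Fit (decay_a, amplitude_b) of the probabilistic length threshold."""
    model_params = model_params or TelomereModelParams()
    config = config or FitObjectiveConfig()
    return _fit(
        lambda th: ProbabilisticThreshold(
            decay_a=float(th[0]), amplitude_b=float(min(th[1], 1.0 - 1e-12))
        ),
        experimental_ordered, model_params, bounds, config, seed,
    )


def envelope_comparison(
    threshold,
    model_params: TelomereModelParams,
    experimental_ordered: Sequence[float],
    N: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-rank quantile band of N fresh ordered simulations vs the data.

    Returns a table with, per rank, the experimental value, band bounds and
    an inside/outside flag; the fraction inside is in ``df.attrs``.
    """
    exp = np.sort(np.asarray(experimental_ordered, dtype=float))
    config = FitObjectiveConfig(N=N, n=exp.size)
    bank = build_path_bank(model_params, config, seed)
    sims = trigger_generations(bank, threshold)
    band = rank_envelope(sims, level=level)
    inside = band.contains(exp)
    df = pd.DataFrame(
        {
            "rank": np.arange(1, exp.size + 1),
            "experimental": exp,
            "lower": band.lower,
            "upper": band.upper,
            "inside": inside,
        }
    )
    df.attrs["fraction_inside"] = float(inside.mean())
    return df
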
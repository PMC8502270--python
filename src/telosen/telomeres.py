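"""Mechanistic telomere-shortening simulator with pluggable signalling rules.

Each cell carries 32 telomeres (16 chromosomes, two ends). Without
telomerase, at each division every telomere either loses twice the
per-division shortening rate (the lagging-strand end) or stays unchanged,
with probability 1/2 each — the asymmetric end-replication problem. One
daughter is followed, defining a lineage.

Cell-cycle arrest signalling is driven by the shortest telomere length L1
(and optionally the second shortest L2):

* deterministic threshold — the arrest triggers at the first division where
  L1 + alpha * L2 <= L_min;
* probabilistic threshold — at each division the arrest triggers with
  probability p(L1) = b * exp(-a * L1), with a forced trigger at L1 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "TelomereModelParams",
    "DeterministicThreshold",
    "ProbabilisticThreshold",
    "sample_initial_state",
    "divide",
    "signal_probability",
    "simulate_first_signal_generation",
    "simulate_ordered_set",
    "simulate_length_paths",
]


@dataclass(frozen=True)
class TelomereModelParams:
    """Configuration of the telomere-shortening model.

    Parameters
    ----------
    n_telomeres : int
        Telomeres per cell (32 for budding yeast: 16 chromosomes x 2 ends).
    shortening_rate : float
        Mean loss in bp per telomere per division; a shortened end loses
        twice this amount, the other half of the ends lose nothing.
    initial_distribution : dict
        Initial-length sampler. ``{"mode": "surrogate", "loc", "spread"}``
        draws i.i.d. truncated-normal lengths; ``{"mode": "stationary", ...}``
        runs a telomerase-positive burn-in with length-dependent preferential
        elongation of short telomeres and samples its steady state (keys:
        ``elong_midpoint``, ``elong_width``, ``elong_bp``, ``burn_in``).
    exact_half : bool
        If True, exactly half of the telomeres shorten each division (a
        random subset); default is independent Bernoulli(1/2) per telomere.
    """

    n_telomeres: int = 32
    shortening_rate: float = 3.0
    initial_distribution: dict = field(
        default_factory=lambda: {"mode": "surrogate", "loc": 300.0, "spread": 75.0}
    )
    max_generations: int = 1000
    exact_half: bool = False

    def __post_init__(self) -> None:
        if self.n_telomeres % 2 != 0 or self.n_telomeres < 2:
            raise ValueError("n_telomeres must be a positive even count")
        if not self.shortening_rate > 0:
            raise ValueError("shortening_rate must be > 0")


@dataclass(frozen=True)
class DeterministicThreshold:
    """Arrest iff L1 + alpha * L2 <= L_min (trigger when reached)."""

    alpha: float = 0.0
    l_min: float = 61.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.l_min < 0:
            raise ValueError("alpha and l_min must be non-negative")


@dataclass(frozen=True)
class ProbabilisticThreshold:
    """Arrest probability per division p(L1) = amplitude_b * exp(-decay_a * L1).

    A telomere at 0 bp triggers the arrest with certainty, regardless of
    the distribution.
    """

    decay_a: float = 0.023
    amplitude_b: float = 0.276

    def __post_init__(self) -> None:
        if not self.decay_a > 0:
            raise ValueError("decay_a must be > 0")
        if not 0.0 < self.amplitude_b < 1.0:
            raise ValueError("amplitude_b must be in (0, 1)")


Threshold = Union[DeterministicThreshold, ProbabilisticThreshold]


def _elongation_step(
    lengths: np.ndarray, params: TelomereModelParams, cfg: dict, rng: np.random.Generator
) -> np.ndarray:
    """One telomerase-positive update: asymmetric shortening plus
    length-dependent elongation favouring short telomeres."""
    lengths = divide(lengths, params, rng)
    mid = cfg.get("elong_midpoint", 220.0)
    width = cfg.get("elong_width", 30.0)
    add = cfg.get("elong_bp", 40.0)
    p_elong = 1.0 / (1.0 + np.exp((lengths - mid) / width))
    elong = rng.random(lengths.size) < p_elong
    return lengths + add * elong


def sample_initial_state(
    params: TelomereModelParams, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw the 32 initial telomere lengths.

    Surrogate mode: i.i.d. normal(loc, spread) truncated at 0 (a configurable
    stand-in for the steady-state length distribution under telomerase).
    Stationary mode: long burn-in of the telomerase-positive chain with
    preferential elongation of short telomeres, then one state is sampled.
    """
    rng = np.random.default_rng(rng)
    cfg = params.initial_distribution
    mode = cfg.get("mode")
    if mode == "surrogate":
        loc = float(cfg.get("loc", 300.0))
        spread = float(cfg.get("spread", 75.0))
        if spread == 0:
            return np.full(params.n_telomeres, loc, dtype=float)
        return np.clip(rng.normal(loc, spread, size=params.n_telomeres), 0.0, None)
    if mode == "stationary":
        burn_in = int(cfg.get("burn_in", 500))
        lengths = np.full(params.n_telomeres, float(cfg.get("start", 300.0)))
        for _ in range(burn_in):
            lengths = _elongation_step(lengths, params, cfg, rng)
        return lengths
    raise ValueError(f"unconfigured initial distribution mode {mode!r}")


def divide(
    state: np.ndarray,
    params: TelomereModelParams,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One telomerase-negative division of the followed daughter.

    Each telomere independently loses 2 * shortening_rate bp with
    probability 1/2 (exactly half of them with ``exact_half``); lengths are
    clamped at 0.
    """
    rng = np.random.default_rng(rng)
    state = np.asarray(state, dtype=float)
    n = state.size
    if params.exact_half:
        shorten = np.zeros(n, dtype=bool)
        shorten[rng.permutation(n)[: n // 2]] = True
    else:
        shorten = rng.random(n) < 0.5
    return np.clip(state - 2.0 * params.shortening_rate * shorten, 0.0, None)


def signal_probability(state: np.ndarray, threshold: Threshold) -> float:
    """Probability that the current state signals an arrest at this division."""
    lengths = np.sort(np.asarray(state, dtype=float))
    l1 = lengths[0]
    if isinstance(threshold, DeterministicThreshold):
        l2 = lengths[1] if lengths.size > 1 else 0.0
        return 1.0 if l1 + threshold.alpha * l2 <= threshold.l_min else 0.0
    if l1 <= 0.0:
        return 1.0
    return float(min(1.0, threshold.amplitude_b * np.exp(-threshold.decay_a * l1)))


def simulate_first_signal_generation(
    params: TelomereModelParams,
    threshold: Threshold,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Generation of the first arrest signal in one simulated lineage.

    Returns ``params.max_generations + 1`` when no trigger occurred within
    the cap (a censored draw).
    """
    rng = np.random.default_rng(rng)
    state = sample_initial_state(params, rng)
    for gen in range(1, params.max_generations + 1):
        state = divide(state, params, rng)
        p = signal_probability(state, threshold)
        if p >= 1.0 or (p > 0.0 and rng.random() < p):
            return gen
    return params.max_generations + 1


def simulate_ordered_set(
    n: int,
    params: TelomereModelParams,
    threshold: Threshold,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """n independent first-signal generations, sorted ascending."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    gens = [simulate_first_signal_generation(params, threshold, rng) for _ in range(n)]
    return np.sort(np.asarray(gens, dtype=int))


def simulate_length_paths(
    params: TelomereModelParams,
    n_paths: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-simulated shortest/second-shortest length trajectories.

    Telomere shortening does not depend on the signalling rule, so length
    paths can be generated once and shared across candidate threshold
    parameters (common random numbers). Returns arrays ``l1``, ``l2`` of
    shape (n_paths, T) — T capped at ``max_generations`` and truncated once
    every path's shortest telomere has reached 0, after which values stay at
    their final state — plus per-division uniforms ``u`` of the same shape
    for probabilistic-trigger evaluation.
    """
    rng = np.random.default_rng(rng)
    states = np.stack(
        [sample_initial_state(params, rng) for _ in range(n_paths)], axis=0
    )
    l1_steps: list[np.ndarray] = []
    l2_steps: list[np.ndarray] = []
    for _ in range(params.max_generations):
        shorten = rng.random(states.shape) < 0.5
        states = np.clip(states - 2.0 * params.shortening_rate * shorten, 0.0, None)
        two = np.partition(states, 1, axis=1)[:, :2]
        two.sort(axis=1)
        l1_steps.append(two[:, 0].copy())
        l2_steps.append(two[:, 1].copy())
        if np.all(two[:, 1] <= 0.0):
            # once even the second-shortest telomere is gone, every
            # signalling rule with l_min >= 0 has triggered
            break
    l1 = np.stack(l1_steps, axis=1)
    l2 = np.stack(l2_steps, axis=1)
    u = rng.random(l1.shape)
    return l1, l2, u
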
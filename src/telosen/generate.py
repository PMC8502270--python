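"""Synthetic lineage-dataset generator.

Produces full lineage tables with the statistical structure the analyses
assume, so every pipeline stage runs without the original microfluidics
dataset:

* telomerase-positive lineages — tightly distributed normal cycle
  durations with a rare, generation-independent long cycle;
* telomerase-negative lineages — telomere shortening (mechanistic
  simulator) drives non-terminal arrest episodes via a probabilistic
  shortest-telomere threshold; each episode ends by repair with a constant
  per-generation probability, after which the signalling telomere is
  re-elongated and normal divisions resume; once the shortest telomere
  reaches a deterministic senescence threshold the lineage enters a
  terminal run of long cycles ending in death, with a much longer final
  cycle.

As the shortest telomere approaches the senescence threshold the generator
inserts moderately long "slowdown" cycles (~210 min), so at low duration
thresholds the terminal run is a hitting-time count rather than a
geometric one — matching the qualitative contrast between non-terminal and
terminal run-length laws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .lineages import (
    FATE_CENSORED,
    FATE_DIED,
    CellCycle,
    Lineage,
    LineageSet,
)
from .telomeres import (
    DeterministicThreshold,
    ProbabilisticThreshold,
    TelomereModelParams,
    divide,
    sample_initial_state,
    signal_probability,
)

__all__ = [
    "GeneratorConfig",
    "generate_negative_lineage",
    "generate_positive_lineage",
    "generate_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator configuration.

    Duration distributions are either normal ``(loc, spread)`` tuples or
    shifted lognormal dicts ``{"shift", "median", "sigma"}`` (median of the
    total duration = shift + median). Defaults are chosen so the headline
    statistics of the analyses are reproduced qualitatively: normal cycles
    90/30 min (mean + 3 SD = 180), non-terminal arrest cycles with median
    250 min, terminal preceding/final cycles with medians 290/730 min,
    repair probability 0.65 per generation, probabilistic first-arrest
    threshold (0.023 /bp, 0.276) and deterministic senescence threshold at
    19 bp.
    """

    n_negative: int = 187
    n_positive: int = 31
    normal_cycle: tuple[float, float] = (90.0, 30.0)
    arrest_cycle: dict = field(
        default_factory=lambda: {"shift": 180.0, "median": 70.0, "sigma": 0.6}
    )
    terminal_preceding_cycle: dict = field(
        default_factory=lambda: {"shift": 180.0, "median": 110.0, "sigma": 0.5}
    )
    terminal_final_cycle: dict = field(
        default_factory=lambda: {"shift": 180.0, "median": 550.0, "sigma": 0.4}
    )
    slowdown_cycle: tuple[float, float] = (215.0, 12.0)
    slowdown_length: float = 30.0
    repair_q: float = 0.65
    terminal_stop_q: float = 0.58
    nonterminal_threshold: ProbabilisticThreshold = field(
        default_factory=ProbabilisticThreshold
    )
    terminal_threshold: DeterministicThreshold = field(
        default_factory=lambda: DeterministicThreshold(alpha=0.0, l_min=19.0)
    )
    telomere_params: TelomereModelParams = field(default_factory=TelomereModelParams)
    repair_rule: str = "elongate"  # or "refractory"
    repair_elongation_bp: float = 100.0
    refractory_generations: int = 5
    positive_long_prob: float = 0.002
    positive_n_cycles: int = 78
    censor_fraction: float = 0.1
    time_resolution: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.repair_q, self.terminal_stop_q, self.censor_fraction,
                  self.positive_long_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _grid(duration: float, resolution: float) -> float:
    """Round to the acquisition grid, at least one resolution step."""
    return max(resolution, round(duration / resolution) * resolution)


def _draw_normal(rng, loc_spread: tuple[float, float], resolution: float) -> float:
    loc, spread = loc_spread
    return _grid(rng.normal(loc, spread), resolution)


def _draw_shifted_lognormal(rng, spec: dict, resolution: float) -> float:
    d = spec["shift"] + rng.lognormal(mean=np.log(spec["median"]), sigma=spec["sigma"])
    return _grid(d, resolution)


def generate_negative_lineage(
    config: GeneratorConfig, rng: np.random.Generator, lineage_id: str = "neg-0"
) -> Lineage:
    """One telomerase-negative lineage driven by telomere shortening."""
    tp = config.telomere_params
    res = config.time_resolution
    state = sample_initial_state(tp, rng)
    durations: list[float] = []
    in_episode = False
    refractory_left = 0
    died = False
    for _ in range(tp.max_generations):
        state = divide(state, tp, rng)
        l1 = float(state.min())
        if signal_probability(state, config.terminal_threshold) >= 1.0:
            # senescence: a limited run of adaptation divisions, each ending
            # the run with constant probability, then a far longer final cycle
            k = int(rng.geometric(config.terminal_stop_q))
            for _ in range(k - 1):
                durations.append(
                    _draw_shifted_lognormal(rng, config.terminal_preceding_cycle, res)
                )
            durations.append(
                _draw_shifted_lognormal(rng, config.terminal_final_cycle, res)
            )
            died = True
            break
        # below slowdown_length the shortest telomere is in a committed
        # pre-senescent state: cycles lengthen moderately and no further
        # transient (repairable) episodes are triggered
        if not in_episode and refractory_left == 0 and l1 > config.slowdown_length:
            p = signal_probability(state, config.nonterminal_threshold)
            if rng.random() < p:
                in_episode = True
        if in_episode:
            durations.append(_draw_shifted_lognormal(rng, config.arrest_cycle, res))
            if rng.random() < config.repair_q:
                in_episode = False
                if config.repair_rule == "elongate":
                    idx = int(np.argmin(state))
                    state = state.copy()
                    state[idx] += config.repair_elongation_bp
                elif config.repair_rule == "refractory":
                    refractory_left = config.refractory_generations
                else:
                    raise ValueError(f"unknown repair rule {config.repair_rule!r}")
        else:
            if refractory_left > 0:
                refractory_left -= 1
            if l1 <= config.slowdown_length:
                durations.append(_draw_normal(rng, config.slowdown_cycle, res))
            else:
                durations.append(_draw_normal(rng, config.normal_cycle, res))
    fate = FATE_DIED if died else FATE_CENSORED
    if died and config.censor_fraction > 0 and rng.random() < config.censor_fraction:
        if len(durations) > 1:
            cut = int(rng.integers(1, len(durations)))
            durations = durations[:cut]
        fate = FATE_CENSORED
    cycles = tuple(
        CellCycle(generation=i + 1, duration=d) for i, d in enumerate(durations)
    )
    return Lineage(id=lineage_id, telomerase="negative", cycles=cycles, fate=fate)


def generate_positive_lineage(
    config: GeneratorConfig, rng: np.random.Generator, lineage_id: str = "pos-0"
) -> Lineage:
    """One telomerase-positive lineage: tight normal durations, a rare
    generation-independent long cycle, censored at the end of observation."""
    res = config.time_resolution
    durations = []
    for _ in range(config.positive_n_cycles):
        if config.positive_long_prob > 0 and rng.random() < config.positive_long_prob:
            durations.append(_draw_shifted_lognormal(rng, config.arrest_cycle, res))
        else:
            durations.append(_draw_normal(rng, config.normal_cycle, res))
    cycles = tuple(
        CellCycle(generation=i + 1, duration=d) for i, d in enumerate(durations)
    )
    return Lineage(
        id=lineage_id, telomerase="positive", cycles=cycles, fate=FATE_CENSORED
    )


def generate_dataset(
    config: GeneratorConfig, seed: int | None = None
) -> LineageSet:
    """Full synthetic dataset: n_negative + n_positive lineages with
    provenance recording the configuration hash and seed."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    lineages = [
        generate_negative_lineage(config, rng, lineage_id=f"neg-{i:04d}")
        for i in range(config.n_negative)
    ]
    lineages += [
        generate_positive_lineage(config, rng, lineage_id=f"pos-{i:04d}")
        for i in range(config.n_positive)
    ]
    provenance = {
        "generator": "telosen.generate",
        "config_hash": config.config_hash(),
        "seed": seed,
    }
    return LineageSet(lineages=tuple(lineages), provenance=provenance)
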
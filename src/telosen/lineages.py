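"""Lineage data model, I/O, arrest classification and curation rules.

A *lineage* is the sequence of consecutive cell-cycle durations measured for
one tracked cell position (mother-cell line) in a microfluidic chamber, from
telomerase inactivation (telomerase-negative) or from the start of imaging
(telomerase-positive) to cell death or the end of observation.

Cycles longer than a duration threshold ``D`` are classified as *arrests*.
The last run of consecutive long cycles of a lineage that dies is the
*terminal* (senescence) run; every other run of long cycles is *non-terminal*
because at least one normal-duration cycle follows it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd

__all__ = [
    "CellCycle",
    "Lineage",
    "LineageSet",
    "ArrestRun",
    "ArrestAnnotation",
    "LineageValidationError",
    "read_lineage_table",
    "write_lineage_table",
    "estimate_threshold_D",
    "annotate_arrests",
    "filter_for_nonterminal_analysis",
    "filter_for_senescence_analysis",
]

FATE_DIED = "died"
FATE_CENSORED = "censored_end_of_observation"
_VALID_FATES = (FATE_DIED, FATE_CENSORED)
_VALID_TELOMERASE = ("positive", "negative")

#: acquisition time resolution in minutes
TIME_RESOLUTION_MIN = 10.0


class LineageValidationError(ValueError):
    """Raised when a lineage table violates the data model invariants."""


@dataclass(frozen=True)
class CellCycle:
    """One cell cycle: its generation index (1-based) and duration in minutes."""

    generation: int
    duration: float

    def __post_init__(self) -> None:
        if self.generation < 1:
            raise LineageValidationError(
                f"generation must be >= 1, got {self.generation}"
            )
        if not self.duration > 0:
            raise LineageValidationError(
                f"duration must be positive, got {self.duration}"
            )


@dataclass(frozen=True)
class Lineage:
    """Ordered cell-cycle series of one single-cell lineage.

    Parameters
    ----------
    id : str
        Unique lineage identifier.
    telomerase : {"positive", "negative"}
        Telomerase status. For negative lineages generation 1 is the first
        division after telomerase inactivation; for positive lineages it is
        the first observed division.
    cycles : tuple of CellCycle
        Contiguous, ascending generation indices starting at 1.
    fate : {"died", "censored_end_of_observation"}
    """

    id: str
    telomerase: Literal["positive", "negative"]
    cycles: tuple[CellCycle, ...]
    fate: str

    def __post_init__(self) -> None:
        if self.telomerase not in _VALID_TELOMERASE:
            raise LineageValidationError(
                f"lineage {self.id!r}: invalid telomerase status {self.telomerase!r}"
            )
        if self.fate not in _VALID_FATES:
            raise LineageValidationError(
                f"lineage {self.id!r}: invalid fate {self.fate!r}"
            )
        if len(self.cycles) == 0:
            raise LineageValidationError(f"lineage {self.id!r}: empty cycle list")
        gens = [c.generation for c in self.cycles]
        if gens[0] != 1 or any(b - a != 1 for a, b in zip(gens, gens[1:])):
            raise LineageValidationError(
                f"lineage {self.id!r}: generations must be contiguous from 1, got {gens}"
            )

    @property
    def durations(self) -> tuple[float, ...]:
        return tuple(c.duration for c in self.cycles)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def __len__(self) -> int:
        return len(self.cycles)


def lineage_from_durations(
    id: str,
    durations: Iterable[float],
    *,
    telomerase: str = "negative",
    fate: str = FATE_DIED,
) -> Lineage:
    """Convenience constructor from a plain duration list."""
    cycles = tuple(
        CellCycle(generation=i + 1, duration=float(d))
        for i, d in enumerate(durations)
    )
    return Lineage(id=id, telomerase=telomerase, cycles=cycles, fate=fate)


@dataclass(frozen=True)
class LineageSet:
    """A collection of lineages with free-text provenance metadata."""

    lineages: tuple[Lineage, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ids = [lin.id for lin in self.lineages]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LineageValidationError(f"duplicate lineage ids: {dupes}")

    def __iter__(self) -> Iterator[Lineage]:
        return iter(self.lineages)

    def __len__(self) -> int:
        return len(self.lineages)

    def subset(self, predicate) -> "LineageSet":
        return LineageSet(
            lineages=tuple(l for l in self.lineages if predicate(l)),
            provenance=dict(self.provenance),
        )

    @property
    def negative(self) -> "LineageSet":
        return self.subset(lambda l: l.telomerase == "negative")

    @property
    def positive(self) -> "LineageSet":
        return self.subset(lambda l: l.telomerase == "positive")


@dataclass(frozen=True)
class ArrestRun:
    """A maximal run of consecutive long cycles.

    ``terminal`` is True only for the last run of a died lineage when the run
    extends to the lineage's final cycle — the senescence run ending in death.
    """

    start_generation: int
    length: int
    terminal: bool


@dataclass(frozen=True)
class ArrestAnnotation:
    """Per-cycle long/normal flags and maximal arrest runs under threshold D."""

    threshold_D: float
    flags: tuple[bool, ...]
    runs: tuple[ArrestRun, ...]

    @property
    def nonterminal_runs(self) -> tuple[ArrestRun, ...]:
        return tuple(r for r in self.runs if not r.terminal)

    @property
    def terminal_run(self) -> ArrestRun | None:
        for r in self.runs:
            if r.terminal:
                return r
        return None

    @property
    def nonterminal_long_generations(self) -> tuple[int, ...]:
        """Generations of individual long cycles in non-terminal runs."""
        gens: list[int] = []
        for r in self.nonterminal_runs:
            gens.extend(range(r.start_generation, r.start_generation + r.length))
        return tuple(gens)


# ---------------------------------------------------------------------------
# I/O

_COLUMNS = ["lineage_id", "generation", "duration_min", "fate", "telomerase"]


def _set_to_frame(lineage_set: LineageSet) -> pd.DataFrame:
    rows = [
        (lin.id, c.generation, c.duration, lin.fate, lin.telomerase)
        for lin in lineage_set
        for c in lin.cycles
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def _frame_to_set(df: pd.DataFrame, provenance: dict) -> LineageSet:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise LineageValidationError(f"missing required columns: {missing}")
    lineages = []
    for lid, grp in df.groupby("lineage_id", sort=False):
        grp = grp.sort_values("generation")
        fates = grp["fate"].unique()
        stats = grp["telomerase"].unique()
        if len(fates) != 1 or len(stats) != 1:
            raise LineageValidationError(
                f"lineage {lid!r}: inconsistent fate/telomerase across rows"
            )
        cycles = []
        for _, row in grp.iterrows():
            d = float(row["duration_min"])
            if not d > 0:
                raise LineageValidationError(
                    f"lineage {lid!r}: non-positive duration {d}"
                )
            cycles.append(CellCycle(generation=int(row["generation"]), duration=d))
        try:
            lineages.append(
                Lineage(
                    id=str(lid),
                    telomerase=str(stats[0]),
                    cycles=tuple(cycles),
                    fate=str(fates[0]),
                )
            )
        except LineageValidationError as exc:
            raise LineageValidationError(f"lineage {lid!r}: {exc}") from exc
    return LineageSet(lineages=tuple(lineages), provenance=provenance)


def read_lineage_table(path: str | Path, format: str = "csv") -> LineageSet:
    """Read a lineage table from CSV or JSON.

    CSV columns: lineage_id, generation, duration_min, fate, telomerase
    (one row per cell cycle). The JSON mirror is a list of lineage objects.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path)
        if df.empty and list(df.columns) == _COLUMNS:
            return LineageSet(lineages=(), provenance={"source": str(path)})
        return _frame_to_set(df, provenance={"source": str(path)})
    if format == "json":
        payload = json.loads(path.read_text())
        lineages = tuple(
            lineage_from_durations(
                obj["lineage_id"],
                obj["durations_min"],
                telomerase=obj["telomerase"],
                fate=obj["fate"],
            )
            for obj in payload["lineages"]
        )
        return LineageSet(
            lineages=lineages,
            provenance=payload.get("provenance", {"source": str(path)}),
        )
    raise ValueError(f"unknown format {format!r}")


def write_lineage_table(
    lineage_set: LineageSet, path: str | Path, format: str = "csv"
) -> None:
    """Write a lineage table; ``read_lineage_table`` round-trips it exactly."""
    path = Path(path)
    if format == "csv":
        _set_to_frame(lineage_set).to_csv(path, index=False)
        return
    if format == "json":
        payload = {
            "provenance": lineage_set.provenance,
            "lineages": [
                {
                    "lineage_id": lin.id,
                    "telomerase": lin.telomerase,
                    "fate": lin.fate,
                    "durations_min": list(lin.durations),
                }
                for lin in lineage_set
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Threshold estimation and arrest classification


def estimate_threshold_D(positive_set: LineageSet) -> float:
    """Arrest-duration threshold: mean + 3 SD of telomerase-positive cycles.

    Because imaging start/end are not synchronised with divisions, the first
    and last cycle of every lineage are censored before computing the mean
    and (sample, n-1) standard deviation.
    """
    retained: list[float] = []
    for lin in positive_set:
        if lin.telomerase != "positive":
            raise ValueError(f"lineage {lin.id!r} is not telomerase-positive")
        if lin.n_cycles < 3:
            raise ValueError(
                f"lineage {lin.id!r} has {lin.n_cycles} cycles; "
                "nothing left after censoring first and last"
            )
        retained.extend(lin.durations[1:-1])
    mean = sum(retained) / len(retained)
    if len(retained) > 1:
        var = sum((d - mean) ** 2 for d in retained) / (len(retained) - 1)
    else:
        var = 0.0
    return mean + 3.0 * math.sqrt(var)


def annotate_arrests(lineage: Lineage, D: float) -> ArrestAnnotation:
    """Flag long cycles (duration strictly > D) and extract maximal runs.

    A run is terminal only when the lineage died and the run reaches the
    final cycle; for censored lineages no run is terminal (the lineage is
    excluded from senescence analyses upstream).
    """
    if not D > 0:
        raise ValueError(f"threshold D must be positive, got {D}")
    flags = tuple(c.duration > D for c in lineage.cycles)
    runs: list[ArrestRun] = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            terminal = (j == n - 1) and (lineage.fate == FATE_DIED)
            runs.append(
                ArrestRun(
                    start_generation=lineage.cycles[i].generation,
                    length=j - i + 1,
                    terminal=terminal,
                )
            )
            i = j + 1
        else:
            i += 1
    return ArrestAnnotation(threshold_D=float(D), flags=flags, runs=tuple(runs))


def filter_for_nonterminal_analysis(lineage_set: LineageSet, D: float) -> LineageSet:
    """Drop lineages whose every long cycle belongs to the terminal run.

    Lineages with at least one non-terminal long cycle are kept, as are
    lineages with no long cycle at all (at risk but never arrested — they
    contribute right-censored observations to hazard estimation).
    """

    def keep(lin: Lineage) -> bool:
        ann = annotate_arrests(lin, D)
        if not ann.runs:
            return True
        return len(ann.nonterminal_runs) > 0

    return lineage_set.subset(keep)


def filter_for_senescence_analysis(lineage_set: LineageSet) -> LineageSet:
    """Keep only died lineages: for censored ones we cannot tell whether the
    final long cycles were senescence or a transient arrest."""
    return lineage_set.subset(lambda lin: lin.fate == FATE_DIED)
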
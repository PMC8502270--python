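"""Statistics of arrest sequences.

Gaps between the first two non-terminal arrests, geometric laws for the
number of consecutive long cycles per run (non-terminal runs, ended by
repair; terminal runs, ended by death), robustness sweeps over the duration
threshold D, and duration comparisons of the last versus preceding long
cycles of a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lineages import (
    Lineage,
    LineageSet,
    annotate_arrests,
    filter_for_senescence_analysis,
)
from .stats import (
    GOFResult,
    chi2_gof,
    geometric_mle,
    geometric_pmf,
    mann_whitney_u,
    pearson_with_p,
)

__all__ = [
    "RunLengthSample",
    "GapSample",
    "DurationSplit",
    "gap_first_two",
    "collect_gaps",
    "gap_geometric_gof_sweep",
    "consecutive_fraction_vs_D",
    "correlate_gap_with_first_generation",
    "run_lengths",
    "fit_run_geometric",
    "run_gof_sweep",
    "duration_split_comparison",
]


@dataclass(frozen=True)
class RunLengthSample:
    """Numbers of consecutive long cycles per run of one kind."""

    kind: str  # "nonterminal" | "terminal"
    lengths: tuple[int, ...]
    threshold_D: float

    def __post_init__(self) -> None:
        if any(l < 1 for l in self.lengths):
            raise ValueError("run lengths must be >= 1")


@dataclass(frozen=True)
class GapSample:
    """Generation gaps between the first two non-terminal long cycles
    (gap 1 means the arrests are juxtaposed)."""

    gaps: tuple[int, ...]
    threshold_D: float

    def __post_init__(self) -> None:
        if any(g < 1 for g in self.gaps):
            raise ValueError("gaps must be >= 1")


@dataclass(frozen=True)
class DurationSplit:
    """Last vs preceding long-cycle durations across runs of one kind."""

    last: tuple[float, ...]
    preceding: tuple[float, ...]
    median_last: float
    median_preceding: float
    mwu_u: float | None
    mwu_p: float | None
    note: str = ""


def gap_first_two(lineage: Lineage, D: float) -> int | None:
    """Generations between the first two non-terminal long cycles.

    Individual long cycles count as arrests: two consecutive long cycles
    are two arrests at gap 1. Returns None with fewer than two non-terminal
    long cycles.
    """
    gens = annotate_arrests(lineage, D).nonterminal_long_generations
    if len(gens) < 2:
        return None
    return gens[1] - gens[0]


def collect_gaps(lineage_set: LineageSet, D: float) -> GapSample:
    gaps = tuple(
        g for g in (gap_first_two(lin, D) for lin in lineage_set) if g is not None
    )
    return GapSample(gaps=gaps, threshold_D=float(D))


def gap_geometric_gof_sweep(
    lineage_set: LineageSet, D_values: Sequence[float]
) -> pd.DataFrame:
    """Per D: fit a geometric law to the first-two-arrest gaps and test it."""
    rows = []
    for D in D_values:
        sample = collect_gaps(lineage_set, D)
        row: dict = {"D": float(D), "n": len(sample.gaps), "computable": False,
                     "p_hat": np.nan, "p_value": np.nan}
        if len(sample.gaps) >= 2:
            p_hat = geometric_mle(sample.gaps)
            row["p_hat"] = p_hat
            try:
                gof = chi2_gof(
                    list(sample.gaps), lambda k: geometric_pmf(k, p_hat), n_fitted=1
                )
                row.update(p_value=gof.p_value, computable=True)
            except ValueError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def consecutive_fraction_vs_D(
    lineage_set: LineageSet, D_values: Sequence[float]
) -> pd.DataFrame:
    """Per D: fraction of lineages (with >= 2 non-terminal arrests) whose
    first two arrests are juxtaposed (gap 1)."""
    rows = []
    for D in D_values:
        sample = collect_gaps(lineage_set, D)
        n = len(sample.gaps)
        rows.append(
            {
                "D": float(D),
                "n": n,
                "fraction_consecutive": (
                    float(np.mean([g == 1 for g in sample.gaps])) if n else np.nan
                ),
                "computable": n > 0,
            }
        )
    return pd.DataFrame(rows)


def correlate_gap_with_first_generation(
    lineage_set: LineageSet, D: float
) -> tuple[float, float]:
    """Pearson correlation between the generation of the first non-terminal
    arrest and the gap to the second one."""
    firsts, gaps = [], []
    for lin in lineage_set:
        gens = annotate_arrests(lin, D).nonterminal_long_generations
        if len(gens) >= 2:
            firsts.append(gens[0])
            gaps.append(gens[1] - gens[0])
    if len(gaps) < 3:
        raise ValueError("need >= 3 lineages with two non-terminal arrests")
    return pearson_with_p(firsts, gaps)


def run_lengths(lineage_set: LineageSet, D: float, kind: str) -> RunLengthSample:
    """Run-length inventory.

    ``nonterminal``: lengths of every non-terminal run across all lineages
    (runs from lineages that later die still count; only their terminal run
    is excluded). ``terminal``: the length of the terminal run per died
    lineage — censored lineages contribute none.
    """
    if kind not in ("nonterminal", "terminal"):
        raise ValueError(f"kind must be 'nonterminal' or 'terminal', got {kind!r}")
    lengths: list[int] = []
    if kind == "terminal":
        lineage_set = filter_for_senescence_analysis(lineage_set)
    for lin in lineage_set:
        ann = annotate_arrests(lin, D)
        if kind == "nonterminal":
            lengths.extend(r.length for r in ann.nonterminal_runs)
        else:
            term = ann.terminal_run
            if term is not None:
                lengths.append(term.length)
    return RunLengthSample(kind=kind, lengths=tuple(lengths), threshold_D=float(D))


def fit_run_geometric(sample: RunLengthSample) -> tuple[float, GOFResult | None]:
    """Geometric fit of run lengths: q_hat is the per-generation probability
    of ending the run (repair for non-terminal runs, death for terminal),
    tested by chi-square GOF with one fitted parameter.

    The GOF result is None when the sample is too small to support the
    test (fewer than two bins with adequate expected counts).
    """
    if not sample.lengths:
        raise ValueError("empty run-length sample")
    q_hat = geometric_mle(sample.lengths)
    try:
        gof = chi2_gof(
            list(sample.lengths), lambda k: geometric_pmf(k, q_hat), n_fitted=1
        )
    except ValueError:
        gof = None
    return q_hat, gof


def run_gof_sweep(
    lineage_set: LineageSet, D_values: Sequence[float], kind: str
) -> pd.DataFrame:
    """Geometric-law fit and test of run lengths, swept over D."""
    rows = []
    for D in D_values:
        row: dict = {"D": float(D), "kind": kind, "n_runs": 0, "computable": False,
                     "q_hat": np.nan, "p_value": np.nan}
        sample = run_lengths(lineage_set, D, kind)
        row["n_runs"] = len(sample.lengths)
        if sample.lengths:
            q_hat, gof = fit_run_geometric(sample)
            row["q_hat"] = q_hat
            if gof is not None:
                row.update(p_value=gof.p_value, computable=True)
        rows.append(row)
    return pd.DataFrame(rows)


def duration_split_comparison(
    lineage_set: LineageSet, D: float, kind: str
) -> DurationSplit:
    """Last vs preceding long-cycle durations within runs of one kind.

    For each run, its final long cycle's duration goes to "last" and all
    earlier ones to "preceding" (length-1 runs contribute to "last" only).
    Medians are compared with a two-sided Mann-Whitney U test; when either
    sample is empty the test is skipped with a diagnostic note.
    """
    if kind == "terminal":
        lineage_set = filter_for_senescence_analysis(lineage_set)
    last: list[float] = []
    preceding: list[float] = []
    for lin in lineage_set:
        ann = annotate_arrests(lin, D)
        runs = (
            ann.nonterminal_runs
            if kind == "nonterminal"
            else tuple(r for r in (ann.terminal_run,) if r is not None)
        )
        for r in runs:
            i0 = r.start_generation - 1
            durs = [lin.cycles[i].duration for i in range(i0, i0 + r.length)]
            last.append(durs[-1])
            preceding.extend(durs[:-1])
    med_last = float(np.median(last)) if last else float("nan")
    med_prec = float(np.median(preceding)) if preceding else float("nan")
    if last and preceding:
        u, p = mann_whitney_u(last, preceding)
        note = ""
    else:
        u = p = None
        note = "one sample empty; Mann-Whitney test skipped"
    return DurationSplit(
        last=tuple(last),
        preceding=tuple(preceding),
        median_last=med_last,
        median_preceding=med_prec,
        mwu_u=u,
        mwu_p=p,
        note=note,
    )
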
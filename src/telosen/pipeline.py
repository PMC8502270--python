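"""End-to-end analysis pipeline.

Ties the modules into the full analysis over one lineage dataset (read
from a table or produced by the synthetic generator): arrest
classification, first-arrest hazard modelling with threshold sweeps,
telomere-threshold fitting, and arrest-run statistics. Every stage writes
tidy CSV/JSON tables named after the analysis they correspond to, plus a
run log with the configuration hash and seeds; the whole run is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import first_arrest as fa
from . import runs as ar
from . import threshold_fit as tf
from .generate import GeneratorConfig, generate_dataset
from .lineages import (
    LineageSet,
    annotate_arrests,
    estimate_threshold_D,
    filter_for_nonterminal_analysis,
    read_lineage_table,
    write_lineage_table,
)
from .stats import rank_envelope
from .telomeres import (
    DeterministicThreshold,
    ProbabilisticThreshold,
    TelomereModelParams,
)

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("classify", "first_arrest", "runs", "threshold_fit")


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline configuration.

    Either ``input_path`` (lineage CSV) or ``generator`` must be set. When
    ``D`` is None it is estimated from the telomerase-positive lineages
    (mean + 3 SD after censoring first/last cycles).
    """

    output_dir: str
    input_path: str | None = None
    generator: GeneratorConfig | None = None
    D: float | None = None
    sweep_D: tuple[float, ...] = tuple(float(d) for d in range(140, 361, 20))
    seed: int = 0
    stages: tuple[str, ...] = ("classify", "first_arrest", "runs")
    fit_N: int = 100      # simulation replicates for threshold fitting
    envelope_N: int = 200  # replicates for envelope tables

    def __post_init__(self) -> None:
        if self.input_path is None and self.generator is None:
            raise ValueError("either input_path or generator must be given")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _first_appearance_table(negative: LineageSet, D: float) -> pd.DataFrame:
    """Cumulative distribution of the first appearance of non-terminal and
    terminal arrests over generations."""
    first_nt, first_term = [], []
    for lin in negative:
        ann = annotate_arrests(lin, D)
        nt = ann.nonterminal_long_generations
        if nt:
            first_nt.append(nt[0])
        term = ann.terminal_run
        if term is not None:
            first_term.append(term.start_generation)
    horizon = max(first_nt + first_term, default=0)
    gens = np.arange(1, horizon + 1)
    rows = {
        "generation": gens,
        "cdf_nonterminal": [
            np.mean([g <= j for g in first_nt]) if first_nt else np.nan for j in gens
        ],
        "cdf_terminal": [
            np.mean([g <= j for g in first_term]) if first_term else np.nan
            for j in gens
        ],
    }
    return pd.DataFrame(rows)


def _stage_classify(neg: LineageSet, D: float, out: Path) -> list[str]:
    rows = []
    for lin in neg:
        ann = annotate_arrests(lin, D)
        term = ann.terminal_run
        rows.append(
            {
                "lineage_id": lin.id,
                "fate": lin.fate,
                "n_cycles": lin.n_cycles,
                "n_long_cycles": int(sum(ann.flags)),
                "n_nonterminal_runs": len(ann.nonterminal_runs),
                "terminal_run_length": term.length if term else 0,
            }
        )
    pd.DataFrame(rows).to_csv(out / "classification.csv", index=False)
    _first_appearance_table(neg, D).to_csv(out / "first_appearance_cdf.csv", index=False)
    return ["classification.csv", "first_appearance_cdf.csv"]


def _stage_first_arrest(
    neg: LineageSet, D: float, cfg: PipelineConfig, rng: np.random.Generator, out: Path
) -> list[str]:
    written = []
    filtered = filter_for_nonterminal_analysis(neg, D)
    gens = fa.first_arrest_generations(filtered, D)
    const = fa.fit_constant(gens)
    est = fa.empirical_hazard(filtered, D)
    logi = fa.fit_logistic(est)
    ks = np.arange(1, max(gens) + 1)
    pd.DataFrame(
        {
            "generation": ks,
            "observed_fraction": [np.mean([g == k for g in gens]) for k in ks],
            "pmf_logistic": fa.first_arrest_pmf(logi, ks),
            "pmf_constant": fa.first_arrest_pmf(const, ks),
        }
    ).to_csv(out / "first_arrest_pmf.csv", index=False)
    pd.DataFrame(
        {
            "generation": est.generations,
            "empirical_hazard": est.fractions,
            "at_risk": est.at_risk,
            "logistic_hazard": logi.hazard(est.generations),
        }
    ).to_csv(out / "hazard_points.csv", index=False)
    sims = np.sort(
        np.stack(
            [
                fa.simulate_first_arrests(logi, len(gens), rng)
                for _ in range(cfg.envelope_N)
            ]
        ),
        axis=1,
    )
    band = rank_envelope(sims, level=0.95)
    pd.DataFrame(
        {
            "rank": np.arange(1, len(gens) + 1),
            "experimental": np.sort(gens),
            "lower": band.lower,
            "upper": band.upper,
        }
    ).to_csv(out / "ordered_first_arrests_envelope.csv", index=False)
    fa.sweep_threshold_D(neg, cfg.sweep_D, "logistic").to_csv(
        out / "first_arrest_logistic_sweep.csv", index=False
    )
    fa.sweep_threshold_D(neg, cfg.sweep_D, "constant").to_csv(
        out / "first_arrest_constant_sweep.csv", index=False
    )
    written += [
        "first_arrest_pmf.csv",
        "hazard_points.csv",
        "ordered_first_arrests_envelope.csv",
        "first_arrest_logistic_sweep.csv",
        "first_arrest_constant_sweep.csv",
    ]
    return written


def _stage_runs(neg: LineageSet, D: float, cfg: PipelineConfig, out: Path) -> list[str]:
    written = []
    gaps = ar.collect_gaps(neg, D)
    pd.DataFrame({"gap": gaps.gaps}).to_csv(out / "gap_first_two.csv", index=False)
    try:
        r, p = ar.correlate_gap_with_first_generation(neg, D)
        corr = {"pearson_r": r, "p_value": p}
    except ValueError as exc:
        corr = {"error": str(exc)}
    (out / "gap_vs_first_generation.json").write_text(json.dumps(corr, indent=1))
    ar.consecutive_fraction_vs_D(neg, cfg.sweep_D).to_csv(
        out / "consecutive_fraction_vs_D.csv", index=False
    )
    ar.gap_geometric_gof_sweep(neg, cfg.sweep_D).to_csv(
        out / "gap_geometric_sweep.csv", index=False
    )
    for kind in ("nonterminal", "terminal"):
        sample = ar.run_lengths(neg, D, kind)
        pd.DataFrame({"length": sample.lengths}).to_csv(
            out / f"run_lengths_{kind}.csv", index=False
        )
        ar.run_gof_sweep(neg, cfg.sweep_D, kind).to_csv(
            out / f"run_geometric_sweep_{kind}.csv", index=False
        )
        split = ar.duration_split_comparison(neg, D, kind)
        (out / f"duration_split_{kind}.json").write_text(
            json.dumps(
                {
                    "median_last": split.median_last,
                    "median_preceding": split.median_preceding,
                    "mwu_u": split.mwu_u,
                    "mwu_p": split.mwu_p,
                    "n_last": len(split.last),
                    "n_preceding": len(split.preceding),
                    "note": split.note,
                },
                indent=1,
            )
        )
        written += [
            f"run_lengths_{kind}.csv",
            f"run_geometric_sweep_{kind}.csv",
            f"duration_split_{kind}.json",
        ]
    written += [
        "gap_first_two.csv",
        "gap_vs_first_generation.json",
        "consecutive_fraction_vs_D.csv",
        "gap_geometric_sweep.csv",
    ]
    return written


def _stage_threshold_fit(
    neg: LineageSet, D: float, cfg: PipelineConfig, out: Path
) -> list[str]:
    filtered = filter_for_nonterminal_analysis(neg, D)
    gens = np.sort(fa.first_arrest_generations(filtered, D))
    fit_cfg = tf.FitObjectiveConfig(N=cfg.fit_N, n=len(gens))
    model_params = (
        cfg.generator.telomere_params
        if cfg.generator is not None
        else TelomereModelParams()
    )
    written = []
    for name, fitter in (
        ("probabilistic", tf.fit_probabilistic),
        ("deterministic", tf.fit_deterministic),
    ):
        res = fitter(gens, model_params, config=fit_cfg, seed=cfg.seed + 11)
        (out / f"threshold_fit_{name}.json").write_text(
            json.dumps(
                {
                    "params": res.params,
                    "objective": res.objective,
                    "n_evaluations": res.n_evaluations,
                    "seed": res.seed,
                    "N": res.config.N,
                    "n": res.config.n,
                },
                indent=1,
            )
        )
        if name == "probabilistic":
            thr = ProbabilisticThreshold(**res.params)
        else:
            thr = DeterministicThreshold(**res.params)
        env = tf.envelope_comparison(
            thr, model_params, gens, N=cfg.envelope_N, seed=cfg.seed + 13
        )
        env.to_csv(out / f"threshold_envelope_{name}.csv", index=False)
        written += [f"threshold_fit_{name}.json", f"threshold_envelope_{name}.csv"]
    return written


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write their tables.

    Returns a manifest dict (also written as ``run_log.json``) listing the
    outputs per stage, the threshold D used, and the seeds.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if config.input_path is not None:
        dataset = read_lineage_table(config.input_path)
        source = {"input_path": config.input_path}
    else:
        dataset = generate_dataset(config.generator, seed=config.seed)
        write_lineage_table(dataset, out / "lineages.csv")
        source = {
            "generator_config_hash": config.generator.config_hash(),
            "written": "lineages.csv",
        }
    positive = dataset.positive
    negative = dataset.negative
    D = config.D if config.D is not None else estimate_threshold_D(positive)

    manifest: dict = {
        "seed": config.seed,
        "D": D,
        "n_negative": len(negative),
        "n_positive": len(positive),
        "source": source,
        "stages": {},
    }
    stage_fns = {
        "classify": lambda: _stage_classify(negative, D, out),
        "first_arrest": lambda: _stage_first_arrest(negative, D, config, rng, out),
        "runs": lambda: _stage_runs(negative, D, config, out),
        "threshold_fit": lambda: _stage_threshold_fit(negative, D, config, out),
    }
    for stage in config.stages:
        try:
            manifest["stages"][stage] = {"outputs": stage_fns[stage](), "ok": True}
        except Exception as exc:  # partial outputs retained
            manifest["stages"][stage] = {"ok": False, "error": f"{stage}: {exc}"}
    (out / "run_log.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
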
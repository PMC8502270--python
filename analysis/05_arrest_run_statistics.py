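"""Statistics of consecutive arrests: two distinct regimes.

Gaps between the first two non-terminal arrests (over-represented
juxtaposition), geometric laws for the number of consecutive arrests per
run — accepted for non-terminal runs, rejected for terminal runs at
D = 180 min — and last-vs-preceding duration comparisons.
"""

from pathlib import Path

import numpy as np

from telosen import runs as ar
from telosen.lineages import estimate_threshold_D, read_lineage_table
from telosen.pipeline import PipelineConfig, _stage_runs
from telosen.generate import GeneratorConfig

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    dataset = read_lineage_table(OUT / "synthetic_lineages.csv")
    D = estimate_threshold_D(dataset.positive)
    neg = dataset.negative

    gaps = ar.collect_gaps(neg, D)
    frac1 = np.mean([g == 1 for g in gaps.gaps])
    print(f"{len(gaps.gaps)} lineages with two non-terminal arrests; "
          f"fraction juxtaposed (gap = 1): {frac1:.2f}")
    r, p = ar.correlate_gap_with_first_generation(neg, D)
    print(f"gap vs first-arrest generation: Pearson r = {r:.3f}, p = {p:.2f}")

    for kind in ("nonterminal", "terminal"):
        sample = ar.run_lengths(neg, D, kind)
        q, gof = ar.fit_run_geometric(sample)
        verdict = (
            "not rejected" if gof is not None and gof.p_value > 0.05 else "rejected"
        )
        pv = f"{gof.p_value:.2e}" if gof is not None else "n/a"
        print(f"{kind} runs (n = {len(sample.lengths)}): q_hat = {q:.2f}, "
              f"geometric law {verdict} (p = {pv})")
        split = ar.duration_split_comparison(neg, D, kind)
        print(f"  last vs preceding medians: {split.median_last:.0f} vs "
              f"{split.median_preceding:.0f} min (Mann-Whitney p = "
              f"{split.mwu_p:.2e})" if split.mwu_p is not None else "  test skipped")

    cfg = PipelineConfig(
        output_dir=str(OUT), generator=GeneratorConfig(), D=D, seed=0,
    )
    written = _stage_runs(neg, D, cfg, OUT)
    print("written:", ", ".join(written))


if __name__ == "__main__":
    main()
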
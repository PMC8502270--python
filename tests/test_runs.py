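"""Arrest-sequence statistics: gaps, run lengths, geometric laws and
duration comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telosen.lineages import (
    FATE_CENSORED,
    FATE_DIED,
    LineageSet,
    lineage_from_durations,
)
from telosen.runs import (
    RunLengthSample,
    collect_gaps,
    consecutive_fraction_vs_D,
    correlate_gap_with_first_generation,
    duration_split_comparison,
    fit_run_geometric,
    gap_first_two,
    gap_geometric_gof_sweep,
    run_lengths,
)


def lset(*lineages):
    return LineageSet(lineages=tuple(lineages))


class TestGaps:
    def test_juxtaposed_and_separated(self):
        # long cycles at generations 5,6 -> gap 1; at 5,9 -> gap 4
        base = [90.0] * 10
        a = base.copy()
        a[4], a[5] = 250.0, 250.0
        b = base.copy()
        b[4], b[8] = 250.0, 250.0
        assert gap_first_two(
            lineage_from_durations("a", a, fate=FATE_CENSORED), 180
        ) == 1
        assert gap_first_two(
            lineage_from_durations("b", b, fate=FATE_CENSORED), 180
        ) == 4

    def test_single_arrest_gives_none(self):
        d = [90.0, 250.0, 90.0]
        assert gap_first_two(
            lineage_from_durations("a", d, fate=FATE_CENSORED), 180
        ) is None

    @settings(derandomize=True, max_examples=40)
    @given(
        durations=st.lists(
            st.sampled_from([90.0, 250.0]), min_size=3, max_size=30
        )
    )
    def test_gap_is_at_least_one(self, durations):
        durations = durations + [90.0]  # avoid a terminal run
        g = gap_first_two(
            lineage_from_durations("a", durations, fate=FATE_DIED), 180
        )
        assert g is None or g >= 1

    def test_all_juxtaposed_gives_fraction_one(self):
        d = [90.0, 250.0, 250.0, 90.0]
        ls = lset(
            *[
                lineage_from_durations(f"l{i}", d, fate=FATE_CENSORED)
                for i in range(5)
            ]
        )
        table = consecutive_fraction_vs_D(ls, [180.0, 200.0, 240.0])
        assert np.allclose(table["fraction_consecutive"], 1.0)

    def test_no_double_arrests_flagged_not_computable(self):
        ls = lset(lineage_from_durations("a", [90.0, 250.0, 90.0],
                                         fate=FATE_CENSORED))
        table = consecutive_fraction_vs_D(ls, [180.0])
        assert not table.loc[0, "computable"]

    def test_gap_sweep_calibrated_under_geometric_null(self, rng):
        accept = 0
        reps = 20
        for _ in range(reps):
            gaps = rng.geometric(0.4, size=500)
            base = [90.0] * 3
            lins = [
                lineage_from_durations(
                    f"l{i}", base + [250.0] + [90.0] * (g - 1) + [250.0, 90.0],
                    fate=FATE_CENSORED,
                )
                for i, g in enumerate(gaps)
            ]
            table = gap_geometric_gof_sweep(lset(*lins), [180.0])
            accept += table.loc[0, "p_value"] > 0.05
        assert accept >= reps * 0.8

    def test_excess_juxtaposition_rejected(self, rng):
        # mixture: 60% always-juxtaposed plus a geometric tail, n=77
        gaps = np.where(
            rng.random(77) < 0.6, 1, rng.geometric(0.25, size=77) + 1
        )
        lins = [
            lineage_from_durations(
                f"l{i}", [90.0, 250.0] + [90.0] * (g - 1) + [250.0, 90.0],
                fate=FATE_CENSORED,
            )
            for i, g in enumerate(gaps)
        ]
        table = gap_geometric_gof_sweep(lset(*lins), [180.0])
        assert table.loc[0, "p_value"] < 0.05


class TestCorrelation:
    def test_gap_equal_to_first_generation_gives_r_one(self):
        lins = []
        for i, first in enumerate([2, 3, 5, 8]):
            d = [90.0] * (first - 1) + [250.0] + [90.0] * (first - 1) + [250.0, 90.0]
            lins.append(lineage_from_durations(f"l{i}", d, fate=FATE_CENSORED))
        r, _ = correlate_gap_with_first_generation(lset(*lins), 180)
        assert r == pytest.approx(1.0)

    def test_too_few_lineages_errors(self):
        ls = lset(lineage_from_durations("a", [250.0, 250.0, 90.0],
                                         fate=FATE_CENSORED))
        with pytest.raises(ValueError):
            correlate_gap_with_first_generation(ls, 180)


class TestRunLengths:
    def test_nonterminal_and_terminal_inventory(self):
        lin = lineage_from_durations(
            "a", [100, 200, 190, 100, 210], fate=FATE_DIED
        )
        nt = run_lengths(lset(lin), 180, "nonterminal")
        term = run_lengths(lset(lin), 180, "terminal")
        assert nt.lengths == (2,)
        assert term.lengths == (1,)

    def test_terminal_length_two(self):
        lin = lineage_from_durations("a", [90, 90, 200, 210], fate=FATE_DIED)
        assert run_lengths(lset(lin), 180, "terminal").lengths == (2,)

    def test_censored_lineage_contributes_no_terminal_run(self):
        lin = lineage_from_durations("a", [90, 200, 210], fate=FATE_CENSORED)
        assert run_lengths(lset(lin), 180, "terminal").lengths == ()

    def test_run_lengths_partition_long_cycles(self, default_dataset):
        from telosen.lineages import annotate_arrests

        neg = default_dataset.negative
        for D in (180.0, 240.0):
            nt = run_lengths(neg, D, "nonterminal")
            term = run_lengths(neg, D, "terminal")
            total_long = sum(sum(annotate_arrests(lin, D).flags) for lin in neg)
            assert sum(nt.lengths) + sum(term.lengths) == total_long


class TestGeometricFit:
    def test_q_hat_is_one_over_mean(self):
        sample = RunLengthSample("nonterminal", (1, 1, 2, 2), 180.0)
        q, gof = fit_run_geometric(sample)
        assert q == pytest.approx(2 / 3)
        assert gof is None  # too few runs to bin

    def test_recovery_at_large_n(self, rng):
        lengths = rng.geometric(0.6, size=10000)
        sample = RunLengthSample("nonterminal", tuple(int(v) for v in lengths), 180.0)
        q, gof = fit_run_geometric(sample)
        se = 0.6 * np.sqrt(0.4) / np.sqrt(10000)
        assert abs(q - 0.6) < 3 * se
        assert gof is not None

    def test_calibration_under_geometric_null(self, rng):
        accept = 0
        for _ in range(20):
            lengths = tuple(int(v) for v in rng.geometric(0.6, size=300))
            _, gof = fit_run_geometric(RunLengthSample("nonterminal", lengths, 180.0))
            accept += gof.p_value > 0.05
        assert accept >= 16

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            fit_run_geometric(RunLengthSample("terminal", (), 180.0))


class TestDurationSplit:
    def test_last_versus_preceding_partition(self):
        lin = lineage_from_durations(
            "a", [90.0, 200.0, 250.0, 300.0, 90.0], fate=FATE_DIED
        )
        split = duration_split_comparison(lset(lin), 180, "nonterminal")
        assert split.last == (300.0,)
        assert sorted(split.preceding) == [200.0, 250.0]

    def test_all_runs_length_one_skips_test(self):
        lins = [
            lineage_from_durations(f"l{i}", [90.0, 250.0, 90.0], fate=FATE_CENSORED)
            for i in range(4)
        ]
        split = duration_split_comparison(lset(*lins), 180, "nonterminal")
        assert split.preceding == ()
        assert split.mwu_p is None
        assert "skipped" in split.note
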
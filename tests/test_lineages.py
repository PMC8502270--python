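"""Lineage data model, I/O round trips, threshold estimation and
arrest classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telosen.lineages import (
    FATE_CENSORED,
    FATE_DIED,
    Lineage,
    LineageSet,
    LineageValidationError,
    annotate_arrests,
    estimate_threshold_D,
    filter_for_nonterminal_analysis,
    filter_for_senescence_analysis,
    lineage_from_durations,
    read_lineage_table,
    write_lineage_table,
)


def lset(*lineages):
    return LineageSet(lineages=tuple(lineages))


class TestIO:
    def test_csv_parse_single_lineage(self, tmp_path):
        path = tmp_path / "lin.csv"
        path.write_text(
            "lineage_id,generation,duration_min,fate,telomerase\n"
            "L1,1,90,died,negative\n"
            "L1,2,90,died,negative\n"
            "L1,3,200,died,negative\n"
            "L1,4,90,died,negative\n"
        )
        ls = read_lineage_table(path)
        assert len(ls) == 1
        assert ls.lineages[0].durations == (90, 90, 200, 90)

    def test_negative_duration_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "lineage_id,generation,duration_min,fate,telomerase\n"
            "L1,1,-10,died,negative\n"
        )
        with pytest.raises(LineageValidationError, match="L1"):
            read_lineage_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("lineage_id,generation\nL1,1\n")
        with pytest.raises(LineageValidationError, match="missing"):
            read_lineage_table(path)

    def test_noncontiguous_generations_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "lineage_id,generation,duration_min,fate,telomerase\n"
            "L1,1,90,died,negative\n"
            "L1,3,90,died,negative\n"
        )
        with pytest.raises(LineageValidationError, match="L1"):
            read_lineage_table(path)

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_round_trip(self, tmp_path, fmt):
        ls = lset(
            lineage_from_durations("a", [90, 200, 90], fate=FATE_DIED),
            lineage_from_durations("b", [100, 110], fate=FATE_CENSORED),
            lineage_from_durations("c", [90] * 5, telomerase="positive",
                                   fate=FATE_CENSORED),
        )
        path = tmp_path / f"set.{fmt}"
        write_lineage_table(ls, path, format=fmt)
        back = read_lineage_table(path, format=fmt)
        assert back.lineages == ls.lineages

    def test_empty_set_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_lineage_table(lset(), path)
        assert path.read_text().strip() == (
            "lineage_id,generation,duration_min,fate,telomerase"
        )
        assert len(read_lineage_table(path)) == 0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(LineageValidationError, match="duplicate"):
            lset(
                lineage_from_durations("a", [90]),
                lineage_from_durations("a", [90]),
            )


class TestThresholdD:
    def test_zero_variance(self):
        ls = lset(
            lineage_from_durations(
                "p1", [50, 90, 90, 90, 50], telomerase="positive",
                fate=FATE_CENSORED,
            )
        )
        # first/last cycles censored -> retained {90, 90, 90}
        assert estimate_threshold_D(ls) == pytest.approx(90.0)

    def test_mean_plus_three_sd(self):
        # retained durations {60, 90, 120}: mean 90, sample SD 30 -> D = 180
        ls = lset(
            lineage_from_durations(
                "p1", [999, 60, 90, 120, 999], telomerase="positive",
                fate=FATE_CENSORED,
            )
        )
        assert estimate_threshold_D(ls) == pytest.approx(180.0)

    def test_short_lineage_rejected(self):
        ls = lset(
            lineage_from_durations("p1", [90, 90], telomerase="positive",
                                   fate=FATE_CENSORED)
        )
        with pytest.raises(ValueError, match="censoring"):
            estimate_threshold_D(ls)

    def test_negative_lineage_rejected(self):
        ls = lset(lineage_from_durations("n1", [90, 90, 90]))
        with pytest.raises(ValueError, match="positive"):
            estimate_threshold_D(ls)


class TestAnnotation:
    def test_single_long_cycle_followed_by_normal_is_nonterminal(self):
        lin = lineage_from_durations("a", [100, 90, 200, 110], fate=FATE_DIED)
        ann = annotate_arrests(lin, 180)
        assert ann.flags == (False, False, True, False)
        assert len(ann.runs) == 1
        run = ann.runs[0]
        assert (run.start_generation, run.length, run.terminal) == (3, 1, False)

    def test_final_run_of_died_lineage_is_terminal(self):
        lin = lineage_from_durations("a", [100, 200, 210], fate=FATE_DIED)
        ann = annotate_arrests(lin, 180)
        assert len(ann.runs) == 1
        run = ann.runs[0]
        assert (run.start_generation, run.length, run.terminal) == (2, 2, True)

    def test_censored_lineage_has_no_terminal_run(self):
        lin = lineage_from_durations("a", [100, 200, 210], fate=FATE_CENSORED)
        ann = annotate_arrests(lin, 180)
        assert len(ann.runs) == 1
        assert not ann.runs[0].terminal
        assert ann.terminal_run is None

    def test_cycle_equal_to_threshold_is_normal(self):
        lin = lineage_from_durations("a", [180, 190], fate=FATE_CENSORED)
        ann = annotate_arrests(lin, 180)
        assert ann.flags == (False, True)

    @settings(derandomize=True, max_examples=50)
    @given(
        durations=st.lists(
            st.sampled_from([90.0, 120.0, 200.0, 250.0, 730.0]), min_size=1,
            max_size=30,
        ),
        d_lo=st.sampled_from([100.0, 180.0, 240.0]),
    )
    def test_raising_threshold_never_adds_long_cycles(self, durations, d_lo):
        lin = lineage_from_durations("a", durations, fate=FATE_DIED)
        lo = annotate_arrests(lin, d_lo)
        hi = annotate_arrests(lin, d_lo + 60.0)
        assert sum(hi.flags) <= sum(lo.flags)
        # terminal run unique and last, if present
        for ann in (lo, hi):
            terminals = [i for i, r in enumerate(ann.runs) if r.terminal]
            assert len(terminals) <= 1
            if terminals:
                assert terminals[0] == len(ann.runs) - 1

    @settings(derandomize=True, max_examples=50)
    @given(
        durations=st.lists(
            st.sampled_from([90.0, 200.0, 250.0]), min_size=1, max_size=30
        )
    )
    def test_run_lengths_partition_long_cycles(self, durations):
        lin = lineage_from_durations("a", durations, fate=FATE_DIED)
        ann = annotate_arrests(lin, 180)
        assert sum(r.length for r in ann.runs) == sum(ann.flags)


class TestFilters:
    def test_only_terminal_lineage_excluded(self):
        only_term = lineage_from_durations("t", [90, 200, 210], fate=FATE_DIED)
        mixed = lineage_from_durations("m", [90, 200, 90, 210], fate=FATE_DIED)
        never = lineage_from_durations("n", [90, 90], fate=FATE_CENSORED)
        out = filter_for_nonterminal_analysis(lset(only_term, mixed, never), 180)
        assert {lin.id for lin in out} == {"m", "n"}

    def test_senescence_filter_keeps_only_died(self):
        died = lineage_from_durations("d", [90, 200], fate=FATE_DIED)
        cens = lineage_from_durations("c", [90, 200], fate=FATE_CENSORED)
        out = filter_for_senescence_analysis(lset(died, cens))
        assert [lin.id for lin in out] == ["d"]
        assert len(filter_for_senescence_analysis(lset())) == 0
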
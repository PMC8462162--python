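import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pradelts as pt
from pradelts.histories import CaptureHistorySet


class TestBuildHistories:
    def test_within_session_captures_collapse(self, short_calendar, tiny_records):
        chs = pt.build_histories(tiny_records, short_calendar)
        patterns = {"".join(map(str, row)) for row in chs.histories}
        # a1 caught twice in session 1: still a single detection there
        # (occasions 1 and 3 -> 101000, shared with a2)
        assert patterns == {"101000", "010000"}
        assert chs.total_individuals() == 4

    def test_identical_patterns_pool_by_sex(self, short_calendar):
        rec = pd.DataFrame(
            {
                "animal_id": ["f1", "f1", "f2", "f2", "m1"],
                "session": ["1993-10", "1994-10", "1993-10", "1994-10", "1994-10"],
                "sex": ["F", "F", "F", "F", "M"],
                "age": ["adult"] * 5,
            }
        )
        chs = pt.build_histories(rec, short_calendar)
        assert chs.n_patterns == 2
        fcol = chs.groups.index("F")
        mcol = chs.groups.index("M")
        assert sorted(chs.counts[:, fcol].tolist()) == [0, 2]
        assert sorted(chs.counts[:, mcol].tolist()) == [0, 1]

    def test_juvenile_only_animal_dropped(self, short_calendar):
        rec = pd.DataFrame(
            {
                "animal_id": ["a", "j"],
                "session": ["1993-10", "1993-10"],
                "sex": ["F", "M"],
                "age": ["adult", "juvenile"],
            }
        )
        chs = pt.build_histories(rec, short_calendar, adults_only=True)
        assert chs.total_individuals() == 1
        assert chs.dropped["juvenile_only_animals"] == 1

    def test_juvenile_marked_keeps_adult_portion(self, short_calendar):
        rec = pd.DataFrame(
            {
                "animal_id": ["x", "x"],
                "session": ["1993-10", "1994-05"],
                "sex": ["F", "F"],
                "age": ["juvenile", "adult"],
            }
        )
        keep = pt.build_histories(rec, short_calendar, juvenile_marked="keep_adult")
        assert keep.total_individuals() == 1
        assert "".join(map(str, keep.histories[0])) == "010000"
        with pytest.raises(ValueError):
            # dropping the animal entirely leaves nothing
            pt.build_histories(rec, short_calendar, juvenile_marked="drop_animal")

    def test_unknown_occasion_errors(self, short_calendar, tiny_records):
        bad = tiny_records.copy()
        bad.loc[0, "session"] = "1997-10"
        with pytest.raises(KeyError):
            pt.build_histories(bad, short_calendar)

    def test_unknown_sex_own_group_or_dropped(self, short_calendar):
        rec = pd.DataFrame(
            {
                "animal_id": ["a", "u"],
                "session": ["1993-10", "1993-10"],
                "sex": ["F", "unknown"],
                "age": ["adult", "adult"],
            }
        )
        own = pt.build_histories(rec, short_calendar)
        assert "unknown" in own.groups and own.total_individuals() == 2
        drop = pt.build_histories(rec, short_calendar, unknown_sex="drop")
        assert drop.total_individuals() == 1
        assert drop.dropped["unknown_sex_animals"] == 1

    def test_conservation_of_individuals(self, sim_constant):
        chs = sim_constant.histories
        assert chs.total_individuals() == sim_constant.n_marked()


class TestInpFormat:
    def test_parse_single_group(self, tmp_path):
        p = tmp_path / "a.inp"
        p.write_text("/* demo */\n101 3;\n")
        chs = pt.read_inp(p, group_count=1)
        assert chs.n_patterns == 1
        assert chs.histories[0].tolist() == [1, 0, 1]
        assert chs.counts[0, 0] == 3

    def test_parse_two_groups(self, tmp_path):
        p = tmp_path / "b.inp"
        p.write_text("1100 2 1;\n0011 0 4;\n")
        chs = pt.read_inp(p, group_count=2)
        assert chs.total_individuals() == 7
        assert chs.groups == ["F", "M"]

    @pytest.mark.parametrize(
        "content",
        ["10x1 1;\n", "101 1;\n1001 1;\n", "101 -2;\n", "101 1 2;\n"],
        ids=["nonbinary", "ragged", "negative", "excess-freqs"],
    )
    def test_malformed_lines_rejected(self, tmp_path, content):
        p = tmp_path / "bad.inp"
        p.write_text(content)
        with pytest.raises(ValueError):
            pt.read_inp(p, group_count=1)

    def test_round_trip(self, tmp_path, sim_constant):
        chs = sim_constant.histories
        p = tmp_path / "rt.inp"
        pt.write_inp(chs, p)
        back = pt.read_inp(p, group_count=2, calendar=chs.calendar)
        assert back.equals(chs)
        assert back.total_individuals() == chs.total_individuals()

    def test_empty_set_round_trip(self, tmp_path, short_calendar):
        empty = CaptureHistorySet(
            np.zeros((0, 6), dtype=np.int8), np.zeros((0, 2), dtype=int),
            ["F", "M"], short_calendar,
        )
        p = tmp_path / "empty.inp"
        pt.write_inp(empty, p)
        back = pt.read_inp(p, group_count=2, calendar=short_calendar)
        assert back.n_patterns == 0

    @settings(deadline=None, max_examples=30)
    @given(data=st.data())
    def test_round_trip_property(self, tmp_path_factory, data):
        T = data.draw(st.integers(2, 8))
        n = data.draw(st.integers(1, 12))
        rows = data.draw(
            st.lists(
                st.lists(st.integers(0, 1), min_size=T, max_size=T).filter(
                    lambda r: sum(r) > 0
                ),
                min_size=n,
                max_size=n,
                unique_by=tuple,
            )
        )
        counts = data.draw(
            st.lists(
                st.tuples(st.integers(0, 5), st.integers(0, 5)).filter(
                    lambda c: sum(c) > 0
                ),
                min_size=len(rows),
                max_size=len(rows),
            )
        )
        chs = CaptureHistorySet(
            np.array(rows, dtype=np.int8), np.array(counts), ["F", "M"]
        )
        p = tmp_path_factory.mktemp("inp") / "prop.inp"
        pt.write_inp(chs, p)
        assert pt.read_inp(p, group_count=2).equals(chs)


def test_validation_rejects_bad_sets(short_calendar):
    with pytest.raises(ValueError):
        CaptureHistorySet(np.array([[0, 0]]), np.array([[1]]), ["all"])
    with pytest.raises(ValueError):
        CaptureHistorySet(np.array([[1, 0]]), np.array([[-1]]), ["all"])
    with pytest.raises(ValueError):
        CaptureHistorySet(np.array([[1, 2]]), np.array([[1]]), ["all"])
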
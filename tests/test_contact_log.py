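"""Preprocessing chain: reading, trimming, filtering, union, bouts, phases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from replinet import contact_log as cl
from conftest import intervals_frame, records_frame


# ---------------------------------------------------------------- reading

class TestReadContactLog:
    def test_single_row_identity(self, tmp_path, small_design, tiny_roster):
        p = tmp_path / "log.csv"
        p.write_text("group_id,logger_animal,partner_animal,start_s,duration_s\n"
                     "g1,g1c1,g1c2,100.0,12.5\n")
        rec = cl.read_contact_log(p, small_design, tiny_roster)
        assert len(rec) == 1
        assert rec.loc[0].tolist() == ["g1", "g1c1", "g1c2", 100.0, 12.5]

    def test_header_only_gives_empty(self, tmp_path, small_design, tiny_roster):
        p = tmp_path / "log.csv"
        p.write_text("group_id,logger_animal,partner_animal,start_s,duration_s\n")
        assert cl.read_contact_log(p, small_design, tiny_roster).empty

    def test_self_contact_rejected(self, tmp_path, small_design, tiny_roster):
        p = tmp_path / "log.csv"
        p.write_text("group_id,logger_animal,partner_animal,start_s,duration_s\n"
                     "g1,g1c1,g1c1,0,5\n")
        with pytest.raises(cl.ValidationError, match="line 2"):
            cl.read_contact_log(p, small_design, tiny_roster)

    def test_unknown_animal_and_cross_group_rejected(self, tmp_path, small_design, tiny_roster):
        p = tmp_path / "log.csv"
        p.write_text("group_id,logger_animal,partner_animal,start_s,duration_s\n"
                     "g1,g1c1,ghost,0,5\n")
        with pytest.raises(cl.ValidationError, match="ghost"):
            cl.read_contact_log(p, small_design, tiny_roster)
        p.write_text("group_id,logger_animal,partner_animal,start_s,duration_s\n"
                     "g1,g1c1,g2c1,0,5\n")
        with pytest.raises(cl.ValidationError):
            cl.read_contact_log(p, small_design, tiny_roster)

    def test_malformed_row_names_line(self, tmp_path, small_design, tiny_roster):
        p = tmp_path / "log.csv"
        p.write_text("group_id,logger_animal,partner_animal,start_s,duration_s\n"
                     "g1,g1c1,g1c2,10,5\n"
                     "g1,g1c1,g1c2,oops,5\n")
        with pytest.raises(cl.ContactLogError, match="line 3"):
            cl.read_contact_log(p, small_design, tiny_roster)

    def test_iso_datetime_reader(self, tmp_path, tiny_roster, small_design):
        design = cl.StudyDesign(
            n_groups=2, residents_per_group=3, phases=small_design.phases,
            experiment_start="2019-01-01T06:00:00")
        p = tmp_path / "log.csv"
        p.write_text("group_id,logger_animal,partner_animal,start_time,duration_s\n"
                     "g1,g1c1,g1c2,2019-01-01T06:01:40,12.5\n")
        rec = cl.read_contact_log(p, design, tiny_roster)
        assert rec.loc[0, "start_s"] == 100.0


# ---------------------------------------------------------------- trim / filter

def test_trim_drops_strictly_negative_times(small_design):
    rec = records_frame([("g1", "a", "b", -50.0, 5.0),
                         ("g1", "a", "b", 0.0, 5.0),
                         ("g1", "a", "b", 10.0, 5.0)])
    out = cl.trim_pre_experiment(rec, small_design)
    assert out["start_s"].tolist() == [0.0, 10.0]
    all_before = records_frame([("g1", "a", "b", -3.0, 1.0)])
    assert cl.trim_pre_experiment(all_before, small_design).empty


@pytest.mark.parametrize("threshold, survivors", [(1.0, [1.5]), (0.0, [0.5, 1.0, 1.5])])
def test_filter_short_is_inclusive_at_threshold(threshold, survivors):
    rec = records_frame([("g1", "a", "b", 0, 0.5),
                         ("g1", "a", "b", 10, 1.0),
                         ("g1", "a", "b", 20, 1.5)])
    out = cl.filter_short_contacts(rec, threshold)
    assert out["duration_s"].tolist() == survivors


def test_filter_short_empty_input():
    empty = records_frame([])
    assert cl.filter_short_contacts(empty, 1.0).empty


# ---------------------------------------------------------------- reciprocal union

class TestSymmetrizeReciprocal:
    def test_either_logger_extends_the_contact(self):
        rec = records_frame([("g1", "a", "b", 0.0, 100.0),
                             ("g1", "b", "a", 5.0, 105.0)])
        out = cl.symmetrize_reciprocal(rec)
        assert len(out) == 1
        assert (out.loc[0, "start_s"], out.loc[0, "end_s"]) == (0.0, 110.0)
        assert (out.loc[0, "animal_a"], out.loc[0, "animal_b"]) == ("a", "b")

    def test_disjoint_intervals_stay_separate(self):
        rec = records_frame([("g1", "a", "b", 0.0, 10.0), ("g1", "a", "b", 50.0, 10.0)])
        out = cl.symmetrize_reciprocal(rec)
        assert out["start_s"].tolist() == [0.0, 50.0]
        assert out["end_s"].tolist() == [10.0, 60.0]

    def test_nested_interval_absorbed(self):
        rec = records_frame([("g1", "a", "b", 0.0, 20.0), ("g1", "b", "a", 10.0, 5.0)])
        out = cl.symmetrize_reciprocal(rec)
        assert out["end_s"].tolist() == [20.0]

    def test_touching_intervals_coalesce(self):
        rec = records_frame([("g1", "a", "b", 0.0, 10.0), ("g1", "a", "b", 10.0, 5.0)])
        assert len(cl.symmetrize_reciprocal(rec)) == 1


@st.composite
def record_sets(draw):
    n = draw(st.integers(1, 15))
    rows = []
    for _ in range(n):
        dyad = draw(st.sampled_from([("a", "b"), ("b", "a"), ("a", "c")]))
        start = draw(st.floats(0, 500, allow_nan=False))
        dur = draw(st.floats(0.5, 80, allow_nan=False))
        rows.append(("g1", dyad[0], dyad[1], start, dur))
    return rows


@given(rows=record_sets(), seed=st.integers(0, 10))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_union_is_order_invariant(rows, seed):
    rec = records_frame(rows)
    shuffled = rec.sample(frac=1.0, random_state=seed).reset_index(drop=True)
    a = cl.symmetrize_reciprocal(rec)
    b = cl.symmetrize_reciprocal(shuffled)
    pd.testing.assert_frame_equal(a, b)


@given(rows=record_sets())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_union_dominates_single_logger(rows):
    """Unioned per-dyad contact time is never less than either logger's alone."""
    rec = records_frame(rows)
    both = cl.symmetrize_reciprocal(rec)
    total = (both["end_s"] - both["start_s"]).groupby(
        [both["animal_a"], both["animal_b"]]).sum()
    for logger_animal in rec["logger_animal"].unique():
        one = cl.symmetrize_reciprocal(rec[rec["logger_animal"] == logger_animal])
        single = (one["end_s"] - one["start_s"]).groupby(
            [one["animal_a"], one["animal_b"]]).sum()
        for dyad, dur in single.items():
            assert total[dyad] >= dur - 1e-9


# ---------------------------------------------------------------- bout assembly

def brute_force_merge(intervals, gap):
    """O(n^2) repeated pairwise merging until fixpoint: the bout-assembly oracle."""
    items = [list(pair) for pair in intervals]
    merged = True
    while merged:
        merged = False
        for i in range(len(items)):
            if items[i] is None:
                continue
            for j in range(i + 1, len(items)):
                if items[j] is None:
                    continue
                a, b = items[i], items[j]
                if b[0] - a[1] < gap and a[0] - b[1] < gap:
                    items[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    items[j] = None
                    merged = True
    return sorted(tuple(x) for x in items if x is not None)


class TestAssembleBouts:
    def test_gap_below_separation_merges(self):
        iv = intervals_frame([("g1", "a", "b", 0.0, 10.0), ("g1", "a", "b", 25.0, 40.0)])
        out = cl.assemble_bouts(iv, 30.0)
        assert len(out) == 1 and out.loc[0, "end_s"] == 40.0

    def test_gap_above_separation_splits(self):
        iv = intervals_frame([("g1", "a", "b", 0.0, 10.0), ("g1", "a", "b", 45.0, 60.0)])
        assert len(cl.assemble_bouts(iv, 30.0)) == 2

    def test_gap_exactly_separation_splits(self):
        # merge iff gap < separation_time; an exact 30-s gap keeps two bouts,
        # and re-merging the output changes nothing
        iv = intervals_frame([("g1", "a", "b", 0.0, 10.0), ("g1", "a", "b", 40.0, 50.0)])
        out = cl.assemble_bouts(iv, 30.0)
        assert len(out) == 2
        again = cl.assemble_bouts(out[cl.INTERVAL_COLUMNS], 30.0)
        pd.testing.assert_frame_equal(out, again)


@st.composite
def interval_sets(draw):
    n = draw(st.integers(1, 20))
    out = []
    for _ in range(n):
        start = draw(st.floats(0, 1000, allow_nan=False))
        length = draw(st.floats(0.1, 120, allow_nan=False))
        out.append((start, start + length))
    return out


@given(ivs=interval_sets(), gap=st.sampled_from([5.0, 30.0, 75.0]))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_assembly_matches_brute_force_and_is_idempotent(ivs, gap):
    frame = intervals_frame([("g1", "a", "b", s, e) for s, e in ivs])
    out = cl.assemble_bouts(frame, gap)
    got = sorted(zip(out["start_s"], out["end_s"]))
    expected = brute_force_merge(ivs, gap)
    assert np.allclose(got, expected)
    again = cl.assemble_bouts(out[cl.INTERVAL_COLUMNS], gap)
    pd.testing.assert_frame_equal(out, again)


# ---------------------------------------------------------------- phase assignment

class TestAssignPhases:
    def test_bout_inside_phase(self, small_design):
        b = cl.assemble_bouts(intervals_frame([("g1", "a", "b", 1000.0, 1100.0)]), 30.0)
        out = cl.assign_phases(b, small_design)
        assert out["phase"].tolist() == ["1"]

    def test_straddling_bout_split_conserves_duration(self, small_design):
        boundary = small_design.phases[0].end_s
        b = cl.assemble_bouts(
            intervals_frame([("g1", "a", "b", boundary - 40.0, boundary + 60.0)]), 30.0)
        out = cl.assign_phases(b, small_design)
        assert out["phase"].tolist() == ["1", "2a"]
        assert (out["end_s"] - out["start_s"]).sum() == pytest.approx(100.0)

    def test_bout_after_last_phase_dropped(self, small_design):
        after = small_design.phases[-1].end_s + 100.0
        b = cl.assemble_bouts(intervals_frame([("g1", "a", "b", after, after + 10.0)]), 30.0)
        assert cl.assign_phases(b, small_design).empty

    def test_assign_by_start_policy(self, small_design):
        boundary = small_design.phases[0].end_s
        b = cl.assemble_bouts(
            intervals_frame([("g1", "a", "b", boundary - 40.0, boundary + 60.0)]), 30.0)
        out = cl.assign_phases(b, small_design, policy="start")
        assert out["phase"].tolist() == ["1"]
        assert (out["end_s"] - out["start_s"]).sum() == pytest.approx(100.0)


@given(ivs=interval_sets())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_phase_split_conserves_total_duration(ivs):
    small_design = cl.StudyDesign(
        n_groups=2, residents_per_group=3,
        phases=(cl.Phase("1", 1, 2), cl.Phase("2a", 3, 4), cl.Phase("2b", 5, 6)))
    window = small_design.phases[-1].end_s
    frame = intervals_frame(
        [("g1", "a", "b", s * window / 1200, min(e * window / 1200, window)) for s, e in ivs])
    frame = frame[frame["end_s"] > frame["start_s"]]
    bouts = cl.assemble_bouts(frame, 30.0)
    assigned = cl.assign_phases(bouts, small_design)
    total_before = (bouts["end_s"] - bouts["start_s"]).sum()
    total_after = (assigned["end_s"] - assigned["start_s"]).sum()
    assert total_after == pytest.approx(total_before)


# ---------------------------------------------------------------- full chain

def test_chain_is_identity_on_clean_bouts(small_design):
    """Symmetric records with >1-s durations, >=30-s gaps, inside phases: untouched."""
    rows = []
    for start in (100.0, 200.0, 400.0, 86400.0 * 3 + 50.0):
        rows.append(("g1", "a", "b", start, 50.0))
        rows.append(("g1", "b", "a", start, 50.0))  # perfectly reciprocal logger
    rec = records_frame(rows)
    result = cl.preprocess(rec, small_design)
    assert result.counts["dropped_pre_experiment"] == 0
    assert result.counts["dropped_short"] == 0
    got = list(zip(result.bouts["start_s"], result.bouts["end_s"], result.bouts["phase"]))
    assert got == [(100.0, 150.0, "1"), (200.0, 250.0, "1"), (400.0, 450.0, "1"),
                   (86400.0 * 3 + 50.0, 86400.0 * 3 + 100.0, "2a")]


def test_design_validation_rejects_bad_phases():
    with pytest.raises(ValueError):
        cl.StudyDesign(phases=(cl.Phase("1", 1, 6), cl.Phase("2", 9, 12)))
    with pytest.raises(ValueError):
        cl.StudyDesign(separation_time=0)
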
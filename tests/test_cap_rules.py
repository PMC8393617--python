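"""Annotation parsing, Terzano sequence rules, segmentation, balancing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capdet.cap_rules import (
    AnnotationEvent,
    balance_classes,
    build_cap_sequences,
    cap_parameters_from_times,
    compute_cap_parameters,
    label_and_segment,
    merge_phase_a,
    parse_annotations,
)
from capdet.preprocess import TimeSeries


def A(onset, dur, label="A2"):
    return AnnotationEvent(onset=onset, duration=dur, label=label)


class TestParsing:
    def test_simple_tsv(self):
        events = parse_annotations("10.0\t8.0\tA1", dialect="simple-tsv")
        assert events == [AnnotationEvent(10.0, 8.0, "A1")]

    def test_out_of_order_lines_are_sorted(self):
        text = "50\t5\tA2\n10\t5\tA1\n"
        events = parse_annotations(text)
        assert [e.onset for e in events] == [10.0, 50.0]

    def test_overlapping_a_events_rejected(self):
        with pytest.raises(ValueError, match="10.*12|12.*10"):
            parse_annotations("10\t5\tA1\n12\t5\tA2\n")

    def test_unknown_label_warns_and_skips(self):
        with pytest.warns(UserWarning, match="BOGUS"):
            events = parse_annotations("10\t5\tBOGUS\n20\t5\tA1\n")
        assert len(events) == 1

    def test_unparseable_line_reports_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_annotations("10\t5\tA1\nnot\ta\tnumber\n")

    def test_physionet_dialect_with_midnight_wrap(self):
        text = (
            "Patient: anonymous\n"
            "Sleep Stage\tPosition\tTime [hh:mm:ss]\tEvent\tDuration[s]\tLocation\n"
            "S2\tSupine\t23:59:50\tSLEEP-S2\t30\tC4-A1\n"
            "S2\tSupine\t00:00:10\tMCAP-A1\t8\tC4-A1\n"
            "S2\tSupine\t00:00:40\tMCAP-A3\t6\tC4-A1\n"
            "REM\tSupine\t00:00:50\tSLEEP-REM\t30\tC4-A1\n"
        )
        events = parse_annotations(text.splitlines(), dialect="physionet-cap")
        assert [e.label for e in events] == ["NREM2", "A1", "A3", "REM"]
        assert [e.onset for e in events] == [0.0, 20.0, 50.0, 60.0]


class TestMerge:
    def test_gap_below_two_seconds_merges(self):
        merged = merge_phase_a([A(0, 5), A(6.5, 3.5)])
        assert merged == [AnnotationEvent(0.0, 10.0, "A2")]

    def test_gap_of_exactly_two_seconds_does_not_merge(self):
        merged = merge_phase_a([A(0, 5), A(7, 3)])
        assert len(merged) == 2

    def test_cascading_merge_reaches_fixed_point(self):
        merged = merge_phase_a([A(0, 4), A(5, 3), A(9.5, 2.5)])
        assert merged == [AnnotationEvent(0.0, 12.0, "A2")]

    def test_mixed_subtypes_collapse_to_plain_a(self):
        merged = merge_phase_a([A(0, 5, "A1"), A(6, 4, "A3")])
        assert merged[0].label == "A"

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.floats(0, 500), st.floats(2, 20)),
            min_size=1,
            max_size=12,
        )
    )
    def test_merge_is_idempotent(self, raw):
        events, t = [], 0.0
        for gap, dur in raw:  # build non-overlapping events
            t += gap
            events.append(A(t, dur))
            t += dur
        once = merge_phase_a(events)
        np.testing.assert_array_equal(
            [(e.onset, e.duration) for e in merge_phase_a(once)],
            [(e.onset, e.duration) for e in once],
        )


class TestSequences:
    def test_three_a_phases_form_one_sequence(self):
        seqs = build_cap_sequences([A(0, 10), A(40, 10), A(80, 10)])
        assert len(seqs) == 1
        s = seqs[0]
        assert s.n_a == 3 and s.start == 0.0 and s.end == 90.0
        s.validate()

    def test_two_a_phases_are_not_a_sequence(self):
        assert build_cap_sequences([A(0, 10), A(40, 10)]) == []

    def test_long_gap_isolates_leading_phase(self):
        # gap 90 s > 60 s: first A isolated; remaining two insufficient
        seqs = build_cap_sequences([A(0, 10), A(100, 10), A(140, 10)])
        assert seqs == []

    def test_out_of_range_duration_breaks_chain(self):
        events = [A(0, 10), A(40, 10), A(80, 70), A(180, 10), A(220, 10)]
        assert build_cap_sequences(events) == []

    def test_sequence_events_alternate_and_satisfy_limits(self):
        seqs = build_cap_sequences([A(0, 5), A(20, 5), A(40, 5), A(60, 5)])
        (s,) = seqs
        labels = [e.label for e in s.events]
        assert labels == ["A2", "B", "A2", "B", "A2", "B", "A2"]
        for e in s.events:
            assert 2.0 <= e.duration <= 60.0


class TestCapParameters:
    @pytest.mark.parametrize(
        "cap_time,nrem_time,rate",
        [(144.50, 350.83, 0.41), (221.00, 283.00, 0.78), (180.47, 322.16, 0.56)],
    )
    def test_published_cap_rates(self, cap_time, nrem_time, rate):
        p = cap_parameters_from_times(cap_time, nrem_time)
        assert round(p.cap_rate, 2) == rate

    def test_rate_from_sequences(self):
        seqs = build_cap_sequences([A(0, 10), A(40, 10), A(80, 10)])
        p = compute_cap_parameters(seqs, nrem_time=3.0)
        assert p.cap_time == pytest.approx(1.5)
        assert p.cap_rate == pytest.approx(0.5)

    def test_no_sequences_gives_zero_rate(self):
        assert compute_cap_parameters([], nrem_time=10.0).cap_rate == 0.0

    def test_inconsistent_annotations_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cap_parameters_from_times(400.0, 350.0)


def _recording(duration_s, fs=64.0, n_channels=1, seed=0):
    rng = np.random.default_rng(seed)
    return {
        f"ch{i}": TimeSeries(
            samples=rng.standard_normal(int(duration_s * fs)), fs=fs, label=f"ch{i}"
        )
        for i in range(n_channels)
    }


class TestSegmentation:
    def test_seven_second_a_interval_gives_three_epochs(self):
        ch = _recording(7.0)
        es = label_and_segment(ch, [A(0, 7)], epoch_len=2)
        assert list(es.labels) == ["A", "A", "A"]
        assert es.channels["ch0"].shape == (3, 128)

    def test_interval_shorter_than_epoch_contributes_nothing(self):
        ch = _recording(20.0)
        # B time is 0..1.9 and 11.9..20; the first B interval yields 0 epochs
        es = label_and_segment(ch, [A(1.9, 10.0)], epoch_len=2)
        a_epochs = int(np.sum(es.labels == "A"))
        assert a_epochs == 5

    def test_tiling_arithmetic_on_pure_nrem_minute(self):
        ch = _recording(60.0)
        es = label_and_segment(ch, [A(0, 10)], epoch_len=2)
        counts = es.class_counts()
        assert counts == {"A": 5, "B": 25}

    def test_rem_and_wake_are_excluded(self):
        ch = _recording(120.0)
        events = [
            AnnotationEvent(0, 60, "NREM2"),
            AnnotationEvent(60, 60, "REM"),
            A(10, 10),
            A(70, 10),  # inside REM: must not be segmented
        ]
        es = label_and_segment(ch, events, epoch_len=2)
        assert es.class_counts() == {"A": 5, "B": 25}

    def test_total_labeled_time_matches_nrem(self):
        ch = _recording(300.0)
        events = [AnnotationEvent(0, 300, "NREM2"), A(10, 9), A(50, 21)]
        es = label_and_segment(ch, events, epoch_len=2)
        labeled = es.n_epochs * es.epoch_len
        assert abs(labeled - 300.0) <= 3 * es.epoch_len  # one truncation per interval

    def test_epoch_sample_count_is_exact(self):
        ch = _recording(30.0, fs=64.0)
        es = label_and_segment(ch, [A(3, 8)], epoch_len=1)
        assert es.channels["ch0"].shape[1] == 64


class TestBalancing:
    def _epochs(self, n_a, n_b, fs=64.0, epoch_len=2.0, seed=0):
        rng = np.random.default_rng(seed)
        n = n_a + n_b
        from capdet.cap_rules import EpochSet

        return EpochSet(
            channels={"ch0": rng.standard_normal((n, int(fs * epoch_len)))},
            labels=np.array(["A"] * n_a + ["B"] * n_b),
            epoch_len=epoch_len,
            fs=fs,
        )

    def test_majority_class_reduced_to_minority(self):
        es = balance_classes(self._epochs(100, 60), seed=0)
        assert es.class_counts() == {"A": 60, "B": 60}

    def test_equal_counts_unchanged(self):
        es0 = self._epochs(50, 50)
        es = balance_classes(es0, seed=0)
        np.testing.assert_array_equal(es.channels["ch0"], es0.channels["ch0"])

    def test_seed_determinism(self):
        es0 = self._epochs(100, 60)
        a = balance_classes(es0, seed=7)
        b = balance_classes(es0, seed=7)
        np.testing.assert_array_equal(a.channels["ch0"], b.channels["ch0"])
        c = balance_classes(es0, seed=8)
        assert not np.array_equal(a.channels["ch0"], c.channels["ch0"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            balance_classes(self._epochs(10, 0), seed=0)
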
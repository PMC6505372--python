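"""Tests for stream reading, nonwear detection, masking and aggregation."""

import numpy as np
import pandas as pd
import pytest

from stepagree import (
    StepStream,
    WearMask,
    aggregate_pairs,
    detect_nonwear,
    generate_study,
    mask_streams,
    read_streams,
    write_study,
)
from stepagree.ingest import (
    REASON_NO_STREAM,
    REASON_NO_USABLE_DATA,
    REASON_REFERENCE_ZERO,
)
from stepagree.models import ResolutionError, StreamValidationError
from stepagree.synthetic import default_study_config

from conftest import T0, build_toy_streams, five_minute_stream, minute_stream
from oracles import overlap_minutes_brute, zero_runs_brute


class TestReadStreams:
    def test_round_trip_equals_in_memory_streams(self, tmp_path):
        config = default_study_config(seed=3).model_copy(update={"n_participants": 2})
        streams, manifest = generate_study(config)
        manifest_path = write_study(streams, manifest, tmp_path / "s")
        loaded = read_streams(manifest_path)
        assert len(loaded) == len(streams)
        by_key = {(s.participant_id, s.device_id): s for s in loaded}
        for s in streams:
            other = by_key[(s.participant_id, s.device_id)]
            pd.testing.assert_frame_equal(s.epochs, other.epochs)

    def test_toy_manifest_loads_all_files(self, toy_study_dir):
        assert len(read_streams(toy_study_dir)) == 8

    def test_negative_steps_reported_with_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant_id,device_id,epoch_start_iso8601,epoch_minutes,steps\n"
            "p01,dev,2016-06-06T00:00:00,1,5\n"
            "p01,dev,2016-06-06T00:01:00,1,-3\n"
        )
        manifest = tmp_path / "manifest.csv"
        manifest.write_text(
            "participant_id,device_id,path,is_reference\np01,dev,bad.csv,True\n"
        )
        with pytest.raises(StreamValidationError, match="line 3"):
            read_streams(str(manifest))

    def test_missing_file_names_participant_and_device(self, tmp_path):
        manifest = tmp_path / "manifest.csv"
        manifest.write_text(
            "participant_id,device_id,path,is_reference\np09,devX,gone.csv,True\n"
        )
        with pytest.raises(StreamValidationError, match="p09.*devX"):
            read_streams(str(manifest))

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(StreamValidationError, match="overlap"):
            StepStream(
                "p01",
                "dev",
                pd.DataFrame(
                    {
                        "epoch_start": pd.to_datetime(
                            ["2016-06-06 00:00", "2016-06-06 00:03"]
                        ),
                        "epoch_minutes": [5, 5],
                        "steps": [1, 2],
                    }
                ),
            )


class TestDetectNonwear:
    def ref_with_zero_run(self, run_start, run_len, n_min=72 * 60):
        steps = np.ones(n_min, dtype=int)
        steps[run_start : run_start + run_len] = 0
        return minute_stream("p01", "ref", steps)

    def test_all_zero_stream_is_one_nonworn_interval(self):
        mask = detect_nonwear(minute_stream("p01", "ref", np.zeros(72 * 60, int)))
        assert len(mask.intervals) == 1
        assert mask.intervals["status"].iloc[0] == "nonworn"
        assert mask.window == (T0, T0 + pd.Timedelta(hours=72))

    @pytest.mark.parametrize(
        "threshold,expect_nonworn", [(60, True), (90, True), (91, False), (120, False)]
    )
    def test_ninety_minute_run_against_thresholds(self, threshold, expect_nonworn):
        ref = self.ref_with_zero_run(600, 90)
        mask = detect_nonwear(ref, threshold)
        nonworn = mask.intervals[mask.intervals["status"] == "nonworn"]
        if expect_nonworn:
            assert len(nonworn) == 1
            assert nonworn["start"].iloc[0] == T0 + pd.Timedelta(minutes=600)
            assert nonworn["end"].iloc[0] == T0 + pd.Timedelta(minutes=690)
        else:
            assert len(nonworn) == 0

    def test_runs_one_short_of_threshold_stay_worn(self):
        mask = detect_nonwear(self.ref_with_zero_run(600, 59), 60)
        assert (mask.intervals["status"] == "worn").all()

    def test_matches_brute_force_run_scan(self):
        rng = np.random.default_rng(5)
        steps = (rng.random(2000) > 0.97).astype(int)  # long zero runs, sparse ones
        ref = minute_stream("p01", "ref", steps)
        mask = detect_nonwear(ref, 60)
        expected = zero_runs_brute(list(steps), 60)
        nonworn = mask.intervals[mask.intervals["status"] == "nonworn"]
        got = [
            (
                int((row.start - T0) / pd.Timedelta(minutes=1)),
                int((row.end - T0) / pd.Timedelta(minutes=1)),
            )
            for row in nonworn.itertuples(index=False)
        ]
        assert got == expected

    def test_coarse_reference_rejected(self):
        coarse = five_minute_stream("p01", "ref", np.ones(600, int))
        with pytest.raises(ResolutionError):
            detect_nonwear(coarse)


class TestMaskStreams:
    def simple_mask(self, nonworn_runs, n_min=720):
        steps = np.ones(n_min, dtype=int)
        for a, b in nonworn_runs:
            steps[a:b] = 0
        return detect_nonwear(minute_stream("p01", "ref", steps), 60)

    def test_fully_worn_mask_is_identity(self):
        mask = self.simple_mask([])
        stream = five_minute_stream("p01", "trk", np.ones(720, int) * 3)
        (out,) = mask_streams([stream], mask)
        pd.testing.assert_frame_equal(out.epochs, stream.epochs)

    def test_partial_overlap_scales_proportionally(self):
        # nonworn [60, 122): the 5-min epoch at minute 120 overlaps it by 2
        mask = self.simple_mask([(60, 122)])
        steps = np.zeros(720, int)
        steps[120:125] = 10  # 50 steps in the epoch starting at minute 120
        stream = five_minute_stream("p01", "trk", steps)
        (out,) = mask_streams([stream], mask)
        epoch = out.epochs[out.epochs["epoch_start"] == T0 + pd.Timedelta(minutes=120)]
        assert int(epoch["steps"].iloc[0]) == 30  # round(50 * 3/5)
        worn = [
            (
                int((a - T0) / pd.Timedelta(minutes=1)),
                int((b - T0) / pd.Timedelta(minutes=1)),
            )
            for a, b in mask.worn_intervals()
        ]
        assert overlap_minutes_brute((120, 5), worn) == 3

    def test_masking_never_increases_totals(self):
        rng = np.random.default_rng(11)
        ref_steps = rng.poisson(1.2, 1440)
        ref_steps[300:420] = 0
        mask = detect_nonwear(minute_stream("p01", "ref", ref_steps), 60)
        trk = five_minute_stream("p01", "trk", rng.poisson(5, 1440))
        (out,) = mask_streams([trk], mask)
        assert out.total_steps <= trk.total_steps

    def test_shared_mask_excises_same_wall_clock_time(self):
        mask = self.simple_mask([(60, 180)])
        ref = minute_stream("p01", "ref", np.ones(720, int))
        trk = five_minute_stream("p01", "trk", np.ones(720, int))
        ref_m, trk_m = mask_streams([ref, trk], mask)
        assert ref_m.total_steps == trk_m.total_steps == 720 - 120

    def test_participant_mismatch_raises(self):
        mask = self.simple_mask([])
        with pytest.raises(StreamValidationError):
            mask_streams([minute_stream("p02", "trk", np.ones(720, int))], mask)

    def test_diary_epoch_kept_whole(self):
        mask = self.simple_mask([(0, 360)], n_min=1440)
        diary = StepStream(
            "p01",
            "diary",
            pd.DataFrame(
                {"epoch_start": [T0], "epoch_minutes": [1440], "steps": [8000]}
            ),
        )
        (out,) = mask_streams([diary], mask)
        assert out.total_steps == 8000


class TestAggregatePairs:
    def test_identity_streams_give_equal_totals(self):
        ref = minute_stream("p01", "ref", np.ones(720, int))
        trk = five_minute_stream("p01", "trk", np.ones(720, int))
        ref2 = minute_stream("p02", "ref", np.full(720, 2))
        trk2 = five_minute_stream("p02", "trk", np.full(720, 2))
        paired, excl = aggregate_pairs([ref, trk, ref2, trk2], "ref")
        assert excl.empty
        pairs = paired["trk"].pairs
        assert (pairs["reference_steps"] == pairs["tracker_steps"]).all()

    def test_lost_day_keeps_pair_but_lost_device_excludes(self):
        streams = build_toy_streams()
        masked = []
        by_pid = {}
        for s in streams:
            by_pid.setdefault(s.participant_id, []).append(s)
        for pid, group in by_pid.items():
            ref = next(s for s in group if s.device_id == "actigraph")
            mask = detect_nonwear(ref, 60)
            masked.extend(mask_streams(group, mask))
        paired, excl = aggregate_pairs(masked, "actigraph")
        # p02 lost a tracker day but still pairs; p02 has no trk2 at all
        assert "p02" in set(paired["trk"].pairs["participant_id"])
        assert set(paired["trk2"].pairs["participant_id"]) == {"p01", "p03"}
        assert excl.to_dict(orient="records") == [
            {"participant_id": "p02", "device_id": "trk2", "reason": REASON_NO_STREAM}
        ]

    def test_toy_totals_match_hand_sums(self):
        streams = build_toy_streams()
        masked = []
        for pid in ["p01", "p02", "p03"]:
            group = [s for s in streams if s.participant_id == pid]
            ref = next(s for s in group if s.device_id == "actigraph")
            masked.extend(mask_streams(group, detect_nonwear(ref, 60)))
        paired, _ = aggregate_pairs(masked, "actigraph")
        rows = paired["trk"].pairs.set_index("participant_id")
        # hand sums: 840 waking min/day at 10 (ref) and 9 (trk) steps/min,
        # minus p01's 90-minute nonworn run, minus p02's lost tracker day
        assert rows.loc["p01"].tolist() == [(2520 - 90) * 10, (2520 - 90) * 9]
        assert rows.loc["p02"].tolist() == [2520 * 10, 1680 * 9]
        assert rows.loc["p03"].tolist() == [2520 * 10, 2520 * 9]

    def test_zero_reference_total_excludes_pair(self):
        ref = minute_stream("p01", "ref", np.zeros(720, int))
        trk = five_minute_stream("p01", "trk", np.ones(720, int))
        ref2 = minute_stream("p02", "ref", np.ones(720, int))
        trk2 = five_minute_stream("p02", "trk", np.ones(720, int))
        paired, excl = aggregate_pairs([ref, trk, ref2, trk2], "ref")
        assert len(paired["trk"]) == 1
        assert excl["reason"].tolist() == [REASON_REFERENCE_ZERO]

    def test_empty_tracker_stream_excluded(self):
        ref = minute_stream("p01", "ref", np.ones(720, int))
        trk = StepStream("p01", "trk")
        paired, excl = aggregate_pairs([ref, trk], "ref")
        assert len(paired["trk"]) == 0
        assert excl["reason"].tolist() == [REASON_NO_USABLE_DATA]

    def test_missing_reference_device_raises(self):
        trk = five_minute_stream("p01", "trk", np.ones(720, int))
        with pytest.raises(StreamValidationError):
            aggregate_pairs([trk], "ref")

    def test_epoch_order_is_irrelevant_after_validation(self):
        rng = np.random.default_rng(21)
        steps = rng.poisson(3, 720)
        ordered = minute_stream("p01", "dev", steps)
        shuffled_epochs = ordered.epochs.sample(frac=1, random_state=1)
        shuffled = StepStream("p01", "dev", shuffled_epochs)
        pd.testing.assert_frame_equal(ordered.epochs, shuffled.epochs)
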
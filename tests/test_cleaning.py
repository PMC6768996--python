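"""Track cleaning: filters, features, classification, desegmentation."""
import itertools

import numpy as np
import pandas as pd
import pytest

from dfadrift import cleaning as cl
from dfadrift.cleaning import (AT_SEA, ON_BOARD, SpeedPortRule, basic_filters,
                               classify_positions, clean_and_segment,
                               compute_features, desegment, split_segments,
                               train_position_classifier)
from conftest import segments_from_truth


def make_track(hours, lons, lats, buoy="B1"):
    return pd.DataFrame({
        "buoy_id": buoy,
        "timestamp": pd.Timestamp("2016-01-01") + pd.to_timedelta(hours, "h"),
        "lon": lons, "lat": lats})


class TestBasicFilters:
    def test_single_position_track_removed(self):
        kept, rej = basic_filters(make_track([0], [150.0], [0.0]))
        assert kept.empty
        assert rej.reason.tolist() == ["single_position"]

    def test_duplicate_transmissions_deduplicated(self):
        track = make_track([0, 0, 1, 2, 24], [150.0] * 5, [0.0] * 5)
        kept, rej = basic_filters(track)
        assert len(kept) == 4
        assert (rej.reason == "duplicate").sum() == 1

    def test_speed_spike_dropped_and_rest_kept(self):
        # hourly track with one position implying ~200 km/h
        lons = [150.0, 150.01, 150.02, 152.0, 150.04, 150.05]
        hours = [0, 1, 2, 3, 4, 30]
        track = make_track(hours, lons, [0.0] * 6)
        kept, rej = basic_filters(track, max_speed_kmh=30.0)
        assert (rej.reason == "excess_speed").sum() == 1
        assert rej.loc[rej.reason == "excess_speed", "lon"].iloc[0] == 152.0
        # recomputed speeds between surviving fixes are all realistic
        d = np.diff(kept.lon) * 111.19
        dt = np.diff(kept.timestamp).astype("timedelta64[s]").astype(float) / 3600
        assert np.all(d / dt <= 30.0)

    def test_short_track_removed(self):
        track = make_track([0, 1, 2], [150.0, 150.01, 150.02], [0.0] * 3)
        kept, rej = basic_filters(track, min_duration_h=24.0)
        assert kept.empty
        assert set(rej.reason) == {"short_duration"}

    def test_empty_input_is_not_an_error(self):
        kept, rej = basic_filters(pd.DataFrame(
            columns=["buoy_id", "timestamp", "lon", "lat"]))
        assert kept.empty and rej.empty


class TestFeatures:
    def test_stationary_track_all_zero(self):
        track = make_track(range(10), [150.0] * 10, [0.0] * 10)
        f = compute_features(track)
        assert (f.speed_kmh == 0).all()
        assert (f.accel_kmh2 == 0).all()
        assert (f.heading_change_deg == 0).all()

    def test_one_degree_lat_hop_in_a_day(self):
        track = make_track([0, 24, 48], [150.0] * 3, [0.0, 1.0, 2.0])
        f = compute_features(track)
        assert f.speed_kmh.iloc[1] == pytest.approx(111.19 / 24.0, abs=0.01)

    def test_constant_eastward_course_has_zero_heading_change(self):
        track = make_track(range(8), 150.0 + 0.01 * np.arange(8), [0.0] * 8)
        f = compute_features(track)
        assert np.allclose(f.heading_change_deg.iloc[2:], 0.0, atol=1e-9)

    def test_too_few_positions_raises(self):
        with pytest.raises(ValueError):
            compute_features(make_track([0, 1], [150.0, 150.1], [0.0, 0.0]))


class TestClassifier:
    @staticmethod
    def separable(n=2000, seed=0):
        rng = np.random.default_rng(seed)
        drift_speed = rng.uniform(0.0, 3.0, n // 2)
        vessel_speed = rng.uniform(15.0, 25.0, n // 2)
        f = pd.DataFrame({
            "dt_h": np.ones(n),
            "speed_kmh": np.concatenate([drift_speed, vessel_speed]),
            "accel_kmh2": rng.normal(0, 0.2, n),
            "heading_change_deg": rng.uniform(0, 30, n),
            "dist_to_port_km": rng.uniform(50, 500, n)})
        y = np.array([AT_SEA] * (n // 2) + [ON_BOARD] * (n // 2))
        return f, y

    def test_separable_set_perfect_holdout(self):
        f, y = self.separable()
        m = train_position_classifier(f, y, rng_seed=0)
        assert m.holdout_accuracy == 1.0

    def test_shuffled_labels_give_chance_accuracy(self):
        f, y = self.separable(4000)
        rng = np.random.default_rng(1)
        m = train_position_classifier(f, rng.permutation(y), rng_seed=0)
        assert m.holdout_accuracy == pytest.approx(0.5, abs=0.05)

    def test_same_seed_identical_predictions(self):
        f, y = self.separable()
        m1 = train_position_classifier(f, y, rng_seed=3)
        m2 = train_position_classifier(f, y, rng_seed=3)
        np.testing.assert_array_equal(classify_positions(f, m1),
                                      classify_positions(f, m2))

    def test_single_class_raises(self):
        f, y = self.separable()
        with pytest.raises(ValueError):
            train_position_classifier(f, np.full(len(y), AT_SEA))

    def test_fallback_rule(self):
        f = pd.DataFrame({"dt_h": [1.0, 1.0, 1.0],
                          "speed_kmh": [0.0, 20.0, 0.0],
                          "accel_kmh2": [0.0] * 3,
                          "heading_change_deg": [0.0] * 3,
                          "dist_to_port_km": [500.0, 500.0, 2.0]})
        labels = classify_positions(f, SpeedPortRule())
        assert labels.tolist() == [AT_SEA, ON_BOARD, ON_BOARD]

    def test_model_round_trip(self, tmp_path):
        from dfadrift.cleaning import PositionClassifier
        f, y = self.separable(400)
        m = train_position_classifier(f, y, rng_seed=0)
        m.save(tmp_path / "m.joblib")
        back = PositionClassifier.load(tmp_path / "m.joblib")
        np.testing.assert_array_equal(classify_positions(f, back),
                                      classify_positions(f, m))


def count_runs(lab):
    lab = np.asarray(lab)
    return 1 + int(np.sum(lab[1:] != lab[:-1])) if len(lab) else 0


class TestDesegment:
    def test_isolated_label_flipped(self):
        lab = np.array([AT_SEA, ON_BOARD, AT_SEA, AT_SEA])
        out = desegment(lab, min_run=2)
        assert (out == AT_SEA).all()

    def test_uniform_sequence_unchanged(self):
        lab = np.array([AT_SEA] * 6)
        np.testing.assert_array_equal(desegment(lab, 3), lab)

    @pytest.mark.parametrize("min_run", [2, 3])
    def test_exhaustive_length6_properties(self, min_run):
        # every binary sequence of length 6: idempotent, no short runs
        # survive (unless a single run remains), run count never grows
        for bits in itertools.product([AT_SEA, ON_BOARD], repeat=6):
            lab = np.array(bits)
            out = desegment(lab, min_run)
            runs = count_runs(out)
            assert runs <= count_runs(lab)
            if runs > 1:
                lengths = np.diff(np.concatenate(
                    [[0], np.nonzero(out[1:] != out[:-1])[0] + 1, [6]]))
                assert lengths.min() >= min_run
            np.testing.assert_array_equal(desegment(out, min_run), out)

    def test_long_runs_untouched(self):
        lab = np.array([AT_SEA] * 5 + [ON_BOARD] * 5 + [AT_SEA] * 5)
        np.testing.assert_array_equal(desegment(lab, 3), lab)

    def test_never_increases_runs_on_random_sequences(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            lab = np.where(rng.random(rng.integers(1, 40)) < 0.5,
                           AT_SEA, ON_BOARD)
            assert count_runs(desegment(lab, 3)) <= count_runs(lab)


class TestSegments:
    def test_all_at_sea_single_segment(self):
        track = make_track(range(5), 150 + 0.01 * np.arange(5), [0.0] * 5)
        segs = split_segments(track, [AT_SEA] * 5)
        assert len(segs) == 1
        assert segs[0].deployment[:2] == (150.0, 0.0)

    def test_sea_board_sea_gives_two_segments(self):
        track = make_track(range(9), 150 + 0.01 * np.arange(9), [0.0] * 9)
        labels = [AT_SEA] * 3 + [ON_BOARD] * 3 + [AT_SEA] * 3
        segs = split_segments(track, labels)
        assert [s.segment_index for s in segs] == [1, 2]
        assert len(segs[0]) == 3 and len(segs[1]) == 3
        assert segs[1].deployment[0] == pytest.approx(150.06)

    def test_segment_counts_match_ground_truth(self, vessel_world):
        _, truth, events = vessel_world["test"]
        segs = segments_from_truth(truth)
        pred = pd.Series([s.buoy_id for s in segs]).value_counts()
        true = events[events.event == "deployment"].groupby("buoy_id").size()
        both = pd.concat([true.rename("t"), pred.rename("p")], axis=1).fillna(0)
        assert (both.t == both.p).mean() >= 0.95


class TestEndToEnd:
    def test_pipeline_conservation_and_accuracy(self, vessel_world):
        # classifier trained on an independent fleet from the same world
        mask = vessel_world["mask"]
        _, tr_truth, _ = vessel_world["train"]
        te_tracks, te_truth, _ = vessel_world["test"]
        feats, labels = [], []
        for _, g in tr_truth.groupby("buoy_id", sort=False):
            if len(g) < 3:
                continue
            feats.append(compute_features(g, mask=mask))
            labels.append(g["label"].to_numpy())
        model = train_position_classifier(pd.concat(feats),
                                          np.concatenate(labels), rng_seed=0)
        res = clean_and_segment(te_tracks, model, mask=mask)
        acc = res.accounting()
        assert acc["balance"] == 0
        merged = res.labels.merge(
            te_truth[["buoy_id", "timestamp", "label"]],
            on=["buoy_id", "timestamp"], suffixes=("_pred", "_true"))
        assert len(merged) == len(res.labels)
        accuracy = (merged.label_pred == merged.label_true).mean()
        assert accuracy >= 0.9
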
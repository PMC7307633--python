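import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcxdend import calcium
from pcxdend.calcium import (RoiTraceSet, coactivity, delta_f_over_f,
                             detect_events, detect_fov_events, filter_events,
                             global_event_rate, neuropil_correct, noise_sd)
from pcxdend.synth import gen_ca_movie


class TestDeltaFOverF:
    def test_constant_trace_is_zero(self):
        res = delta_f_over_f(np.full(50, 100.0))
        assert np.allclose(res.dff, 0.0)
        assert res.baseline_sd == 0.0
        assert res.baseline_mean == 100.0

    def test_plateau_doubling_gives_dff_one(self):
        trace = np.concatenate([np.full(20, 50.0), np.full(20, 100.0)])
        res = delta_f_over_f(trace)
        assert res.baseline_mean == pytest.approx(50.0)
        assert np.allclose(res.dff[20:], 1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(10.0, 1000.0), min_size=8, max_size=60))
    def test_window_matches_exhaustive_scan(self, values):
        trace = np.asarray(values)
        res = delta_f_over_f(trace)
        sds = [trace[i:i + 6].std() for i in range(len(trace) - 5)]
        best = int(np.argmin(sds))
        assert res.window_start == best
        assert res.baseline_mean == pytest.approx(trace[best:best + 6].mean())

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            delta_f_over_f(np.full(10, -1.0))


class TestDetectEvents:
    def _trace(self, n=60):
        return np.zeros(n)

    def test_mid_trace_bump_detected_once(self):
        dff = self._trace()
        dff[30:33] = 5.0
        ev = detect_events(dff, baseline_sd=1.0)
        assert len(ev) == 1
        row = ev.iloc[0]
        assert (row.onset, row.offset, row.peak_dff) == (30, 32, 5.0)

    def test_single_frame_spike_ignored(self):
        dff = self._trace()
        dff[30] = 5.0
        assert detect_events(dff, 1.0).empty

    @pytest.mark.parametrize("where", ["start", "end"])
    def test_edge_touching_runs_excluded(self, where):
        dff = self._trace()
        sl = slice(0, 4) if where == "start" else slice(-4, None)
        dff[sl] = 5.0
        assert detect_events(dff, 1.0).empty

    def test_zero_sd_warns_and_counts_positive_excursions(self):
        dff = self._trace()
        dff[10:13] = 0.01
        with pytest.warns(UserWarning, match="zero"):
            ev = detect_events(dff, 0.0)
        assert len(ev) == 1

    def test_events_sorted_and_non_overlapping(self):
        rng = np.random.default_rng(0)
        dff = rng.normal(0, 1, 2000)
        ev = detect_events(dff, 1.0)
        assert (ev["offset"] >= ev["onset"] + 1).all()
        assert (ev["onset"].to_numpy()[1:] > ev["offset"].to_numpy()[:-1]).all()

    def test_affine_rescaling_of_raw_fluorescence_invariant(self):
        rng = np.random.default_rng(1)
        trace = 100.0 + 5.0 * rng.normal(size=400)
        trace[200:205] += 40.0
        def events(t):
            r = delta_f_over_f(t)
            return detect_events(r.dff, noise_sd(r.dff),
                                 baseline_level=float(np.median(r.dff)))
        e1, e2 = events(trace), events(3.7 * trace)
        pd.testing.assert_frame_equal(
            e1[["onset", "offset"]], e2[["onset", "offset"]])

    def test_curation_filters(self):
        ev = pd.DataFrame({"roi_id": [1, 1, 1], "onset": [10, 14, 40],
                           "offset": [12, 16, 45],
                           "peak_dff": [0.5, 0.2, 1.0]})
        out = filter_events(ev, sampling_rate=10.0, min_iei_s=1.0)
        assert list(out["onset"]) == [10, 40]      # smaller-peak neighbour dropped
        out = filter_events(ev, 10.0, min_amplitude=0.4)
        assert list(out["onset"]) == [10, 40]
        out = filter_events(ev, 10.0, min_width=4)
        assert list(out["onset"]) == [40]


class TestNeuropil:
    def test_identical_neuropil_cancels(self):
        movie, labels, _ = gen_ca_movie(seed=0, frames=80, noise_sd=0.0,
                                        neuropil_gain=1.0)
        corrected, _ = neuropil_correct(movie, labels, roi_id=1, seed=1)
        assert np.allclose(corrected, 0.0, atol=1e-12)

    def test_constant_neuropil_leaves_roi_dff(self):
        movie, labels, _ = gen_ca_movie(seed=0, frames=80, noise_sd=0.0,
                                        neuropil_gain=0.0)
        corrected, info = neuropil_correct(movie, labels, roi_id=1, seed=1)
        assert np.allclose(corrected, info["roi_dff"].dff)

    def test_same_seed_same_pixels(self):
        movie, labels, _ = gen_ca_movie(seed=2, frames=60)
        _, a = neuropil_correct(movie, labels, 2, seed=9)
        _, b = neuropil_correct(movie, labels, 2, seed=9)
        assert np.array_equal(a["pixel_rows"], b["pixel_rows"])
        assert np.array_equal(a["pixel_cols"], b["pixel_cols"])
        _, c = neuropil_correct(movie, labels, 2, seed=10)
        assert not np.array_equal(a["pixel_rows"], c["pixel_rows"])


class TestGlobalRate:
    def test_rate_is_count_over_duration(self):
        movie, _, truth = gen_ca_movie(seed=1, frames=3600, n_global=8)
        res = global_event_rate(movie, (0, 64), sampling_rate=10.0)
        assert res.status == "ok"
        assert res.rate_per_min == pytest.approx(len(truth["global_onsets"]) / 6.0)

    def test_flat_movie_zero_rate(self):
        movie = np.full((3100, 8, 8), 100.0)
        movie += np.random.default_rng(0).normal(0, 0.1, movie.shape)
        res = global_event_rate(movie, (0, 8), 10.0)
        assert res.status == "ok" and res.rate_per_min == 0.0

    def test_short_recording_excluded_without_override(self):
        movie = np.full((2400, 8, 8), 100.0)
        res = global_event_rate(movie, (0, 8), 10.0)
        assert res.status == "excluded: < 5 min"
        assert res.rate_per_min is None
        assert global_event_rate(movie, (0, 8), 10.0, allow_short=True).status == "ok"


def _fov(n_rois, n_frames=200, depth=None):
    rng = np.random.default_rng(0)
    return RoiTraceSet(roi_ids=np.arange(n_rois),
                       traces=100 + rng.normal(0, 1e-6, (n_rois, n_frames)),
                       sampling_rate=10.0,
                       depth_norm=depth)


class TestCoactivity:
    def test_four_of_fortynine_fraction(self):
        rois = _fov(50, depth=np.linspace(0, 1, 50))
        rows = [{"roi_id": 0, "onset": 50, "offset": 55, "peak_dff": 1.0}]
        for rid in (1, 2, 3, 4):            # overlapping
            rows.append({"roi_id": rid, "onset": 53, "offset": 60, "peak_dff": 1.0})
        for rid in (5, 6):                  # elsewhere
            rows.append({"roi_id": rid, "onset": 100, "offset": 105, "peak_dff": 1.0})
        records, _ = coactivity(pd.DataFrame(rows), rois)
        ref = records[records.roi_id == 0].iloc[0]
        assert ref.coactive_frac == pytest.approx(4 / 49)
        assert ref.coactive_frac_incl == pytest.approx(5 / 50)

    def test_fully_synchronous_event_gives_one(self):
        n = 12
        rois = _fov(n, depth=np.linspace(0, 1, n))
        ev = pd.DataFrame({"roi_id": range(n), "onset": 20, "offset": 25,
                           "peak_dff": 1.0})
        records, _ = coactivity(ev, rois)
        assert np.allclose(records["coactive_frac"], 1.0)
        assert np.allclose(records["coactive_frac_incl"], 1.0)

    def test_inactive_roi_has_no_record(self):
        rois = _fov(5, depth=np.linspace(0, 1, 5))
        ev = pd.DataFrame({"roi_id": [0, 1], "onset": [10, 12],
                           "offset": [15, 14], "peak_dff": 1.0})
        records, _ = coactivity(ev, rois)
        assert set(records["roi_id"]) == {0, 1}

    def test_event_level_symmetry(self):
        rng = np.random.default_rng(5)
        rois = _fov(8, n_frames=300, depth=np.linspace(0, 1, 8))
        rows = []
        for rid in range(8):
            for onset in rng.integers(5, 280, size=3):
                rows.append({"roi_id": rid, "onset": int(onset),
                             "offset": int(onset) + 5, "peak_dff": 1.0})
        ev = pd.DataFrame(rows)
        # independent oracle: pairwise overlap relation is symmetric, so a
        # pair contributes to both ROIs' coactive sets or neither
        overlap = np.zeros((8, 8), dtype=bool)
        for a in ev.itertuples():
            for b in ev.itertuples():
                if a.roi_id != b.roi_id and a.onset <= b.offset and b.onset <= a.offset:
                    overlap[a.roi_id, b.roi_id] = True
        assert (overlap == overlap.T).all()
        records, _ = coactivity(ev, rois)
        expected = overlap.sum(axis=1) / 7.0   # every ROI here has >=1 event
        # per-ROI mean over events is bounded by the any-overlap fraction
        assert (records.sort_values("roi_id")["coactive_frac"].to_numpy()
                <= expected + 1e-12).all()


class TestMovieAnalysis:
    def test_label_rois_filtered_by_size(self):
        movie, labels, _ = gen_ca_movie(seed=0, frames=60, cell_radius=5)
        rois = calcium.rois_from_labels(movie, labels, 10.0, min_pixels=70)
        assert (rois.pixel_counts >= 70).all()
        with pytest.raises(ValueError, match="pixels"):
            calcium.rois_from_labels(movie, labels, 10.0, min_pixels=10_000)

    def test_movie_pipeline_detects_global_transients(self):
        movie, labels, truth = gen_ca_movie(seed=3, frames=900, cell_radius=5,
                                            n_global=5)
        rois, events = calcium.analyze_movie(movie, labels, 10.0, seed=1,
                                             min_pixels=50)
        assert not events.empty
        # every detection must fall inside the support of some injected
        # transient (plateau + decay), and every ROI must see the events
        onsets = truth["global_onsets"]
        inside = sum(any(o <= ev.onset <= o + 25 for o in onsets)
                     for ev in events.itertuples())
        assert inside == len(events)
        assert set(events["roi_id"]) == set(rois.roi_ids)

    def test_movie_pipeline_seeded(self):
        movie, labels, _ = gen_ca_movie(seed=4, frames=300, cell_radius=5)
        _, a = calcium.analyze_movie(movie, labels, 10.0, seed=5, min_pixels=50)
        _, b = calcium.analyze_movie(movie, labels, 10.0, seed=5, min_pixels=50)
        pd.testing.assert_frame_equal(a, b)

    def test_tiff_round_trip(self, tmp_path):
        import tifffile
        movie, labels, _ = gen_ca_movie(seed=0, frames=80)
        tifffile.imwrite(tmp_path / "m.tif", movie.astype(np.float32))
        tifffile.imwrite(tmp_path / "l.tif", labels.astype(np.uint16))
        m2 = calcium.read_movie_tiff(tmp_path / "m.tif")
        l2 = calcium.read_labels_tiff(tmp_path / "l.tif")
        assert m2.shape == movie.shape and np.array_equal(l2, labels)


def test_detect_fov_events_roundtrip_roi_ids():
    rois = _fov(3)
    rois.traces[1, 50:54] += 40.0
    ev = detect_fov_events(rois)
    assert set(ev["roi_id"]) == {1}
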
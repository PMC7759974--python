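"""Trimming, differential channels, windowing arithmetic, artifact rules
and normalization."""

import numpy as np
import pytest

from gaitmse.io import GaitRecord
from gaitmse.preprocess import (
    CHANNEL_NAMES,
    ArtifactRules,
    SignalWindow,
    average_foot,
    build_channels,
    detect_artifacts,
    differentiate,
    expected_window_count,
    normalize,
    segment_windows,
    trim_initial,
)
from gaitmse.simulate import GaitClassParams, simulate_gait_record


def _record(lf, rf=None, fs=300.0):
    lf = np.asarray(lf, dtype=float)
    rf = lf.copy() if rf is None else np.asarray(rf, dtype=float)
    return GaitRecord("s1", "HC", fs, lf, rf)


class TestTrim:
    def test_five_minute_record_trims_to_280_s(self, rng):
        rec = _record(rng.normal(size=90000))
        out = trim_initial(rec)
        assert out.n_samples == 84000
        np.testing.assert_array_equal(out.lf, rec.lf[6000:])

    def test_zero_trim_is_identity(self, rng):
        rec = _record(rng.normal(size=1000))
        out = trim_initial(rec, trim_s=0.0)
        np.testing.assert_array_equal(out.lf, rec.lf)

    def test_too_short_record_rejected(self, rng):
        rec = _record(rng.normal(size=15 * 300))
        with pytest.raises(ValueError, match="not longer than trim"):
            trim_initial(rec, trim_s=20.0)


class TestChannels:
    def test_average_foot(self):
        np.testing.assert_array_equal(average_foot([2, 4], [4, 8]), [3, 6])
        np.testing.assert_array_equal(average_foot([1, -1], [-1, 1]), [0, 0])
        x = np.arange(5.0)
        np.testing.assert_array_equal(average_foot(x, x), x)

    def test_average_foot_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            average_foot([1, 2], [1, 2, 3])

    def test_differentiate(self):
        np.testing.assert_array_equal(differentiate([1, 3, 6, 10]), [2, 3, 4])
        np.testing.assert_array_equal(differentiate(differentiate([1, 3, 6, 10])), [1, 1])
        assert not differentiate(np.full(10, 3.0)).any()
        with pytest.raises(ValueError):
            differentiate([1.0])

    def test_build_channels_lengths_and_order(self, rng):
        rec = _record(rng.normal(size=100), rng.normal(size=100))
        cs = build_channels(rec)
        assert tuple(cs.channels) == CHANNEL_NAMES
        lengths = [len(v) for v in cs.channels.values()]
        assert lengths == [100, 100, 100, 99, 99, 99, 98, 98, 98]

    def test_af1_is_differentiated_average(self, rng):
        rec = _record(rng.normal(size=50), rng.normal(size=50))
        cs = build_channels(rec)
        np.testing.assert_allclose(
            cs.channels["AF1"], differentiate(average_foot(rec.lf, rec.rf))
        )

    def test_constant_record_gives_zero_differences(self):
        rec = _record(np.full(20, 5.0), np.full(20, 7.0))
        cs = build_channels(rec)
        for name in ("LF1", "LF2", "AF1", "AF2", "RF1", "RF2"):
            assert not cs.channels[name].any()

    def test_build_channels_deterministic(self, rng):
        rec = _record(rng.normal(size=60), rng.normal(size=60))
        a, b = build_channels(rec), build_channels(rec)
        for name in CHANNEL_NAMES:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])


class TestWindowCounts:
    # (l, TW, d, T) -> cohort window totals from the closed form
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((280, 10, 5, 13), 715),
            ((280, 10, 5, 20), 1100),
            ((280, 20, 10, 15), 405),
            ((280, 20, 10, 16), 432),
            ((280, 30, 15, 20), 353),
            ((280, 60, 30, 15), 125),
            ((100, 100, 50, 1), 1),
        ],
    )
    def test_expected_window_count(self, args, expected):
        assert expected_window_count(*args) == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            expected_window_count(5, 10, 5, 1)
        with pytest.raises(ValueError):
            expected_window_count(100, 10, 0, 1)
        with pytest.raises(ValueError):
            expected_window_count(100, 10, 5, 0)

    @pytest.mark.parametrize("tw", [10.0, 20.0, 30.0, 60.0])
    def test_segmentation_matches_closed_form(self, rng, tw):
        """Emitted per-cohort window counts match the closed-form total for
        equal-length records: exactly when the per-subject count is whole,
        within the truncated fractional remainder (< T windows) otherwise."""
        T = 3
        l_s, fs = 140.0, 50.0
        per_subject = int((l_s - tw) // (tw / 2)) + 1
        total = 0
        for _ in range(T):
            rec = _record(rng.normal(size=int(l_s * fs)), fs=fs)
            ws = segment_windows(build_channels(rec), tw)
            assert ws.n_total == per_subject
            total += ws.n_total
        closed_form = expected_window_count(l_s, tw, tw / 2, T)
        if ((l_s - tw) / (tw / 2)) % 1 == 0:
            assert total == closed_form
        else:
            assert 0 < closed_form - total < T


class TestSegmentation:
    def test_window_equals_record_length(self, rng):
        rec = _record(rng.normal(size=500), fs=50.0)
        ws = segment_windows(build_channels(rec), 10.0)
        assert ws.n_total == 1

    def test_no_overlap_tiles(self, rng):
        rec = _record(rng.normal(size=int(280 * 50)), fs=50.0)
        ws = segment_windows(build_channels(rec), 10.0, overlap_fraction=0.0)
        assert ws.n_total == 28

    def test_fifty_percent_overlap_shares_half_the_samples(self, rng):
        rec = _record(rng.normal(size=3000), fs=100.0)
        ws = segment_windows(build_channels(rec), 10.0)
        w0, w1 = ws.windows[0], ws.windows[1]
        n = len(w0.segments["LF"])
        np.testing.assert_array_equal(w0.segments["LF"][n // 2 :], w1.segments["LF"][: n // 2])
        assert w1.start_s - w0.start_s == pytest.approx(5.0)

    def test_all_segments_full_length(self, rng):
        rec = _record(rng.normal(size=3000), fs=100.0)
        ws = segment_windows(build_channels(rec), 10.0)
        for w in ws.windows:
            for name in CHANNEL_NAMES:
                assert len(w.segments[name]) == 1000

    def test_window_longer_than_record_rejected(self, rng):
        rec = _record(rng.normal(size=100), fs=100.0)
        with pytest.raises(ValueError, match="exceeds record length"):
            segment_windows(build_channels(rec), 10.0)


def _window_from(segments, fs=300.0):
    full = {name: np.asarray(segments.get(name, segments["LF"]), dtype=float)
            for name in CHANNEL_NAMES}
    return SignalWindow(0, "s1", "HC", 0.0, len(full["LF"]) / fs, fs, full)


class TestArtifacts:
    def test_flatline_all_zero_segment(self, rng):
        seg = {name: rng.normal(size=3000) for name in CHANNEL_NAMES}
        seg["LF"] = np.zeros(3000)
        assert detect_artifacts(_window_from(seg)) is True

    def test_partial_flat_run_detected(self, rng):
        lf = rng.normal(size=3000)
        lf[1000:1700] = 0.25  # 700 samples > 2 s at 300 Hz
        seg = {name: rng.normal(size=3000) for name in CHANNEL_NAMES}
        seg["LF"] = lf
        assert detect_artifacts(_window_from(seg)) is True

    def test_clean_synthetic_window_passes(self):
        rec = simulate_gait_record(
            GaitClassParams(label="HC"), duration_s=40.0, fs=300.0, seed=3
        )
        ws = segment_windows(build_channels(rec), 10.0)
        assert detect_artifacts(ws.windows[1]) is False

    def test_clipping_detected(self, rng):
        lf = rng.normal(size=3000)
        lf[lf > np.quantile(lf, 0.95)] = lf.max()  # 5% saturated at the ceiling
        seg = {name: rng.normal(size=3000) for name in CHANNEL_NAMES}
        seg["LF"] = lf
        assert detect_artifacts(_window_from(seg)) is True

    def test_dropout_flags_not_crashes(self, rng):
        seg = {name: rng.normal(size=3000) for name in CHANNEL_NAMES}
        seg["RF1"] = seg["RF1"].copy()
        seg["RF1"][10] = np.nan
        assert detect_artifacts(_window_from(seg)) is True

    def test_exclusion_list(self, rng):
        seg = {name: rng.normal(size=3000) for name in CHANNEL_NAMES}
        w = _window_from(seg)
        rules = ArtifactRules(exclude={("s1", 0)})
        assert detect_artifacts(w, rules) is True
        assert detect_artifacts(w) is False


class TestNormalize:
    def test_minmax_example(self):
        np.testing.assert_allclose(normalize([0, 5, 10], "minmax"), [0, 0.5, 1])

    def test_zscore_moments(self, rng):
        out = normalize(rng.normal(2.0, 3.0, size=500), "zscore")
        assert abs(out.mean()) < 1e-12
        assert abs(out.std() - 1.0) < 1e-12

    @pytest.mark.parametrize("method", ["minmax", "zscore"])
    def test_constant_degenerates_to_zeros_with_warning(self, method, caplog):
        with caplog.at_level("WARNING"):
            out = normalize([7.0, 7.0, 7.0], method)
        np.testing.assert_array_equal(out, np.zeros(3))
        assert any("degenerate" in r.message for r in caplog.records)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown"):
            normalize([1.0, 2.0], "robust")
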
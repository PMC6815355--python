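"""Voxel metrics, enhancement-pattern classification, and VOI aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from dceperf import (
    ClassifierThresholds,
    DceSeries,
    EnhancementPattern,
    InvalidVoxelError,
    PerfusionQuantifier,
    RelativeTic,
    SynthImagingConfig,
    TicPatternClassifier,
    VoiMask,
    classify_voxel,
    compute_ire,
    compute_irw,
    compute_me,
    compute_relative_tic,
    compute_voxel_metrics,
    detect_onset,
    generate_canonical_tic,
    generate_dce_volume,
    summarize_voi,
)

NE, PERS, PLAT, WASH = EnhancementPattern


def series_from_tics(tics, frame_spacing_s=9.0, n_baseline_frames=2):
    """Wrap a list of 1D TICs into a one-row DceSeries + single-VOI mask."""
    arr = np.asarray(tics, dtype=float)[None, :, None, :]  # (1, n, 1, t)
    mask = VoiMask(np.ones((1, arr.shape[1], 1), dtype=int))
    return DceSeries(arr, frame_spacing_s, n_baseline_frames), mask


class TestRelativeTic:
    def test_hand_division(self):
        series, _ = series_from_tics([[100, 100, 150, 200]])
        tic = compute_relative_tic(series, (0, 0, 0))
        np.testing.assert_allclose(tic.s, [1.0, 1.0, 1.5, 2.0])

    def test_constant_series_is_unit(self):
        series, _ = series_from_tics([[80.0] * 6])
        assert np.allclose(compute_relative_tic(series, (0, 0, 0)).s, 1.0)

    def test_zero_baseline_is_invalid(self):
        series, _ = series_from_tics([[0, 0, 150, 200]])
        with pytest.raises(InvalidVoxelError):
            compute_relative_tic(series, (0, 0, 0))


class TestOnsetMePeak:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ([1, 1, 1.05, 1.2, 1.5], 3),
            ([1.0] * 5, None),
            ([1, 1, 1.10], 2),  # threshold crossing is inclusive
        ],
    )
    def test_onset_detection(self, s, expected):
        assert detect_onset(RelativeTic(np.array(s), 2)) == expected

    @pytest.mark.parametrize(
        "s,me,peak",
        [
            ([1, 1, 1.5, 2.0, 1.8], 2.0, 3),
            ([1.0] * 5, 1.0, 2),
            ([1, 1, 2.0, 2.0, 1.5], 2.0, 2),  # tie: first attainment
        ],
    )
    def test_me_and_peak(self, s, me, peak):
        got_me, got_peak = compute_me(RelativeTic(np.array(s), 2))
        assert got_me == pytest.approx(me) and got_peak == peak


class TestIreIrw:
    def test_ire_slope_formula(self):
        tic = RelativeTic(np.array([1, 1, 1.2, 1.6, 2.0, 2.0]), 2, 9.0)
        assert compute_ire(tic, 2, 4) == pytest.approx(100 * 0.8 / 18, abs=1e-9)

    def test_ire_single_step_fallback(self):
        tic = RelativeTic(np.array([1, 1, 2.0, 2.0, 2.0]), 2, 9.0)
        assert compute_ire(tic, 2, 2) == pytest.approx(100 * 1.0 / 9, abs=1e-9)

    def test_ire_floored_at_zero(self):
        tic = RelativeTic(np.array([1, 1, 1.5, 1.5, 1.5]), 2, 9.0)
        # zero-slope segment between onset and a later equal frame
        assert compute_ire(tic, 2, 4) == 0.0

    def test_ire_requires_onset(self):
        tic = RelativeTic(np.ones(6), 2, 9.0)
        with pytest.raises(ValueError, match="onset"):
            compute_ire(tic, None, 3)

    def test_irw_closed_form_decline(self):
        s = np.concatenate([[1, 1], np.linspace(1, 2, 8), 2 - 0.02 * np.arange(1, 11)])
        tic = RelativeTic(s, 2, 9.0)
        peak = int(np.argmax(s))
        assert compute_irw(tic, peak) == pytest.approx(-0.02 * 100 / 9, abs=1e-9)

    def test_irw_flat_is_zero_and_final_peak_absent(self):
        s = np.concatenate([[1, 1], np.linspace(1, 2, 8), np.full(10, 2.0)])
        tic = RelativeTic(s, 2, 9.0)
        assert compute_irw(tic, 10) == pytest.approx(0.0, abs=1e-12)
        assert compute_irw(tic, len(s) - 1) is None


class TestClassification:
    def test_flat_curve_no_enhancement(self):
        assert classify_voxel(np.ones(30)) == NE

    def test_twenty_percent_late_drop_is_washout(self):
        t = np.arange(30, dtype=float)
        s = np.where(t < 3, 1.0, np.where(t <= 10, 1 + (t - 3) / 7, 2.0 - 0.4 * (t - 10) / 19))
        assert classify_voxel(s) == WASH

    def test_canonical_palette_semantics(self):
        # persistent keeps rising; plateau rises then holds
        assert classify_voxel(generate_canonical_tic("persistent")) == PERS
        assert classify_voxel(generate_canonical_tic("plateau")) == PLAT
        assert classify_voxel(generate_canonical_tic("washout")) == WASH

    def test_thresholds_validation(self):
        with pytest.raises(ValueError):
            ClassifierThresholds(theta_enh=0.0)
        with pytest.raises(ValueError):
            ClassifierThresholds(smooth_window=4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e4), pattern=st.sampled_from([PERS, PLAT, WASH]))
    def test_scale_invariance_of_metrics_and_class(self, scale, pattern):
        tic = generate_canonical_tic(pattern, noise_sd=0.02, rng=7)
        base = series_from_tics([100 * tic])[0]
        scaled = series_from_tics([100 * scale * tic])[0]
        m1 = compute_voxel_metrics(compute_relative_tic(base, (0, 0, 0)))
        m2 = compute_voxel_metrics(compute_relative_tic(scaled, (0, 0, 0)))
        assert m1.pattern == m2.pattern
        assert m1.me == pytest.approx(m2.me, abs=1e-12)
        assert m1.ire == pytest.approx(m2.ire, abs=1e-12)
        assert m1.onset_frame == m2.onset_frame and m1.peak_frame == m2.peak_frame


def metrics_row(x, pattern, me=np.nan, ire=np.nan, voi="extensor", valid=True):
    return dict(x=x, y=0, z=0, voi=voi, valid=valid, pattern=int(pattern), me=me,
                ire=ire, irw=np.nan, onset_frame=None, peak_frame=None)


class TestVoiSummary:
    def make_mask(self, n, label=1):
        m = np.zeros((n, 1, 1), dtype=int)
        m[:, 0, 0] = label
        return VoiMask(m)

    def test_hand_arithmetic_from_table_definitions(self):
        # 10 voxels: 4 highly perfused; enhancing voxels have mean IRE 0.5, mean ME 1.8
        rows = (
            [metrics_row(i, PLAT, me=1.8, ire=0.5) for i in range(2)]
            + [metrics_row(i + 2, WASH, me=1.8, ire=0.5) for i in range(2)]
            + [metrics_row(i + 4, PERS, me=1.8, ire=0.5) for i in range(2)]
            + [metrics_row(i + 6, NE, me=1.0) for i in range(4)]
        )
        summ = summarize_voi(pd.DataFrame(rows), self.make_mask(10), "extensor")
        assert summ.nvoxel == 4
        assert summ.nvoxel_pct == pytest.approx(40.0)
        assert summ.ire_x_nvoxel == pytest.approx(2.0)
        assert summ.ire_x_nvoxel_pct == pytest.approx(20.0)
        assert summ.me_x_nvoxel == pytest.approx(7.2)
        assert summ.me_x_nvoxel_pct == pytest.approx(72.0)

    def test_all_non_enhancing_gives_zero_composites(self):
        rows = [metrics_row(i, NE, me=1.0) for i in range(5)]
        summ = summarize_voi(pd.DataFrame(rows), self.make_mask(5), "extensor")
        assert summ.nvoxel == 0
        assert (summ.ire_x_nvoxel, summ.ire_x_nvoxel_pct, summ.me_x_nvoxel,
                summ.me_x_nvoxel_pct) == (0.0, 0.0, 0.0, 0.0)

    def test_empty_voi_errors(self):
        rows = [metrics_row(i, NE) for i in range(5)]
        with pytest.raises(ValueError, match="no voxels"):
            summarize_voi(pd.DataFrame(rows), self.make_mask(5, label=1), "flexor")


class TestQuantifier:
    def test_pooling_identity_and_composite_consistency(self, small_phantom):
        _, series, mask, _ = small_phantom
        q = PerfusionQuantifier().fit(series, mask)
        s = q.summaries_.set_index("voi_label")
        assert s.loc["total", "nvoxel"] == s.loc["extensor", "nvoxel"] + s.loc["flexor", "nvoxel"]
        for _, row in q.summaries_.iterrows():
            assert row.ire_x_nvoxel_pct * row.n_total_voxels == pytest.approx(
                100.0 * row.ire_x_nvoxel, rel=1e-12
            )
            assert row.nvoxel_pct == pytest.approx(100.0 * row.nvoxel / row.n_total_voxels)

    def test_noise_free_recovery_is_exact(self, small_phantom):
        _, series, mask, labels = small_phantom
        q = PerfusionQuantifier().fit(series, mask)
        vm = q.voxel_metrics_
        truth = labels[vm["x"], vm["y"], vm["z"]]
        assert (vm["pattern"].to_numpy() == truth).all()

    def test_accuracy_non_increasing_in_noise(self):
        accs = []
        for sd in (0.0, 0.05, 0.15):
            cfg = SynthImagingConfig(grid_dims=(14, 14, 2), noise_sd=sd, seed=21)
            series, mask, labels = generate_dce_volume(cfg)
            vm = PerfusionQuantifier().fit(series, mask).voxel_metrics_
            truth = labels[vm["x"], vm["y"], vm["z"]]
            accs.append((vm["pattern"].to_numpy() == truth).mean())
        assert accs[0] == 1.0
        assert accs[0] >= accs[1] >= accs[2]

    def test_dimension_mismatch_raises(self, small_phantom):
        _, series, _, _ = small_phantom
        bad_mask = VoiMask(np.ones((3, 3, 3), dtype=int))
        with pytest.raises(ValueError, match="dims"):
            PerfusionQuantifier().fit(series, bad_mask)

    def test_invalid_voxels_are_excluded_and_counted(self):
        tics = np.tile(np.linspace(100, 200, 8), (3, 1))
        tics[1, :2] = 0.0  # zero baseline
        series, mask = series_from_tics(tics)
        q = PerfusionQuantifier().fit(series, mask)
        assert q.n_invalid_ == 1
        assert int(q.voxel_metrics_["valid"].sum()) == 2
        assert q.summaries_.set_index("voi_label").loc["extensor", "n_total_voxels"] == 3


class TestParametricMaps:
    def test_flat_volume_pattern_map_zero_in_mask(self):
        cfg = SynthImagingConfig(
            grid_dims=(8, 8, 2), pattern_mix=(1.0, 0, 0, 0), noise_sd=0.0, seed=2
        )
        series, mask, _ = generate_dce_volume(cfg)
        q = PerfusionQuantifier().fit(series, mask)
        pat = q.parametric_map("pattern")
        assert pat.shape == mask.labels.shape
        assert np.all(pat[mask.labels != 0] == 0)
        assert np.all(pat[mask.labels == 0] == -1)

    def test_ire_map_matches_worked_example(self):
        series, mask = series_from_tics([[100, 100, 120, 160, 200, 200]])
        q = PerfusionQuantifier().fit(series, mask)
        ire_map = q.parametric_map("ire")
        assert ire_map[0, 0, 0] == pytest.approx(100 * 0.8 / 18, abs=1e-9)

    def test_unknown_map_name_raises(self, small_phantom):
        _, series, mask, _ = small_phantom
        q = PerfusionQuantifier().fit(series, mask)
        with pytest.raises(ValueError, match="unknown parametric map"):
            q.parametric_map("ktrans")


class TestSklearnSurface:
    def test_classifier_predict_and_clone(self):
        X = np.stack(
            [generate_canonical_tic(p) for p in (NE, PERS, PLAT, WASH)]
        )
        clf = TicPatternClassifier()
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
        pred = clf.fit(X).predict(X)
        np.testing.assert_array_equal(pred, [int(NE), int(PERS), int(PLAT), int(WASH)])
        frame = clf.metrics_frame(X)
        assert list(frame["pattern"]) == [int(NE), int(PERS), int(PLAT), int(WASH)]
        assert frame.loc[3, "me"] == pytest.approx(2.2)

    def test_set_params_changes_behaviour(self):
        # a huge enhancement threshold suppresses every class
        X = np.stack([generate_canonical_tic(PLAT)])
        clf = TicPatternClassifier().set_params(theta_enh=5.0)
        assert clf.fit(X).predict(X)[0] == int(NE)
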
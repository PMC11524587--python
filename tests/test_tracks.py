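"""Trajectory processing: imputation, smoothing, normalisation, peaks,
correlations, AUC arithmetic and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reladyn import simulate
from reladyn.simulate import SimulationConfig, simulate_tracks
from reladyn.tracks import (
    Track,
    auc_fold_change,
    compare_groups,
    compute_auc,
    detect_peak,
    impute_interior,
    iter_tracks,
    normalize_auc,
    normalize_to_solvent_control,
    sg_smooth,
    within_track_correlation,
)

from conftest import make_track


class TestImputeInterior:
    @pytest.mark.parametrize("values, expected", [
        ([1, np.nan, 3], [1, 2, 3]),
        ([1, np.nan, np.nan, 4], [1, 2, 3, 4]),
    ])
    def test_interior_gaps_linearly_interpolated(self, values, expected):
        out = impute_interior(make_track(values))
        np.testing.assert_allclose(out.values, expected)
        assert not out.edge_missing

    def test_leading_gap_left_missing_and_flagged(self):
        out = impute_interior(make_track([np.nan, 2, 3]))
        assert np.isnan(out.values[0])
        np.testing.assert_allclose(out.values[1:], [2, 3])
        assert out.edge_missing

    def test_all_missing_track_rejected(self):
        with pytest.raises(ValueError, match="all-missing"):
            impute_interior(make_track([np.nan, np.nan, np.nan]))


class TestSavitzkyGolay:
    def test_constant_track_unchanged(self):
        track = make_track(np.full(20, 7.0))
        out = sg_smooth(track, order=1, window=7)
        np.testing.assert_allclose(out.values, 7.0)

    def test_cubic_polynomial_reproduced_exactly(self):
        t = np.arange(30) * 10.0
        values = 1e-4 * t**3 - 0.02 * t**2 + 3 * t + 5
        out = sg_smooth(Track(t, values), order=3, window=11)
        np.testing.assert_allclose(out.values, values, rtol=1e-9, atol=1e-9)

    def test_matches_direct_sliding_least_squares_oracle(self, rng):
        # Oracle: at each interior point, fit the window polynomial by
        # explicit least squares and evaluate at the centre.
        order, window = 3, 11
        half = window // 2
        values = np.sin(np.arange(60) / 6) + rng.normal(0, 0.1, 60)
        out = sg_smooth(make_track(values), order, window)
        for i in range(half, 60 - half):
            x = np.arange(-half, half + 1)
            coeffs = np.polynomial.polynomial.polyfit(x, values[i - half:i + half + 1], order)
            assert out.values[i] == pytest.approx(coeffs[0], abs=1e-9)

    @pytest.mark.parametrize("order, window", [(3, 10), (3, 3), (5, 5)])
    def test_invalid_window_rejected(self, order, window):
        with pytest.raises(ValueError):
            sg_smooth(make_track(np.ones(30)), order, window)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="impute"):
            sg_smooth(make_track([1, np.nan, 3, 4, 5, 6, 7]), 1, 7)


def _two_condition_frame(drift=None, scale=1.0):
    cfg_ctrl = SimulationConfig(doses=(0.0,), n_cells_per_condition=8,
                                noise_sd=0.0, dropout_rate=0.0, seed=1)
    cfg_tnf = SimulationConfig(doses=(10.0,), n_cells_per_condition=8,
                               noise_sd=0.0, dropout_rate=0.0, seed=2)
    a, _ = simulate_tracks(cfg_ctrl)
    b, _ = simulate_tracks(cfg_tnf)
    b["cell_id"] = "tnf_" + b["cell_id"]
    frame = pd.concat([a, b], ignore_index=True)
    frame["nuc_intensity"] *= scale
    if drift is not None:
        frame["nuc_intensity"] *= drift(frame["time_min"].to_numpy())
    return frame


class TestControlNormalisation:
    def test_control_mean_exactly_one_at_every_timepoint(self):
        out = normalize_to_solvent_control(_two_condition_frame())
        ctrl_means = (
            out[out["dose_ng_ml"] == 0]
            .groupby(["cell_line", "time_min"])["nuc_intensity"].mean()
        )
        np.testing.assert_allclose(ctrl_means.to_numpy(), 1.0, rtol=1e-12)

    def test_invariant_to_global_intensity_rescaling(self):
        base = normalize_to_solvent_control(_two_condition_frame())
        scaled = normalize_to_solvent_control(_two_condition_frame(scale=37.5))
        np.testing.assert_allclose(
            base["nuc_intensity"], scaled["nuc_intensity"], rtol=1e-12
        )

    def test_multiplicative_photobleaching_drift_cancels(self):
        # Oracle: apply a known time-varying decay to all wells and verify
        # the normalised output is unchanged.
        drift = lambda t: np.exp(-(t - t.min()) / 800.0)
        base = normalize_to_solvent_control(_two_condition_frame())
        drifted = normalize_to_solvent_control(_two_condition_frame(drift=drift))
        np.testing.assert_allclose(
            base["nuc_intensity"], drifted["nuc_intensity"], rtol=1e-10
        )

    def test_missing_control_stratum_is_an_error(self):
        frame = _two_condition_frame()
        frame = frame[frame["dose_ng_ml"] != 0]
        with pytest.raises(ValueError, match="control"):
            normalize_to_solvent_control(frame)


class TestDetectPeak:
    def test_constant_track_peaks_at_first_post_stimulus_timepoint(self):
        track = make_track(np.full(40, 5.0), t0_index=12)
        call = detect_peak(track)
        assert call.peak_time == 10.0
        assert call.peak_amplitude == pytest.approx(1.0)
        assert not call.censored

    def test_strictly_increasing_track_is_censored_at_the_end(self):
        track = make_track(np.linspace(1, 9, 40), t0_index=0)
        call = detect_peak(track)
        assert call.censored
        assert call.peak_time == track.times[-1]

    def test_gaussian_hump_peak_recovered_within_one_interval(self):
        # Oracle: brute-force scan of the smoothed forward differences.
        t = -120 + 10.0 * np.arange(73)
        values = 1 + 2 * np.exp(-((t - 200.0) ** 2) / (2 * 80.0**2))
        track = Track(t, values)
        call = detect_peak(track)
        assert abs(call.peak_time - 200.0) <= 10.0
        smoothed = sg_smooth(track, 3, 11)
        slopes = np.diff(smoothed.values)
        scan = next(i for i in range(len(slopes))
                    if t[i] > 0 and slopes[i] <= 0)
        assert call.peak_time == t[scan]

    def test_amplitude_is_relative_to_prestimulus_baseline(self):
        t = -120 + 10.0 * np.arange(73)
        values = np.where(t <= 0, 4.0, 4.0 + 8.0 * (1 - np.exp(-t / 20.0))
                          * np.exp(-t / 100.0))
        call = detect_peak(Track(t, values))
        assert call.peak_amplitude == pytest.approx(
            values[np.argmax(values)] / 4.0, rel=0.05
        )

    def test_track_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            detect_peak(make_track(np.ones(5)))

    def test_noise_free_damped_simulation_recovers_planted_peaks(self):
        cfg = SimulationConfig(doses=(10.0,), n_cells_per_condition=500,
                               noise_sd=0.0, dropout_rate=0.0,
                               sustain_mode="damped", seed=42)
        frame, truth = simulate_tracks(cfg)
        planted = truth.set_index("cell_id")["peak_time"]
        hits = 0
        for track in iter_tracks(frame):
            call = detect_peak(track)
            hits += abs(call.peak_time - planted[track.cell_id]) <= cfg.dt
        assert hits / len(planted) >= 0.99


class TestWithinTrackCorrelation:
    @staticmethod
    def _frame_from_matrix(values_by_time, line="L", dose=10.0):
        rows = []
        for c, series in enumerate(values_by_time):
            for t, v in series.items():
                rows.append({"cell_id": f"c{c}", "cell_line": line,
                             "sirna": "NT", "dose_ng_ml": dose, "bio_rep": "R1",
                             "well": "W1", "time_min": t, "nuc_intensity": v})
        return pd.DataFrame(rows)

    def test_perfectly_sustained_cells_give_r_of_one(self):
        # heterogeneous per-cell fold amplitudes, identical at 60 and 180 min
        cells = [{0.0: 1.0, 60.0: a, 180.0: a} for a in (1.0, 2.0, 5.0, 9.0)]
        frame = self._frame_from_matrix(cells)
        out = within_track_correlation(frame, t_cmp=(180.0,))
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_identical_cells_flagged_undefined_not_zero(self):
        cells = [{0.0: 1.0, 60.0: 2.0, 180.0: 3.0}] * 5
        out = within_track_correlation(self._frame_from_matrix(cells),
                                       t_cmp=(180.0,))
        assert out.loc[0, "undefined"]
        assert np.isnan(out.loc[0, "r"])

    def test_damped_heterogeneity_decorrelates_late_timepoints(self):
        # Oracle: seeded damped simulation with per-cell decay rates;
        # correlation with 600 min must fall below that with 180 min.
        cfg = SimulationConfig(doses=(10.0,), n_cells_per_condition=200,
                               sustain_mode="damped", decay_cv=0.5,
                               noise_sd=0.5, dropout_rate=0.0, seed=8)
        frame, _ = simulate_tracks(cfg)
        out = within_track_correlation(frame).set_index("t_cmp")
        assert out.loc[600.0, "r"] < out.loc[180.0, "r"]


class TestAUC:
    def test_constant_one_over_720_minutes_integrates_to_720(self):
        track = make_track(np.ones(73))
        res = compute_auc(track, (0.0, 720.0))
        assert res.auc == pytest.approx(720.0, rel=1e-12)

    def test_linear_ramp_integrates_to_triangle_area(self):
        track = Track(np.linspace(0, 100, 11), np.linspace(0, 1, 11))
        assert compute_auc(track, (0.0, 100.0)).auc == pytest.approx(50.0, rel=1e-12)

    def test_quadratic_samples_match_closed_form(self):
        t = np.linspace(0, 1, 200)
        res = compute_auc(Track(t, t**2), (0.0, 1.0))
        assert res.auc == pytest.approx(1 / 3, rel=1e-4)

    def test_additivity_over_adjacent_windows(self, rng):
        values = rng.random(73) * 5
        track = make_track(values)
        full = compute_auc(track, (0.0, 720.0)).auc
        left = compute_auc(track, (0.0, 335.0)).auc
        right = compute_auc(track, (335.0, 720.0)).auc
        assert left + right == pytest.approx(full, rel=1e-9)

    def test_window_outside_span_rejected(self):
        with pytest.raises(ValueError, match="window"):
            compute_auc(make_track(np.ones(5)), (0.0, 100.0))


class TestAUCNormalisation:
    def test_reference_group_means_are_one_per_stratum(self, sirna_auc_table):
        out = normalize_auc(sirna_auc_table)
        ref = out[out["sirna"] == "NT"]
        means = ref.groupby(["bio_rep"])["auc_norm"].mean()
        np.testing.assert_allclose(means, 1.0)

    def test_scale_invariance_within_stratum(self, sirna_auc_table):
        doubled = sirna_auc_table.copy()
        mask = doubled["bio_rep"] == "R1"
        doubled.loc[mask, "auc"] *= 2
        a = normalize_auc(sirna_auc_table)["auc_norm"]
        b = normalize_auc(doubled)["auc_norm"]
        np.testing.assert_allclose(a, b)

    def test_hand_computed_example(self, sirna_auc_table):
        # NT {2, 4} has mean 3, so GENEX {3, 9} maps to {1, 3}.
        out = normalize_auc(sirna_auc_table)
        genex = out[(out["sirna"] == "GENEX") & (out["bio_rep"] == "R1")]
        assert sorted(genex["auc_norm"]) == pytest.approx([1.0, 3.0])

    def test_absent_reference_stratum_is_an_error(self, sirna_auc_table):
        broken = sirna_auc_table[
            ~((sirna_auc_table["sirna"] == "NT") & (sirna_auc_table["bio_rep"] == "R2"))
        ]
        with pytest.raises(ValueError, match="reference"):
            normalize_auc(broken)


class TestFoldChange:
    @staticmethod
    def _table():
        rows = [
            {"sirna": "NT", "cell_line": "L", "treatment": "control", "auc": 2.0},
            {"sirna": "NT", "cell_line": "L", "treatment": "control", "auc": 4.0},
            {"sirna": "NT", "cell_line": "L", "treatment": "TNFa", "auc": 9.0},
        ]
        return pd.DataFrame(rows)

    def test_hand_computed_fold_change(self):
        out = auc_fold_change(self._table())
        tnf = out[out["treatment"] == "TNFa"]
        assert tnf["fold_change"].item() == pytest.approx(3.0)

    def test_control_group_folds_average_to_one(self):
        out = auc_fold_change(self._table())
        ctrl = out[out["treatment"] == "control"]
        assert ctrl["fold_change"].mean() == pytest.approx(1.0)

    def test_zero_control_mean_rejected(self):
        table = self._table()
        table.loc[table["treatment"] == "control", "auc"] = 0.0
        with pytest.raises(ValueError, match="zero control"):
            auc_fold_change(table)


class TestCompareGroups:
    def test_bh_adjustment_matches_hand_example(self):
        # Raw p (0.01, 0.02, 0.03, 0.04) with m=4 all adjust to 0.04.
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.04)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            frame = pd.DataFrame({
                "value": rng.normal(size=40),
                "group": ["a"] * 20 + ["ref"] * 20,
            })
            out = compare_groups(frame, "value", "group", "ref")
            rejections += int(out["p"].item() < 0.05)
        assert 0.035 <= rejections / reps <= 0.065

    def test_shifted_groups_rejected_far_above_alpha(self):
        # Power oracle: a 1-sd location shift at n=20 vs 20 is detected in
        # the large majority of seeded replicates.
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            frame = pd.DataFrame({
                "value": np.concatenate([rng.normal(1.0, 1, 20),
                                         rng.normal(0.0, 1, 20)]),
                "group": ["a"] * 20 + ["ref"] * 20,
            })
            out = compare_groups(frame, "value", "group", "ref")
            rejections += int(out["p"].item() < 0.05)
        assert rejections / reps > 0.5

    def test_small_groups_skipped_with_warning(self):
        frame = pd.DataFrame({
            "value": [1.0, 2.0, 3.0, 4.0, 9.0],
            "group": ["ref", "ref", "ref", "ref", "tiny"],
        })
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_groups(frame, "value", "group", "ref")
        assert out.loc[out["group"] == "tiny", "skipped"].item()

    def test_bh_adjusted_p_monotone_in_rank_and_bounded(self, rng):
        frame = pd.DataFrame({
            "value": rng.normal(size=120),
            "group": np.repeat([f"g{i}" for i in range(5)] + ["ref"], 20),
        })
        out = compare_groups(frame, "value", "group", "ref").sort_values("p")
        padj = out["p_adj"].to_numpy()
        assert (np.diff(padj) >= -1e-12).all()
        assert ((padj >= 0) & (padj <= 1)).all()
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestUnitInvariance:
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=10, deadline=None)
    def test_pipeline_outputs_invariant_under_intensity_rescaling(self, scale):
        from reladyn.tracks import analyze_tracks

        cfg = SimulationConfig(doses=(0.0, 10.0), n_cells_per_condition=6,
                               dropout_rate=0.0, seed=31)
        frame, _ = simulate_tracks(cfg)
        base = analyze_tracks(frame)
        scaled_frame = frame.copy()
        scaled_frame["nuc_intensity"] *= scale
        scaled = analyze_tracks(scaled_frame)
        np.testing.assert_allclose(
            base["peaks"]["peak_time"], scaled["peaks"]["peak_time"]
        )
        np.testing.assert_allclose(
            base["peaks"]["peak_amplitude"], scaled["peaks"]["peak_amplitude"],
            rtol=1e-9,
        )
        np.testing.assert_allclose(base["auc"]["auc"], scaled["auc"]["auc"],
                                   rtol=1e-9)
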
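"""Trajectory feature extraction: run-length event detection, censoring,
exit alignment, lag recovery against simulator ground truth, ordering."""

import numpy as np
import pytest

from redoxtf import DEFAULT_PARAMS, DosePreset
from redoxtf.dynamics import (PhaseFeatures, detect_p53_onset, detect_phase,
                              exit_align, extract_features, features_to_frame,
                              heatmap_order, lag_summary)
from redoxtf.errors import InputError, InsufficientDataError
from redoxtf.gating import Thresholds
from redoxtf.simulate import (CellTrajectory, TrajectoryTruth, foxo_waveform,
                              p53_waveform, generate_population)
from redoxtf.pipeline import substream

TH = Thresholds(0.5, 2.2)
GRID = np.arange(0.0, 1441.0, 20.0)


def traj(foxo=None, p53=None, died=False, t_death=None, cid="c0"):
    n = len(GRID)
    return CellTrajectory(
        cell_id=cid, t=GRID.copy(),
        foxo1_nf=np.full(n, 0.25) if foxo is None else np.asarray(foxo, float),
        p53=np.full(n, 100.0) if p53 is None else np.asarray(p53, float),
        died=died, t_death=t_death,
        truth=TrajectoryTruth(None, None, None, "none", 0.0))


class TestDetectPhase:
    def test_flat_trajectory_has_no_events(self):
        f = detect_phase(traj(), TH)
        assert (f.t_entry, f.t_exit, f.duration) == (None, None, None)
        assert not (f.entry_censored or f.exit_censored)

    def test_noise_free_cell_detected_exactly(self):
        """With noise off, run-length detection recovers the programmed
        phase window exactly on the frame grid."""
        nf = foxo_waveform(GRID, 40.0, 400.0, DEFAULT_PARAMS)
        f = detect_phase(traj(foxo=nf), TH)
        assert (f.t_entry, f.t_exit, f.duration) == (40.0, 400.0, 360.0)

    def test_single_noisy_frame_is_rejected(self):
        nf = np.full(len(GRID), 0.25)
        nf[10] = 0.9  # one-frame spike, below the m=2 run rule
        f = detect_phase(traj(foxo=nf), TH, m=2)
        assert f.t_entry is None

    def test_open_phase_at_movie_end_is_censored(self):
        nf = foxo_waveform(GRID, 40.0, None, DEFAULT_PARAMS)
        f = detect_phase(traj(foxo=nf), TH)
        assert f.t_entry == 40.0 and f.t_exit is None
        assert f.exit_censored

    def test_death_mid_phase_censors_exit(self):
        nf = foxo_waveform(GRID, 40.0, 800.0, DEFAULT_PARAMS)
        nf[GRID > 500.0] = np.nan  # death at 500, before the exit
        f = detect_phase(traj(foxo=nf, died=True, t_death=500.0), TH)
        assert f.t_entry == 40.0 and f.t_exit is None and f.exit_censored

    def test_nonuniform_grid_rejected(self):
        c = traj()
        c.t = c.t.copy()
        c.t[3] += 1.0
        with pytest.raises(InputError):
            detect_phase(c, TH)

    def test_median_detection_error_within_one_frame(self, pop_by_dose,
                                                     thresholds):
        """Detected entry/exit within one frame of ground truth (median),
        default noise, 100 uM."""
        errs_entry, errs_exit = [], []
        for c in pop_by_dose[100.0]:
            f = detect_phase(c, thresholds)
            tr = c.truth
            if f.t_entry is not None and tr.t_entry is not None:
                errs_entry.append(abs(f.t_entry - tr.t_entry))
            if f.t_exit is not None and tr.t_exit is not None:
                errs_exit.append(abs(f.t_exit - tr.t_exit))
        assert len(errs_entry) >= 150
        assert np.median(errs_entry) <= 20.0
        assert np.median(errs_exit) <= 20.0


class TestDetectOnset:
    def test_constant_p53_has_no_onset(self):
        t, rule = detect_p53_onset(traj())
        assert t is None

    def test_noise_free_step_detected_at_step(self):
        p = np.where(GRID >= 460.0, 400.0, 100.0)
        t, rule = detect_p53_onset(traj(p53=p))
        assert t == 460.0
        assert rule == "relative"  # constant baseline falls back

    def test_noisy_baseline_uses_sd_rule(self, rng):
        p = 100.0 * np.exp(0.05 * rng.standard_normal(len(GRID)))
        p[GRID >= 600.0] = 400.0
        t, rule = detect_p53_onset(traj(p53=p))
        assert rule == "baseline_sd"
        assert t == 600.0

    def test_median_onset_error_within_one_frame(self, pop_by_dose,
                                                 thresholds):
        errs = []
        for c in pop_by_dose[80.0]:
            f = extract_features(c, thresholds)
            if f.t_onset is not None and c.truth.t_onset is not None:
                errs.append(abs(f.t_onset - c.truth.t_onset))
        assert len(errs) >= 100
        assert np.median(errs) <= 20.0

    def test_bad_baseline_frames_rejected(self):
        with pytest.raises(InputError):
            detect_p53_onset(traj(), baseline_frames=1)


class TestExitAlign:
    @staticmethod
    def _pop(n=12, t_exit=400.0):
        cells, feats = [], []
        for i in range(n):
            nf = foxo_waveform(GRID, 40.0, t_exit, DEFAULT_PARAMS)
            p = p53_waveform(GRID, t_exit + 60.0, "oscillatory")
            c = traj(foxo=nf, p53=p, cid=f"c{i:02d}")
            cells.append(c)
            feats.append(extract_features(c, TH))
        return cells, feats

    def test_identical_cells_align_to_single_trace(self):
        cells, feats = self._pop()
        df = exit_align(cells, feats, window=200.0)
        at0 = df[df.rel_t_min == 0.0].iloc[0]
        k = int(np.argmax(GRID == feats[0].t_exit))
        assert at0.foxo1_nf_median == pytest.approx(cells[0].foxo1_nf[k])
        assert at0.n_cells == len(cells)

    def test_shuffling_cells_leaves_median_unchanged(self, rng):
        cells, feats = self._pop()
        df1 = exit_align(cells, feats)
        order = rng.permutation(len(cells))
        df2 = exit_align([cells[i] for i in order], [feats[i] for i in order])
        assert df1.equals(df2)

    def test_too_few_alignable_cells_rejected(self):
        cells, feats = self._pop(n=5)
        with pytest.raises(InsufficientDataError):
            exit_align(cells, feats)

    def test_median_p53_rises_about_one_hour_after_exit(self, pop_by_dose,
                                                        thresholds):
        """Exit-aligned median p53 crosses its onset criterion ~60 min after
        the FOXO1 exit (80+100 uM pool)."""
        cells = pop_by_dose[80.0] + pop_by_dose[100.0]
        feats = [extract_features(c, thresholds) for c in cells]
        df = exit_align(cells, feats, window=480.0)
        pre = df[(df.rel_t_min < 0) & (df.rel_t_min >= -200)]
        baseline = pre.p53_median.mean()
        post = df[df.rel_t_min >= 0]
        crossing = post[post.p53_median > 1.3 * baseline]
        assert not crossing.empty
        t_cross = crossing.rel_t_min.iloc[0]
        assert 20.0 <= t_cross <= 100.0


class TestLagSummary:
    def test_median_of_defined_lags(self):
        feats = [PhaseFeatures(f"c{i}", lag=v)
                 for i, v in enumerate([40.0, 60.0, 80.0])]
        med, iqr, n = lag_summary(feats)
        assert med == 60.0 and n == 3

    def test_censored_lags_excluded(self):
        feats = [PhaseFeatures("a", lag=60.0), PhaseFeatures("b", lag=None)]
        _, _, n = lag_summary(feats)
        assert n == 1

    def test_no_lags_rejected(self):
        with pytest.raises(InsufficientDataError):
            lag_summary([PhaseFeatures("a")])

    def test_programmed_tau_recovered_at_default_noise(self, pop_by_dose,
                                                       thresholds):
        """Median detected lag within one frame of the programmed 60-min
        FOXO1-exit-to-p53 delay (n >= 200)."""
        feats = [extract_features(c, thresholds)
                 for c in pop_by_dose[80.0] + pop_by_dose[100.0]]
        med, _, n = lag_summary(feats)
        assert n >= 200
        assert abs(med - DEFAULT_PARAMS.tau_p53) <= 20.0

    def test_noise_free_lag_is_exact(self):
        cells, feats = TestExitAlign._pop()
        med, _, _ = lag_summary(feats)
        # detection quantizes both events to the frame grid identically
        assert med == pytest.approx(60.0)


class TestHeatmapOrder:
    def test_sorted_by_duration_with_phaseless_first(self):
        feats = [PhaseFeatures("a", t_entry=0.0, t_exit=100.0, duration=100.0),
                 PhaseFeatures("b"),
                 PhaseFeatures("c", t_entry=0.0, t_exit=50.0, duration=50.0)]
        assert heatmap_order(feats) == ["b", "c", "a"]

    def test_ties_break_by_cell_id(self):
        feats = [PhaseFeatures(i, t_entry=0.0, t_exit=100.0, duration=100.0)
                 for i in ("c", "a", "b")]
        assert heatmap_order(feats) == ["a", "b", "c"]

    def test_death_censored_cells_ordered_last_by_death_time(self):
        feats = [PhaseFeatures("a", t_entry=0.0, t_exit=100.0, duration=100.0),
                 PhaseFeatures("dead2", t_entry=0.0, exit_censored=True),
                 PhaseFeatures("dead1", t_entry=0.0, exit_censored=True)]
        order = heatmap_order(feats, {"dead1": 300.0, "dead2": 700.0})
        assert order == ["a", "dead1", "dead2"]

    def test_order_is_permutation(self, pop_by_dose, thresholds):
        pop = pop_by_dose[100.0]
        feats = [extract_features(c, thresholds) for c in pop]
        deaths = {c.cell_id: c.t_death for c in pop if c.t_death is not None}
        order = heatmap_order(feats, deaths)
        assert sorted(order) == sorted(c.cell_id for c in pop)


class TestPopulationLevel:
    def test_recovered_duration_monotone_in_dose(self, pop_by_dose,
                                                 thresholds):
        meds = []
        for dose in (80.0, 100.0, 300.0):
            durs = [f.duration for f in
                    (extract_features(c, thresholds) for c in pop_by_dose[dose])
                    if f.duration is not None]
            meds.append(np.median(durs))
        assert meds[0] < meds[1] < meds[2]

    def test_dying_cells_have_longer_recovered_durations(self, thresholds):
        """One-sided rank comparison of completed durations, dying vs
        surviving, pooled 80+100 uM."""
        from scipy.stats import mannwhitneyu
        dying, surviving = [], []
        for dose in (80.0, 100.0):
            pop = generate_population(400, DosePreset.for_dose(dose),
                                      seed=substream(53, f"d:{dose:g}"))
            for c in pop:
                f = extract_features(c, thresholds)
                if f.duration is not None:
                    (dying if c.died else surviving).append(f.duration)
        assert len(dying) >= 30 and len(surviving) >= 100
        p = mannwhitneyu(dying, surviving, alternative="greater").pvalue
        assert p < 0.05

    def test_features_table_columns(self, pop_by_dose, thresholds):
        feats = [extract_features(c, thresholds) for c in pop_by_dose[80.0]]
        df = features_to_frame(feats)
        assert list(df.columns) == ["cell_id", "t_entry", "t_exit", "duration",
                                    "t_onset", "lag", "entry_censored",
                                    "exit_censored", "onset_censored"]
        ok = df.dropna(subset=["t_entry", "t_exit"])
        assert (ok.t_exit > ok.t_entry).all()
        assert (ok.duration == ok.t_exit - ok.t_entry).all()
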
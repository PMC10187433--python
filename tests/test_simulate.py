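"""Generative simulator: determinism, ground-truth phenomenology (entry
timing, dose ordering, mutual exclusion), death calibration, snapshots."""

import numpy as np
import pytest

from redoxtf import DEFAULT_PARAMS, DosePreset
from redoxtf.errors import CalibrationError, InputError
from redoxtf.params import DEFAULT_DEATH_MULT, death_target_for_dose
from redoxtf.simulate import (DEFAULT_NOISE, NOISE_FREE, calibrate_death,
                              generate_population, generate_snapshot,
                              generate_trajectory, population_to_frame,
                              frame_to_population, snapshot_to_frame,
                              frame_to_snapshot)


def preset(dose):
    return DosePreset.for_dose(float(dose))


class TestTrajectories:
    def test_untreated_cells_stay_at_baseline(self):
        pop = generate_population(50, preset(0), seed=1)
        for c in pop:
            tr = c.truth
            assert tr.t_entry is None and tr.t_exit is None and tr.t_onset is None
            assert not c.died
        nf = np.concatenate([c.foxo1_nf for c in pop])
        # within multiplicative noise of the 0.25 cytoplasmic baseline
        assert 0.2 < np.median(nf) < 0.3
        assert nf.max() < 0.5

    def test_population_is_reproducible(self):
        a = population_to_frame(generate_population(10, preset(100), seed=1))
        b = population_to_frame(generate_population(10, preset(100), seed=1))
        assert a.equals(b)

    def test_cell_ids_unique(self):
        pop = generate_population(25, preset(80), seed=3)
        assert len({c.cell_id for c in pop}) == 25

    def test_invalid_n_rejected(self):
        with pytest.raises(InputError):
            generate_population(0, preset(80))

    def test_high_dose_entry_within_one_hour(self):
        """FOXO1 reaches the nucleus within 1 h of treatment at 100 uM."""
        pop = generate_population(500, preset(100), seed=7)
        entries = [c.truth.t_entry for c in pop if c.truth.t_entry is not None]
        assert len(entries) > 400
        assert np.median(entries) <= 60.0

    def test_low_dose_cells_have_no_foxo_phase(self):
        """At 50 uM FOXO1 stays cytoplasmic in essentially all cells."""
        pop = generate_population(196, preset(50), seed=5)
        n_phase = sum(c.truth.t_entry is not None for c in pop)
        assert n_phase <= 2

    def test_noise_free_onset_is_exit_plus_tau(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            c = generate_trajectory(DEFAULT_PARAMS, preset(80), rng,
                                    noise=NOISE_FREE)
            if c.truth.t_exit is not None:
                assert c.truth.t_onset == pytest.approx(
                    c.truth.t_exit + DEFAULT_PARAMS.tau_p53)

    def test_mutual_exclusion_of_phase_and_p53_by_construction(self):
        for dose in (50.0, 80.0, 100.0, 300.0):
            for c in generate_population(100, preset(dose), seed=13):
                tr = c.truth
                if tr.t_onset is not None and tr.t_entry is not None:
                    assert tr.t_exit is not None
                    assert tr.t_onset > tr.t_exit

    def test_death_censors_the_series(self):
        pop = generate_population(200, preset(300), seed=2)
        died = [c for c in pop if c.died]
        assert died, "98% death preset produced no deaths in 200 cells"
        for c in died:
            after = c.t > c.t_death
            assert np.all(np.isnan(c.foxo1_nf[after]))
            assert np.all(np.isnan(c.p53[after]))
            assert not np.isnan(c.foxo1_nf[~after]).any()

    def test_mean_phase_duration_nondecreasing_in_dose(self):
        meds = []
        for dose in (80.0, 100.0, 300.0):
            pop = generate_population(300, preset(dose), seed=17)
            durs = [c.truth.t_exit - c.truth.t_entry for c in pop
                    if c.truth.t_exit is not None]
            meds.append(np.median(durs))
        assert meds[0] < meds[1] < meds[2]

    def test_phase_fraction_nondecreasing_in_dose(self):
        fracs = []
        for dose in (20.0, 50.0, 80.0, 100.0, 200.0):
            pop = generate_population(300, preset(dose), seed=19)
            fracs.append(np.mean([c.truth.t_entry is not None for c in pop]))
        assert all(b >= a - 0.02 for a, b in zip(fracs, fracs[1:]))

    def test_trajectory_table_round_trip(self):
        pop = generate_population(5, preset(100), seed=23)
        df = population_to_frame(pop)
        back = frame_to_population(df)
        for c0, c1 in zip(pop, back):
            assert c0.cell_id == c1.cell_id
            np.testing.assert_allclose(c0.p53, c1.p53)
            assert c0.truth == c1.truth


class TestPerturbationPhenotypes:
    def test_srxn1oe_reduces_phase_cells_at_intermediate_doses(self):
        """Faster repair suppresses FOXO1 activation in the 80-150 uM band
        (the shift saturates at the top of the band where hyperoxidation
        overwhelms even the overexpressed repair)."""
        oe = DEFAULT_PARAMS.perturbed("srxn1oe")
        n_base_band, n_oe_band = 0, 0
        for dose in (80.0, 100.0, 150.0):
            base_pop = generate_population(150, preset(dose), seed=29)
            oe_pop = generate_population(150, preset(dose), oe, seed=29)
            n_base = sum(c.truth.t_entry is not None for c in base_pop)
            n_oe = sum(c.truth.t_entry is not None for c in oe_pop)
            n_base_band += n_base
            n_oe_band += n_oe
            if dose <= 100.0:
                assert n_oe < n_base, dose
        assert n_oe_band < n_base_band

    def test_prdx1ko_activates_at_low_dose(self):
        ko = DEFAULT_PARAMS.perturbed("prdx1ko")
        pop = generate_population(150, preset(40), ko, seed=31)
        assert np.mean([c.truth.t_entry is not None for c in pop]) > 0.5

    def test_srx_null_prolongs_phases_and_delays_onsets(self):
        null = DEFAULT_PARAMS.replace(k_srx=0.0)
        base = generate_population(150, preset(100), seed=37)
        srx0 = generate_population(150, preset(100), null, seed=37)
        base_durs = [c.truth.t_exit - c.truth.t_entry for c in base
                     if c.truth.t_exit is not None]
        # without repair no phase completes inside the movie
        assert all(c.truth.t_exit is None for c in srx0
                   if c.truth.t_entry is not None)
        assert all(c.truth.t_onset is None for c in srx0
                   if c.truth.t_entry is not None)
        assert base_durs  # default phases do complete


class TestSnapshots:
    def test_untreated_snapshot_has_no_active_truth(self):
        cells = generate_snapshot(300, preset(0), seed=3)
        assert not any(c.truth_foxo_active or c.truth_p53_active for c in cells)
        assert all(c.p53_nuc > 0 and 0 <= c.foxo1_nf <= 1 and c.gh2ax > 0
                   for c in cells)

    def test_gh2ax_mean_increases_with_dose(self):
        means = []
        for dose in (0.0, 50.0, 100.0, 200.0):
            cells = generate_snapshot(2000, preset(dose), seed=41)
            means.append(np.mean([c.gh2ax for c in cells]))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_p53_mean_is_nonmonotone_in_dose(self):
        """p53 rises at intermediate doses but matches control at 200 uM."""
        means = {}
        for dose in (0.0, 50.0, 100.0, 200.0):
            cells = generate_snapshot(2000, preset(dose), seed=43)
            means[dose] = np.mean([c.p53_nuc for c in cells])
        assert abs(means[200.0] - means[0.0]) < 0.05 * means[0.0]
        assert means[200.0] < means[50.0]
        assert means[200.0] < means[100.0]

    def test_truth_p53_fraction_peaks_at_intermediate_dose(self):
        fracs = {}
        for dose in (20.0, 50.0, 60.0, 80.0, 100.0, 200.0, 300.0):
            cells = generate_snapshot(800, preset(dose), seed=47)
            fracs[dose] = np.mean([c.truth_p53_active for c in cells])
        best = max(fracs, key=fracs.get)
        assert 50.0 <= best <= 100.0

    def test_t_fix_off_grid_rejected(self):
        with pytest.raises(InputError):
            generate_snapshot(10, preset(50), t_fix=301.0)

    def test_snapshot_table_round_trip(self):
        cells = generate_snapshot(20, preset(80), seed=53)
        assert frame_to_snapshot(snapshot_to_frame(cells)) == cells


class TestDeathCalibration:
    def test_zero_target_gives_zero_multiplier(self):
        assert calibrate_death(DEFAULT_PARAMS, preset(100), 0.0) == 0.0

    def test_calibrated_fraction_reproduces_at_34_percent(self):
        """Bisection target re-simulated within tolerance (100 uM, 34%)."""
        m = calibrate_death(DEFAULT_PARAMS, preset(100), 0.34,
                            n_mc=20000, tol=0.005, seed=61)
        pop = generate_population(5000, DosePreset("100", 100.0, m), seed=67)
        frac = np.mean([c.died for c in pop])
        assert frac == pytest.approx(0.34, abs=0.025)

    def test_calibrated_fraction_reproduces_at_98_percent(self):
        m = calibrate_death(DEFAULT_PARAMS, preset(300), 0.98,
                            n_mc=20000, tol=0.005, seed=61)
        pop = generate_population(3000, DosePreset("300", 300.0, m), seed=67)
        assert np.mean([c.died for c in pop]) == pytest.approx(0.98, abs=0.012)

    def test_multiplier_monotone_in_target(self):
        ms = [calibrate_death(DEFAULT_PARAMS, preset(100), t,
                              n_mc=5000, tol=0.01, seed=71)
              for t in (0.1, 0.3, 0.6)]
        assert ms[0] < ms[1] < ms[2]

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_death(DEFAULT_PARAMS, preset(20), 0.999,
                            n_mc=2000, tol=0.002, seed=73, mult_max=1.0)

    def test_invalid_target_rejected(self):
        with pytest.raises(InputError):
            calibrate_death(DEFAULT_PARAMS, preset(100), 1.5)

    def test_frozen_defaults_match_interpolated_targets(self):
        """The versioned multipliers reproduce their targets when re-simulated."""
        for dose in (50.0, 80.0):
            pop = generate_population(4000, DosePreset.for_dose(dose), seed=79)
            frac = np.mean([c.died for c in pop])
            target = death_target_for_dose(dose)
            assert frac == pytest.approx(target, abs=0.02), dose

    def test_default_mult_table_covers_all_preset_doses(self):
        from redoxtf.params import DOSES_UM
        assert set(DEFAULT_DEATH_MULT) == set(DOSES_UM)
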
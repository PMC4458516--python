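"""Age assignment, profile maps, and mid-cell statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf
from scipy.stats import kstest, pearsonr

import rodmap
from rodmap.cyclemap import AgeClassSummary
from rodmap.errors import ConsistencyError
from rodmap.profile import AxialProfile
from rodmap.synthgen import steady_state_age_cdf
from conftest import make_truth


def gaussian_profile(length_um, sigma_um, n_bins, mass=1.0, uniform=0.0):
    """Exact bin integrals of uniform + mid-cell Gaussian (the analytic oracle)."""
    from scipy.stats import norm

    edges = np.linspace(0.0, length_um, n_bins + 1)
    vals = uniform * np.diff(edges)
    vals += mass * np.diff(norm.cdf(edges, loc=length_um / 2, scale=sigma_um))
    return vals


class TestAssignAges:
    def test_closed_form_inverse_at_median_rank(self):
        # F = 0.5 -> a = -log2(0.75)
        table = rodmap.assign_ages(np.arange(1.0, 12.0))  # n=11, middle F=0.5
        mid = table[table["rank"] == 6].iloc[0]
        assert mid["rank_fraction"] == pytest.approx(0.5)
        assert mid["age"] == pytest.approx(-math.log2(0.75), abs=1e-12)

    def test_endpoints_approach_zero_and_one(self):
        table = rodmap.assign_ages(np.linspace(2.0, 4.0, 5000))
        assert table["age"].min() == pytest.approx(0.0, abs=1e-3)
        assert table["age"].max() == pytest.approx(1.0, abs=1e-3)
        assert table["age"].is_monotonic_increasing

    def test_empty_and_invalid_inputs(self):
        assert len(rodmap.assign_ages([])) == 0
        with pytest.raises(ValueError):
            rodmap.assign_ages([2.0, -1.0])

    def test_ties_broken_stably_by_cell_id(self):
        table = rodmap.assign_ages([3.0, 3.0], cell_ids=[7, 3])
        by_rank = table.sort_values("rank")
        assert by_rank["cell_id"].tolist() == [3, 7]

    def test_assigned_age_histogram_matches_steady_state(self):
        rng = np.random.default_rng(11)
        ages = -np.log2(1.0 - rng.random(5000) / 2.0)
        lengths = 2.0 * np.exp2(ages)
        table = rodmap.assign_ages(lengths)
        stat = kstest(table["age"], steady_state_age_cdf).statistic
        assert stat < 0.02

    def test_inverse_of_generator_cdf_with_length_noise(self):
        # Pearson(true, assigned) >= 0.95 at n >= 1000 under 5% length noise
        _, truth = rodmap.sample_population(
            2000, rodmap.GrowthModel(length_noise_cv=0.05), seed=17
        )
        table = rodmap.assign_ages(
            truth.cells["true_length_um"], truth.cells["cell_id"]
        )
        r, _ = pearsonr(truth.cells["true_age"], table["age"])
        assert r >= 0.95


class TestProfileMap:
    def test_rows_sorted_by_length(self):
        profiles = [
            AxialProfile(i, "c", np.full(10, float(i)), L)
            for i, L in [(1, 3.0), (2, 2.0), (3, 4.0)]
        ]
        table = rodmap.assign_ages([3.0, 2.0, 4.0], cell_ids=[1, 2, 3])
        pmap = rodmap.build_profile_map(profiles, table, n_cols=10)
        assert pmap.cell_ids.tolist() == [2, 1, 3]
        assert pmap.lengths_um.tolist() == [2.0, 3.0, 4.0]

    def test_equal_lengths_tie_broken_by_id(self):
        profiles = [AxialProfile(i, "c", np.ones(4), 3.0) for i in (7, 3)]
        table = rodmap.assign_ages([3.0, 3.0], cell_ids=[7, 3])
        pmap = rodmap.build_profile_map(profiles, table, n_cols=4)
        assert pmap.cell_ids.tolist() == [3, 7]

    def test_unknown_cell_id_rejected(self):
        profiles = [AxialProfile(99, "c", np.ones(4), 3.0)]
        table = rodmap.assign_ages([3.0], cell_ids=[1])
        with pytest.raises(ConsistencyError):
            rodmap.build_profile_map(profiles, table)

    def test_septal_population_shows_midcell_band_in_old_rows(self):
        _, truth = rodmap.sample_population(1200, seed=23)
        channel = rodmap.ChannelModel(
            name="s", kind="septal", septal_onset_age=0.4, noise_sd=0.5
        )
        profiles = rodmap.analytic_profiles(truth, channel, seed=24)
        table = rodmap.assign_ages(
            truth.cells["true_length_um"], truth.cells["cell_id"]
        )
        pmap = rodmap.build_profile_map(profiles, table, n_cols=50)
        old_rows = pmap.matrix[-100:]
        peak_cols = np.argmax(old_rows, axis=1)
        assert np.median(np.abs(peak_cols - 24.5)) < 3


class TestAgeClassAverages:
    def test_uniform_profiles_give_flat_unit_classes(self):
        profiles = [AxialProfile(i, "c", np.full(20, 2.0), 3.0) for i in range(1, 41)]
        table = rodmap.assign_ages(np.linspace(2, 4, 40))
        summary = rodmap.age_class_averages(profiles, table, n_cols=20)
        assert summary.n_classes == 10
        for k in range(10):
            if summary.counts[k]:
                assert np.allclose(summary.peak_profiles[k], 1.0)

    def test_empty_classes_retained_and_flagged(self):
        profiles = [AxialProfile(1, "c", np.ones(10), 3.0)]
        table = rodmap.assign_ages([3.0])
        summary = rodmap.age_class_averages(profiles, table)
        assert summary.counts.sum() == 1
        assert len(summary.counts) == 10
        empty = summary.counts == 0
        assert np.all(np.isnan(summary.mean_profiles[empty]))

    def test_midclass_occupancy_matches_steady_state(self):
        # ~300-500 cells per mid class at n=4000 under p(a) = 2 ln2 2^-a
        _, truth = rodmap.sample_population(4000, seed=29)
        table = rodmap.assign_ages(
            truth.cells["true_length_um"], truth.cells["cell_id"]
        )
        channel = rodmap.ChannelModel(name="c", kind="cytoplasmic", noise_sd=0.0)
        profiles = rodmap.analytic_profiles(truth, channel)
        summary = rodmap.age_class_averages(profiles, table)
        assert np.all((summary.counts[3:7] >= 300) & (summary.counts[3:7] <= 500))


class TestRingFraction:
    def test_all_mass_inside_window(self):
        vals = gaussian_profile(2.0, 0.05, 50)  # tight band, L=2, window 0.8
        assert rodmap.ring_fraction(vals, 2.0) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_profile_proportionality(self):
        vals = np.full(50, 3.0)
        assert rodmap.ring_fraction(vals, 4.0) == pytest.approx(0.2, abs=1e-12)

    def test_midcell_gaussian_matches_erf_oracle(self):
        # closed form: erf(0.4 / (0.2 sqrt(2)))
        expected = erf(0.4 / (0.2 * math.sqrt(2.0)))
        coarse = rodmap.ring_fraction(gaussian_profile(3.0, 0.2, 50), 3.0)
        assert coarse == pytest.approx(expected, abs=1e-2)
        fine = rodmap.ring_fraction(gaussian_profile(3.0, 0.2, 3000), 3.0)
        assert fine == pytest.approx(expected, abs=1e-6)

    def test_zero_total_flagged_undefined(self):
        assert math.isnan(rodmap.ring_fraction(np.zeros(50), 3.0))

    def test_cell_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            rodmap.ring_fraction(np.ones(50), 0.5)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_uniform_scaling(self, scale):
        vals = gaussian_profile(3.0, 0.3, 50, mass=2.0, uniform=1.0)
        base = rodmap.ring_fraction(vals, 3.0)
        assert rodmap.ring_fraction(vals * scale, 3.0) == pytest.approx(base)


class TestFCplus:
    def test_uniform_profile_gives_zero(self):
        assert rodmap.fc_plus(np.full(50, 5.0), 4.0) == pytest.approx(0.0, abs=1e-9)

    def test_recovers_injected_band_mass(self):
        vals = gaussian_profile(4.0, 0.15, 200, mass=37.0, uniform=10.0)
        assert rodmap.fc_plus(vals, 4.0) == pytest.approx(37.0, rel=0.02)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(deadline=None, max_examples=25)
    def test_scales_linearly_with_amplitude(self, scale):
        vals = gaussian_profile(4.0, 0.15, 100, mass=10.0, uniform=2.0)
        base = rodmap.fc_plus(vals, 4.0)
        assert rodmap.fc_plus(vals * scale, 4.0) == pytest.approx(
            scale * base, rel=1e-9
        )

    def test_short_cell_flagged_undefined(self):
        assert math.isnan(rodmap.fc_plus(np.ones(50), 2.0))  # < 0.8 + 2*0.8

    def test_septal_cells_separate_from_preonset(self):
        _, truth = rodmap.sample_population(800, seed=31)
        channel = rodmap.ChannelModel(
            name="s", kind="septal", septal_onset_age=0.4, noise_sd=0.5
        )
        profiles = rodmap.analytic_profiles(truth, channel, seed=32)
        fc = np.array([rodmap.fc_plus(p) for p in profiles])
        onset = truth.cells["true_age"] >= 0.5
        pre = truth.cells["true_age"] < 0.35
        ok = np.isfinite(fc)
        assert fc[ok & onset].mean() > 5.0 * max(fc[ok & pre].mean(), 1e-9)


class TestInitiationAndMoment:
    @staticmethod
    def population_summary(onset, seed, n=3000, noise=2.0):
        _, truth = rodmap.sample_population(n, seed=seed)
        channel = rodmap.ChannelModel(
            name="s", kind="septal", septal_onset_age=onset, noise_sd=noise
        )
        profiles = rodmap.analytic_profiles(truth, channel, seed=seed + 1)
        table = rodmap.assign_ages(
            truth.cells["true_length_um"], truth.cells["cell_id"]
        )
        summary = rodmap.age_class_averages(profiles, table)
        fc = np.array([rodmap.fc_plus(p) for p in profiles])
        return summary, fc, table["age"].to_numpy()

    def test_no_signal_gives_undefined_initiation(self):
        summary, _, _ = self.population_summary(onset=1.0, seed=41)  # never fires
        assert rodmap.detect_initiation(summary) is None

    @pytest.mark.parametrize("onset", [0.25, 0.4])
    def test_initiation_recovered_within_one_class(self, onset):
        summary, _, _ = self.population_summary(onset=onset, seed=43)
        found = rodmap.detect_initiation(summary)
        assert found is not None
        expected_class = int(onset * 10)
        assert abs(round(found * 10) - expected_class) <= 1

    def test_all_zero_fcplus_gives_undefined_moment(self):
        assert rodmap.detect_moment(np.zeros(100), np.linspace(0, 1, 100)) is None

    def test_monotone_fcplus_peaks_in_last_class(self):
        ages = np.linspace(0.01, 0.99, 200)
        assert rodmap.detect_moment(ages**2, ages) == pytest.approx(0.95)

    def test_moment_recovers_amplitude_peak_age(self):
        summary, fc, ages = self.population_summary(onset=0.4, seed=47)
        moment = rodmap.detect_moment(fc, ages)
        assert moment == pytest.approx(0.65, abs=0.1)

    def test_too_few_nonempty_classes_rejected(self):
        profiles = [AxialProfile(i, "c", np.ones(10), 3.0) for i in (1, 2)]
        table = rodmap.assign_ages([3.0, 3.1], cell_ids=[1, 2])
        summary = rodmap.age_class_averages(profiles, table)
        with pytest.raises(ValueError):
            rodmap.detect_initiation(summary)
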
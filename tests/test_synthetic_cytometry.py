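import dataclasses

import numpy as np
import pytest

from cytoval import (DEFAULT_MAST_SPEC, ExperimentDesign, MatrixProfile,
                     PopulationSpec, generate_dilution_series,
                     quantify_mast_cells, simulate_matrix, spike_mast_cells)
from cytoval.errors import ConfigurationError, ValidationError
from cytoval.synthetic_cytometry import events_needed, viable_mask


def single_pop_profile():
    pop = PopulationSpec("lymphocyte", 1.0, (2.6, 2.0, 0.5, 0.5, 0.4),
                         (0.1, 0.1, 0.3, 0.3, 0.25))
    return MatrixProfile("PB", (pop,), dead_fraction=0.0, background_dp_rate=0.0)


class TestPopulationSpec:
    def test_spread_must_be_positive(self):
        with pytest.raises(ConfigurationError, match="spread"):
            PopulationSpec("x", 0.5, (1,) * 5, (0.1, 0.1, 0.0, 0.1, 0.1))

    def test_fraction_bounds(self):
        with pytest.raises(ConfigurationError, match="fraction"):
            PopulationSpec("x", 1.5, (1,) * 5, (0.1,) * 5)

    def test_correlation_shapes_values(self):
        corr = np.eye(5)
        corr[0, 1] = corr[1, 0] = 0.9
        spec = PopulationSpec("x", 1.0, (2.0,) * 5, (0.2,) * 5, correlation=corr)
        draws = np.log10(spec.sample(20_000, np.random.default_rng(0)))
        r = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert r > 0.85
        r23 = np.corrcoef(draws[:, 2], draws[:, 3])[0, 1]
        assert abs(r23) < 0.05

    def test_bad_correlation_rejected(self):
        with pytest.raises(ConfigurationError, match="correlation"):
            PopulationSpec("x", 1.0, (1,) * 5, (0.1,) * 5, correlation=np.ones((4, 4)))


class TestSimulateMatrix:
    def test_degenerate_mixture_single_label(self):
        t = simulate_matrix(single_pop_profile(), 1000, seed=0)
        assert len(t) == 1000
        assert set(t.label) == {"lymphocyte"}

    def test_fractions_must_sum_to_one(self):
        pop = PopulationSpec("lymphocyte", 0.7, (2.6, 2.0, 0.5, 0.5, 0.4), (0.1,) * 5)
        with pytest.raises(ConfigurationError, match="sum"):
            MatrixProfile("PB", (pop,), dead_fraction=0.0, background_dp_rate=0.0)

    def test_population_counts_binomial_bound(self, pb_profile):
        n = 120_000
        t = simulate_matrix(pb_profile, n, seed=11)
        p = next(s.fraction for s in pb_profile.populations
                 if s.name == "lymphocyte") * (1 - pb_profile.dead_fraction)
        count = int(np.sum(t.label == "lymphocyte"))
        assert abs(count - n * p) <= 4 * np.sqrt(n * p * (1 - p))

    def test_label_conservation(self, ln_profile):
        n = 30_000
        t = simulate_matrix(ln_profile, n, seed=2)
        _, counts = np.unique(t.label.astype(str), return_counts=True)
        assert counts.sum() == n

    def test_dead_fraction_zero_all_viable(self, ln_profile, gates):
        prof = dataclasses.replace(ln_profile, dead_fraction=0.0)
        t = simulate_matrix(prof, 50_000, seed=3)
        assert not np.any(t.fl3_7aad >= gates.viability_max_fl3)

    def test_dead_events_exceed_viability_threshold(self, ln_profile, gates):
        t = simulate_matrix(ln_profile, 50_000, seed=4)
        dead_fl3 = t.fl3_7aad[t.label == "dead"]
        assert np.mean(dead_fl3 >= gates.viability_max_fl3) > 0.999

    def test_debris_has_low_scatter(self, ln_profile):
        t = simulate_matrix(ln_profile, 20_000, seed=5)
        debris = t.label == "debris"
        assert np.median(t.fsc[debris]) < np.median(t.fsc[~debris]) / 5

    def test_no_mast_cell_labels(self, ln_blank):
        assert "mast_cell" not in set(ln_blank.label)

    def test_seed_determinism_and_independence(self, ln_profile):
        a = simulate_matrix(ln_profile, 5_000, seed=9)
        b = simulate_matrix(ln_profile, 5_000, seed=9)
        c = simulate_matrix(ln_profile, 5_000, seed=10)
        np.testing.assert_array_equal(a.channels, b.channels)
        assert not np.array_equal(a.channels, c.channels)

    def test_n_events_validated(self, ln_profile):
        with pytest.raises(ValidationError):
            simulate_matrix(ln_profile, 0, seed=1)


class TestSpike:
    def test_blank_spike_is_pure_shuffle(self, ln_blank):
        out, truth = spike_mast_cells(ln_blank, DEFAULT_MAST_SPEC, 0.0, seed=1)
        assert truth.realized_count == 0
        assert len(out) == len(ln_blank)
        np.testing.assert_array_equal(np.sort(out.fsc), np.sort(ln_blank.fsc))

    def test_fifty_percent_binomial_bound(self, ln_blank):
        out, truth = spike_mast_cells(ln_blank, DEFAULT_MAST_SPEC, 50.0, seed=2)
        v = int(viable_mask(ln_blank).sum())
        trials = round(v / 0.5)  # expected mast share of final viable events = 50%
        assert abs(truth.realized_count - trials * 0.5) <= 4 * np.sqrt(trials * 0.25)
        assert len(out) == len(ln_blank) + truth.realized_count

    def test_end_to_end_recovery_one_percent(self, ln_blank, gates):
        out, _ = spike_mast_cells(ln_blank, DEFAULT_MAST_SPEC, 1.0, seed=3)
        res = quantify_mast_cells(out, gates)
        sd = 100 * np.sqrt(0.01 * 0.99 / res.n_viable)
        assert abs(res.mast_pct - 1.0) <= 4 * sd

    def test_nominal_fraction_validated(self, ln_blank):
        with pytest.raises(ValidationError):
            spike_mast_cells(ln_blank, DEFAULT_MAST_SPEC, 100.0, seed=1)
        with pytest.raises(ValidationError):
            spike_mast_cells(ln_blank, DEFAULT_MAST_SPEC, -1.0, seed=1)

    def test_unlabeled_events_rejected(self, ln_blank):
        bare = ln_blank.subset(np.arange(100))
        bare = dataclasses.replace(bare, label=None)
        with pytest.raises(ValidationError, match="labels"):
            spike_mast_cells(bare, DEFAULT_MAST_SPEC, 1.0, seed=1)

    def test_noise_cv_widens_repeat_scatter(self, ln_profile):
        base = simulate_matrix(ln_profile, 20_000, seed=6)
        quiet = [spike_mast_cells(base, DEFAULT_MAST_SPEC, 10.0, seed=s)[1].realized_count
                 for s in range(30)]
        noisy = [spike_mast_cells(base, DEFAULT_MAST_SPEC, 10.0, seed=s,
                                  noise_cv=20.0)[1].realized_count
                 for s in range(30)]
        assert np.std(noisy) > 3 * np.std(quiet)


class TestDilutionSeries:
    def small_design(self, **kw):
        defaults = dict(matrix="LN", nominal_fractions=(5, 1, 0.5),
                        repeats_per_level=3, n_blanks=4, min_events=4_000,
                        rng_seed=7)
        defaults.update(kw)
        return ExperimentDesign(**defaults)

    def test_table_count_arithmetic(self, ln_profile):
        series = generate_dilution_series(self.small_design(), ln_profile)
        assert len(series) == 3 * 3 + 4

    def test_default_pb_count_is_37(self):
        d = ExperimentDesign(matrix="PB")
        assert len(d.nominal_fractions) * d.repeats_per_level + d.n_blanks == 37

    def test_determinism(self, ln_profile):
        s1 = generate_dilution_series(self.small_design(), ln_profile)
        s2 = generate_dilution_series(self.small_design(), ln_profile)
        for (t1, tr1), (t2, tr2) in zip(s1, s2):
            np.testing.assert_array_equal(t1.channels, t2.channels)
            assert tr1 == tr2

    def test_seed_changes_series(self, ln_profile):
        s1 = generate_dilution_series(self.small_design(), ln_profile)
        s2 = generate_dilution_series(self.small_design(rng_seed=8), ln_profile)
        assert not np.array_equal(s1[0][0].channels, s2[0][0].channels)

    def test_min_events_met_in_morphology_gate(self, ln_profile, gates):
        from cytoval import apply_morphology_gate
        design = self.small_design()
        series = generate_dilution_series(design, ln_profile)
        for table, _ in series:
            assert len(apply_morphology_gate(table, gates)) >= design.min_events

    def test_expected_mast_count_at_low_level(self, pb_profile):
        design = ExperimentDesign(matrix="PB", nominal_fractions=(0.1,),
                                  repeats_per_level=1, n_blanks=0,
                                  min_events=500_000, rng_seed=1)
        (table, truth), = generate_dilution_series(design, pb_profile)
        v = int(viable_mask(table).sum()) - truth.realized_count
        expected = v * 0.001 / 0.999
        assert abs(truth.realized_count - expected) <= 4 * np.sqrt(expected)
        assert 300 <= truth.realized_count <= 700  # ~500 at this depth

    def test_monotone_recovery(self, ln_profile, gates):
        design = self.small_design(n_blanks=0)
        series = generate_dilution_series(design, ln_profile)
        means = {}
        for table, truth in series:
            res = quantify_mast_cells(table, gates)
            means.setdefault(truth.nominal_fraction, []).append(res.mast_pct)
        levels = sorted(means)
        series_means = [np.mean(means[f]) for f in levels]
        assert all(a < b for a, b in zip(series_means, series_means[1:]))

    def test_blank_fidelity(self, ln_profile, gates):
        design = ExperimentDesign(matrix="LN", nominal_fractions=(1,),
                                  repeats_per_level=1, n_blanks=3,
                                  min_events=100_000, rng_seed=5)
        series = generate_dilution_series(design, ln_profile)
        for table, truth in series[1:]:
            res = quantify_mast_cells(table, gates)
            dp_rate = res.quadrant_counts[3] / res.n_viable
            assert dp_rate <= 2 * ln_profile.background_dp_rate

    def test_matrix_mismatch_rejected(self, pb_profile):
        with pytest.raises(ConfigurationError, match="matrix"):
            generate_dilution_series(self.small_design(), pb_profile)

    def test_events_needed_covers_minimum(self, ln_profile):
        d = self.small_design()
        assert events_needed(d, ln_profile) > d.min_events
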
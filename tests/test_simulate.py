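"""Branching-process generator: limits, determinism, ground-truth consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cedad
from cedad.simulate import _harvest_states, _live_counts, _run_branching


def renewal_expected_live(mean, shape, hazard, t_end, dt=0.002):
    """Independent oracle: exact expected live count per founder.

    Solves the age-structured renewal equation
    ``F(t) = S_T(t) e^{-ht} + 2 \\int_0^t f_T(u) e^{-hu} F(t-u) du``
    numerically (trapezoid), where T ~ Gamma(shape, mean/shape) is the
    inter-division time and h the apoptosis-onset hazard.  This is the
    finite-time Euler-Lotka expectation for a population started from
    newborn cells.
    """
    grid = np.arange(0.0, t_end + dt / 2, dt)
    f = stats.gamma.pdf(grid, a=shape, scale=mean / shape)
    S = stats.gamma.sf(grid, a=shape, scale=mean / shape)
    decay = np.exp(-hazard * grid)
    F = np.empty_like(grid)
    F[0] = 1.0
    for i in range(1, grid.size):
        integrand = f[: i + 1] * decay[: i + 1] * F[i::-1]
        F[i] = S[i] * decay[i] + 2.0 * np.trapezoid(integrand, dx=dt)
    return F[-1]


class TestSimulatePopulation:
    def test_deterministic_doubling_limit(self):
        """Deterministic 1-day divisions over 2 days: every cell in generation 2."""
        cfg = cedad.SimulationConfig(
            n_initial=200,
            division_time_mean_days=1.0,
            division_time_shape=np.inf,
            quiescent_fraction=0.0,
            death_hazard_per_day=0.0,
            artifact_fraction=0.0,
            n_events_recorded=600,
            seed=0,
        )
        events, truth = cedad.simulate_population(cfg)
        assert truth.fold_change_realized == 4.0
        assert (events.data["generation"] == 2).all()
        np.testing.assert_allclose(truth.true_generation_proportions, [0, 0, 1, 0, 0])

    def test_division_disabled(self):
        cfg = cedad.SimulationConfig(
            n_initial=300,
            division_time_mean_days=np.inf,
            death_hazard_per_day=0.0,
            artifact_fraction=0.0,
            n_events_recorded=300,
            seed=0,
        )
        events, truth = cedad.simulate_population(cfg)
        assert truth.fold_change_realized == 1.0
        assert (events.data["generation"] == 0).all()

    def test_identical_seed_identical_output(self):
        cfg = cedad.SimulationConfig(n_initial=1000, n_events_recorded=1000, seed=42)
        ev1, tr1 = cedad.simulate_population(cfg)
        ev2, tr2 = cedad.simulate_population(cfg)
        pd.testing.assert_frame_equal(ev1.data, ev2.data, check_exact=True)
        np.testing.assert_array_equal(
            tr1.true_generation_proportions, tr2.true_generation_proportions
        )
        assert tr1.fold_change_realized == tr2.fold_change_realized

    def test_fold_change_matches_renewal_oracle(self):
        """Realized growth agrees with the exact branching-process expectation."""
        base = dict(
            n_initial=5000,
            division_time_mean_days=1.05,
            division_time_shape=8.0,
            quiescent_fraction=0.0,
            death_hazard_per_day=0.15,
            n_events_recorded=1000,
        )
        folds = []
        for seed in range(1, 51):
            _, truth = cedad.simulate_population(cedad.SimulationConfig(seed=seed, **base))
            folds.append(truth.fold_change_realized)
        sd = np.std(folds, ddof=1)
        expected = renewal_expected_live(1.05, 8.0, 0.15, 2.0)
        assert abs(folds[0] - expected) <= 3 * sd
        # and the replicate mean should be tighter still
        assert abs(np.mean(folds) - expected) <= 3 * sd / np.sqrt(50) * 3

    def test_extinct_population_raises(self):
        cfg = cedad.SimulationConfig(
            n_initial=50,
            division_time_mean_days=np.inf,
            death_hazard_per_day=60.0,
            n_events_recorded=100,
            seed=0,
        )
        with pytest.raises(cedad.ExtinctPopulationError, match="extinct"):
            cedad.simulate_population(cfg)

    def test_truth_invariants(self, standard_sample):
        _, truth = standard_sample
        p = truth.true_generation_proportions
        assert abs(p.sum() - 1.0) < 1e-9
        counts = truth.population_counts
        assert truth.fold_change_realized == pytest.approx(
            counts["live_count"].iloc[-1] / truth.n_initial
        )

    def test_state_partition_conservation(self):
        """Every cell ever alive is in exactly one state at harvest."""
        cfg = cedad.SimulationConfig(
            n_initial=2000, death_hazard_per_day=0.3, n_events_recorded=1000, seed=5
        )
        rng = np.random.default_rng(cfg.seed)
        cells = _run_branching(cfg, rng)
        state, divided = _harvest_states(cells, cfg)
        n = cells["birth"].size
        assert int(divided.sum()) + int((state >= 0).sum()) == n
        # live count from interval arithmetic matches the state machine
        assert _live_counts(cells, np.array([cfg.duration_days]))[0] == (state == 0).sum()
        # and at intermediate times the interval count matches a direct scan
        for t in (0.5, 1.0, 1.7):
            direct = int(((cells["birth"] <= t) & (cells["live_end"] > t)).sum())
            assert _live_counts(cells, np.array([t]))[0] == direct

    def test_label_intensity_concordance(self, standard_sample):
        """True-threshold classification recovers the generator's labels."""
        events, truth = standard_sample
        labels = cedad.quadrant_labels(events, truth.ag_threshold, truth.pi_threshold)
        agree = (labels == events.data["state"].to_numpy()).mean()
        assert agree >= 0.99

    def test_generation_intensity_concordance(self):
        """Rounding the log2 dye deficit recovers the true generation."""
        cfg = cedad.SimulationConfig(
            n_initial=25_000, n_events_recorded=50_000, dye_cv_log2=0.25, seed=11
        )
        events, _ = cedad.simulate_population(cfg)
        live = events.data[events.data["state"] == "viable"]
        est = np.rint(cfg.dye_initial_log2 - np.log2(live["CTV_A"])).astype(int)
        agree = (est == live["generation"].to_numpy()).mean()
        assert agree >= 0.95


class TestCountSeries:
    def test_static_population_counts_near_initial(self):
        cfg = cedad.SimulationConfig(
            n_initial=4000,
            division_time_mean_days=np.inf,
            death_hazard_per_day=0.0,
            count_cv=0.05,
            seed=3,
        )
        series = cedad.simulate_count_series(cfg, [0.0, 1.0, 2.0], replicates=4)
        assert len(series) == 12
        rel = series["count"] / cfg.n_initial
        assert np.all(np.abs(np.log(rel)) < 5 * cfg.count_cv)

    def test_single_time_three_replicates(self):
        cfg = cedad.SimulationConfig(n_initial=1000, seed=0)
        series = cedad.simulate_count_series(cfg, [0.0], replicates=3)
        assert len(series) == 3
        assert (series["day"] == 0.0).all()

    def test_replicates_reproducible_in_isolation(self):
        cfg = cedad.SimulationConfig(n_initial=800, seed=9)
        s3 = cedad.simulate_count_series(cfg, [0.0, 2.0], replicates=3)
        s5 = cedad.simulate_count_series(cfg, [0.0, 2.0], replicates=5)
        pd.testing.assert_frame_equal(
            s3, s5[s5["replicate"] < 3].reset_index(drop=True), check_exact=True
        )

    def test_regime_change_slows_late_growth(self):
        """A death-hazard step at day 2 lowers the fitted exponent after day 2."""
        cfg = cedad.SimulationConfig(
            n_initial=3000,
            duration_days=4.0,
            death_hazard_per_day=0.05,
            hazard_step_day=2.0,
            hazard_after_step=0.8,
            seed=21,
        )
        series = cedad.simulate_count_series(cfg, [0, 1, 2, 3, 4], replicates=3)
        early = cedad.fit_exponential(series, (0, 2))
        late = cedad.fit_exponential(series, (2, 4))
        assert late.g < early.g

    def test_bad_arguments(self):
        cfg = cedad.SimulationConfig(n_initial=100, seed=0)
        with pytest.raises(ValueError):
            cedad.simulate_count_series(cfg, [], replicates=3)
        with pytest.raises(ValueError):
            cedad.simulate_count_series(cfg, [0.0, 1.0], replicates=0)
        with pytest.raises(ValueError):
            cedad.simulate_count_series(cfg, [1.0, 0.5], replicates=2)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_initial": 0},
            {"duration_days": 0.0},
            {"artifact_fraction": 1.0},
            {"death_hazard_per_day": -0.1},
            {"n_events_recorded": 0},
            {"hazard_step_day": 1.0},  # without hazard_after_step
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cedad.SimulationConfig(**kwargs)
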
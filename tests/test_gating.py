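"""Singlet gate, generation deconvolution, quadrant classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cedad
from cedad.gating import mixture_loglik

from conftest import make_event_table


def mixture_sample(weights, mu0=14.0, sigma=0.2, n=20000, seed=7):
    rng = np.random.default_rng(seed)
    ks = rng.choice(len(weights), size=n, p=weights)
    return 2.0 ** rng.normal(mu0 - ks, sigma), ks


class TestSingletGate:
    def test_clean_sample_mostly_retained(self, standard_sample):
        events, _ = standard_sample
        gated = cedad.gate_singlets(events)
        assert gated.meta["singlet_retained_fraction"] >= 0.95

    def test_spiked_doublets_removed(self, standard_sample):
        events, _ = standard_sample
        spiked, is_doublet = cedad.spike_doublets(events, fraction=0.10, seed=3)
        # marker column lets us map retained rows back to spike-in labels
        spiked.data["_row"] = np.arange(spiked.n_events)
        gated = cedad.gate_singlets(spiked)
        kept = np.zeros(spiked.n_events, dtype=bool)
        kept[gated.data["_row"].to_numpy()] = True
        doublets_removed = (~kept[is_doublet]).mean()
        assert doublets_removed >= 0.90

    def test_too_few_events_rejected(self):
        table = make_event_table(n=50)
        with pytest.raises(ValueError, match="100"):
            cedad.gate_singlets(table)


class TestFitGenerations:
    def test_single_component_limit(self):
        x, _ = mixture_sample([1.0, 0, 0, 0, 0], n=5000)
        profile = cedad.fit_generations(x)
        np.testing.assert_allclose(profile.proportions, [1, 0, 0, 0, 0], atol=0.01)

    def test_recovers_known_weights(self):
        w_true = [0.25, 0.25, 0.5, 0.0, 0.0]
        x, _ = mixture_sample(w_true, sigma=0.2)
        profile = cedad.fit_generations(x)
        np.testing.assert_allclose(profile.proportions, w_true, atol=0.02)

    def test_heavy_overlap_still_close_and_dominates_truth(self):
        """At sigma=0.6 the fit stays within 0.10 and beats the true params."""
        w_true = np.array([0.25, 0.25, 0.5, 0.0, 0.0])
        x, _ = mixture_sample(list(w_true), sigma=0.6)
        profile = cedad.fit_generations(x)
        np.testing.assert_allclose(profile.proportions, w_true, atol=0.10)
        ll_true = mixture_loglik(
            np.log2(x), 14.0, 0.6, np.maximum(w_true, 1e-300)
        )
        assert profile.fit_loglik >= ll_true - 1e-6 * x.size

    def test_unit_peak_spacing_enforced(self):
        x, _ = mixture_sample([0.4, 0.3, 0.2, 0.1, 0.0])
        profile = cedad.fit_generations(x)
        np.testing.assert_allclose(np.diff(profile.peak_log2_positions), -1.0)
        assert abs(profile.proportions.sum() - 1.0) < 1e-9

    def test_scale_invariance_of_proportions(self):
        x, _ = mixture_sample([0.1, 0.3, 0.4, 0.2, 0.0])
        p1 = cedad.fit_generations(x)
        p2 = cedad.fit_generations(x * 7.3)
        np.testing.assert_allclose(p1.proportions, p2.proportions, atol=1e-9)
        assert p2.mu0 - p1.mu0 == pytest.approx(np.log2(7.3), abs=1e-6)

    def test_too_few_positive_events(self):
        x = np.concatenate([2.0 ** np.random.default_rng(0).normal(14, 0.2, 400), -np.ones(500)])
        with pytest.raises(ValueError, match="500"):
            cedad.fit_generations(x)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(
        weights=st.lists(st.floats(0.05, 1.0), min_size=5, max_size=5),
        sigma=st.floats(0.15, 0.55),
        seed=st.integers(0, 2**20),
    )
    def test_em_loglik_monotone(self, weights, sigma, seed):
        """EM never decreases the mixture log-likelihood."""
        w = np.asarray(weights) / np.sum(weights)
        x, _ = mixture_sample(list(w), sigma=sigma, n=2000, seed=seed)
        profile = cedad.fit_generations(x)
        diffs = np.diff(profile.loglik_trace)
        assert np.all(diffs >= -1e-6 * max(1.0, abs(profile.fit_loglik)))


class TestAssignGenerations:
    @pytest.fixture()
    def profile(self):
        x, _ = mixture_sample([0.2, 0.2, 0.2, 0.2, 0.2], sigma=0.2)
        return cedad.fit_generations(x)

    def test_event_at_peak(self, profile):
        ctv = 2.0 ** np.array([profile.peak_log2_positions[2]])
        assert cedad.assign_generations(ctv, profile)[0] == 2

    def test_midpoint_tie_breaks_to_fewer_divisions(self):
        x, _ = mixture_sample([0.2, 0.2, 0.2, 0.2, 0.2], sigma=0.2)
        profile = cedad.fit_generations(x)
        # force exactly equal weights so the posterior tie is exact
        profile.proportions = np.full(5, 0.2)
        mid = (profile.peak_log2_positions[1] + profile.peak_log2_positions[2]) / 2
        assert cedad.assign_generations(2.0 ** np.array([mid]), profile)[0] == 1

    def test_agreement_with_truth_labels(self):
        w = [0.1, 0.3, 0.4, 0.15, 0.05]
        x, ks = mixture_sample(w, sigma=0.2)
        profile = cedad.fit_generations(x)
        assigned = cedad.assign_generations(x, profile)
        assert (assigned == ks).mean() >= 0.95

    def test_dimmer_than_last_peak_folded_in(self, profile):
        dim = 2.0 ** np.array([profile.peak_log2_positions[-1] - 3.0])
        assert cedad.assign_generations(dim, profile)[0] == profile.k_max


class TestQuadrants:
    def test_exact_counts_from_labeled_intensities(self):
        rng = np.random.default_rng(0)
        n = (80, 10, 10, 5)  # viable, apoptotic, dead, artifact
        ag = np.concatenate([
            10 ** rng.normal(2, 0.2, n[0]), 10 ** rng.normal(4, 0.2, n[1]),
            10 ** rng.normal(4, 0.2, n[2]), 10 ** rng.normal(2, 0.2, n[3]),
        ])
        pi = np.concatenate([
            10 ** rng.normal(2, 0.2, n[0]), 10 ** rng.normal(2, 0.2, n[1]),
            10 ** rng.normal(4, 0.2, n[2]), 10 ** rng.normal(4, 0.2, n[3]),
        ])
        table = make_event_table(ag=ag, pi=pi)
        q = cedad.classify_quadrants(table, 10**3, 10**3)
        assert (q.viable, q.apoptotic, q.dead, q.artifact) == n

    def test_all_negative_is_viable(self):
        table = make_event_table(ag=np.zeros(100), pi=np.zeros(100))
        q = cedad.classify_quadrants(table, 10.0, 10.0)
        assert q.viable == 100 and q.total == 100

    def test_boundary_counts_as_positive(self):
        table = make_event_table(ag=np.array([50.0]), pi=np.array([1.0]))
        q = cedad.classify_quadrants(table, 50.0, 10.0)
        assert q.apoptotic == 1

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 2**20),
        t_ag=st.floats(1.0, 1e4),
        t_pi=st.floats(1.0, 1e4),
    )
    def test_partition_conserves_events(self, seed, t_ag, t_pi):
        """The four quadrants always partition the input events."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 400))
        table = make_event_table(
            ag=10 ** rng.normal(3, 1.5, n), pi=10 ** rng.normal(3, 1.5, n), rng=rng
        )
        q = cedad.classify_quadrants(table, t_ag, t_pi)
        assert q.total == n


class TestAutoThreshold:
    def test_bimodal_threshold_separates_modes(self):
        rng = np.random.default_rng(1)
        neg = 10 ** rng.normal(2.0, 0.25, 4000)
        pos = 10 ** rng.normal(4.0, 0.25, 1000)
        thr = cedad.auto_threshold(np.concatenate([neg, pos]))
        correct = (neg < thr).mean() * 0.8 + (pos >= thr).mean() * 0.2
        assert (neg < thr).mean() >= 0.99
        assert (pos >= thr).mean() >= 0.99
        assert correct >= 0.99

    def test_unimodal_fallback_above_mode(self):
        rng = np.random.default_rng(2)
        neg = 10 ** rng.normal(2.0, 0.25, 5000)
        thr = cedad.auto_threshold(neg)
        assert thr > np.percentile(neg, 99.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cedad.auto_threshold(np.full(1000, 5.0))

    def test_handles_non_positive_values(self):
        rng = np.random.default_rng(3)
        neg = rng.normal(50, 40, 3000)  # instrument baseline can go negative
        pos = 10 ** rng.normal(4.0, 0.25, 1000)
        thr = cedad.auto_threshold(np.concatenate([neg, pos]))
        assert (pos >= thr).mean() >= 0.99


class TestEndToEndRecovery:
    def test_generation_and_quadrant_recovery(self, standard_sample):
        """Full gating chain recovers simulator truth within stated bands."""
        events, truth = standard_sample
        gated = cedad.gate_singlets(events)
        est, profile, quadrants = cedad.point_estimates(gated, generations_from="viable")
        np.testing.assert_allclose(
            profile.proportions, truth.true_generation_proportions, atol=0.03
        )
        n_vad = quadrants.viable + quadrants.apoptotic + quadrants.dead
        assert quadrants.apoptotic / n_vad == pytest.approx(
            truth.true_fraction_apoptotic, abs=0.02
        )
        assert quadrants.dead / n_vad == pytest.approx(
            truth.true_fraction_dead, abs=0.02
        )
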
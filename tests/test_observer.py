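import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import perceptlearn as pl
from perceptlearn.observer import (
    ObserverParams,
    assoc_prior_mean,
    joint_prior,
    memory_prior_mean,
    posterior_prob,
    priming_prior_mean,
    response_prob,
    run_observer,
    simulate_observer,
    stereo_mean,
)


class TestPriorMeans:
    @pytest.mark.parametrize(
        "tone,mu1hat,expected",
        [("low", 0.8, 0.8), ("high", 0.8, 0.2), ("high", 0.5, 0.5)],
    )
    def test_assoc_mean_tone_mapping(self, tone, mu1hat, expected):
        assert assoc_prior_mean(tone, mu1hat) == pytest.approx(expected)

    def test_assoc_mean_rejects_bad_tone(self):
        with pytest.raises(ValueError):
            assoc_prior_mean("middle", 0.5)

    @pytest.mark.parametrize("prev,expected", [(1, 1.0), (0, 0.0), (None, 0.5)])
    def test_priming_mean(self, prev, expected):
        assert priming_prior_mean(prev) == expected

    @pytest.mark.parametrize("prev,expected", [(1, 1.0), (0, 0.0), (None, 0.5)])
    def test_memory_mean(self, prev, expected):
        assert memory_prior_mean(prev) == expected


class TestJointPrior:
    def test_direct_arithmetic(self):
        mu, pi = joint_prior(1.0, 2.0, 0.0, 1.0, 1.0, 1.0)
        assert pi == 4.0
        assert mu == pytest.approx(0.75)

    def test_equal_means_are_fixed_point(self):
        mu, pi = joint_prior(0.3, 1.7, 0.3, 0.2, 0.3, 2.5)
        assert mu == pytest.approx(0.3)
        assert pi == pytest.approx(4.4)

    def test_zero_precision_removes_prior(self):
        mu_with, _ = joint_prior(0.9, 1.0, 0.1, 0.0, 0.5, 1.0)
        mu_without, _ = joint_prior(0.9, 1.0, 0.99, 0.0, 0.5, 1.0)
        assert mu_with == pytest.approx(mu_without)

    def test_all_zero_yields_flat_no_prior(self):
        mu, pi = joint_prior(0.9, 0.0, 0.1, 0.0, 0.4, 0.0)
        assert (mu, pi) == (0.5, 0.0)


class TestStereoMean:
    @pytest.mark.parametrize(
        "trial_type,rotation,expected",
        [
            ("unambiguous", "right", 1.0),
            ("ambiguous", "none", 0.5),
            ("unambiguous", "left", 0.0),
        ],
    )
    def test_disparity_coding(self, trial_type, rotation, expected):
        assert stereo_mean(trial_type, rotation) == expected

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ValueError):
            stereo_mean("ambiguous", "left")
        with pytest.raises(ValueError):
            stereo_mean("unambiguous", "none")


class TestPosterior:
    def test_midpoint_gives_half(self):
        assert posterior_prob(0.5, 1.0, 0.5, 3.0) == pytest.approx(0.5)

    def test_closed_form_example(self):
        # mu_m = 0.75, pi_m = 2 -> logistic(0.5 * 2) = logistic(1)
        p = posterior_prob(1.0, 1.0, 0.5, 1.0)
        assert p == pytest.approx(expit(1.0), abs=1e-12)
        assert p == pytest.approx(0.7311, abs=1e-4)

    def test_label_symmetry(self):
        p = posterior_prob(0.8, 1.3, 1.0, 2.1)
        q = posterior_prob(0.2, 1.3, 0.0, 2.1)
        assert p == pytest.approx(1.0 - q, abs=1e-12)

    def test_matches_logistic_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mu_p, mu_s = rng.random(2)
            pi_p, pi_s = rng.uniform(0.1, 5.0, 2)
            pi_m = pi_p + pi_s
            mu_m = (pi_p * mu_p + pi_s * mu_s) / pi_m
            expected = expit((2.0 * mu_m - 1.0) * pi_m)
            assert posterior_prob(mu_p, pi_p, mu_s, pi_s) == pytest.approx(
                expected, abs=1e-12
            )

    def test_fixed_mode_weight_hook(self):
        p = posterior_prob(1.0, 1.0, 0.5, 1.0, mode_weight=4.0)
        assert p == pytest.approx(expit(0.5 * 4.0), abs=1e-12)

    def test_zero_total_precision_rejected(self):
        with pytest.raises(ValueError):
            posterior_prob(0.5, 0.0, 0.5, 0.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        mu=st.floats(0, 1), pi_prior=st.floats(0, 5),
        mu_st=st.sampled_from([0.0, 0.5, 1.0]), pi_st=st.floats(0.01, 5),
    )
    def test_normalization(self, mu, pi_prior, mu_st, pi_st):
        p = posterior_prob(mu, pi_prior, mu_st, pi_st)
        q = posterior_prob(1.0 - mu, pi_prior, 1.0 - mu_st, pi_st)
        assert 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_each_prior_mean(self):
        params = dict(pi_a=1.0, pi_p=0.7, pi_s=0.4, pi_stereo=2.0)
        grid = np.linspace(0, 1, 11)

        def prob(mu_a, mu_p, mu_s, mu_stereo=0.5):
            mu, pi = joint_prior(mu_a, params["pi_a"], mu_p, params["pi_p"],
                                 mu_s, params["pi_s"])
            return posterior_prob(mu, pi, mu_stereo, params["pi_stereo"])

        for which in range(3):
            args = [0.3, 0.6, 0.4]
            vals = []
            for g in grid:
                args_g = list(args)
                args_g[which] = g
                vals.append(prob(*args_g))
            assert np.all(np.diff(vals) >= -1e-12)


class TestResponseProb:
    def test_identity_at_unit_zeta(self):
        assert response_prob(0.7311, 1.0) == pytest.approx(0.7311)

    def test_half_is_fixed_point(self):
        for zeta in (0.3, 1.0, 5.0):
            assert response_prob(0.5, zeta) == pytest.approx(0.5)

    def test_large_zeta_hard_max(self):
        assert response_prob(0.9, 200.0) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_zeta(self):
        with pytest.raises(ValueError):
            response_prob(0.5, 0.0)


class TestRunObserver:
    def test_likelihood_only_is_flat_on_ambiguous(self, simulated_subject):
        seq, records, _ = simulated_subject
        params = ObserverParams(pi_a=0.0, pi_p=0.0, pi_s=0.0, pi_stereo=2.0)
        run = run_observer(seq, records, params)
        amb = np.array([t.trial_type == "ambiguous" for t in seq])
        assert np.allclose(run.p_right[amb], 0.5)

    def test_likelihood_dominance_on_unambiguous(self, simulated_subject):
        seq, records, _ = simulated_subject
        params = ObserverParams(pi_stereo=500.0)
        run = run_observer(seq, records, params)
        for t, p in zip(seq, run.p_right):
            if t.trial_type == "unambiguous":
                target = 1.0 if t.true_rotation == "right" else 0.0
                assert abs(p - target) < 1e-3

    def test_probabilities_normalized(self, simulated_subject):
        seq, records, params = simulated_subject
        run = run_observer(seq, records, params)
        assert np.all((run.p_right >= 0) & (run.p_right <= 1))

    def test_sequential_vs_joint_fusion_equivalence(self, simulated_subject):
        # fusing priors first and likelihood second equals fusing all four
        # distributions at once
        seq, records, params = simulated_subject
        run = run_observer(seq, records, params)
        tr = run.trace
        pi_all = params.pi_a + params.pi_p + params.pi_s + params.pi_stereo
        mu_all = (
            params.pi_a * tr["mu_a"] + params.pi_p * tr["mu_p"]
            + params.pi_s * tr["mu_s"] + params.pi_stereo * tr["mu_stereo"]
        ) / pi_all
        p_joint = expit((2.0 * mu_all - 1.0) * pi_all)
        assert np.allclose(run.p_right, p_joint, atol=1e-12)

    def test_trace_matches_hand_computation_on_short_sequence(self):
        # sixteen-trial hand-built block: high tone + left rotation
        # (contingency input 1) twelve times, two reversed, two ambiguous at
        # fixed positions; percepts all rightward
        import perceptlearn.task as task

        trials = []
        plan = ["p", "p", "p", "p", "a", "p", "p", "p", "p", "a",
                "p", "p", "r", "p", "r", "p"]
        for i, kind in enumerate(plan, start=1):
            if kind == "a":
                trials.append(task.Trial(1, i, "high", "ambiguous", "none",
                                         1, "highleft", None))
            elif kind == "p":
                trials.append(task.Trial(1, i, "high", "unambiguous", "left",
                                         1, "highleft", True))
            else:
                trials.append(task.Trial(1, i, "high", "unambiguous", "right",
                                         1, "highleft", False))
        seq = task.TrialSequence(trials)
        records = [task.ResponseRecord(1, 0.5, 4, None) for _ in trials]
        params = ObserverParams(pi_a=1.0, pi_p=0.5, pi_s=0.25, pi_stereo=2.0)
        run = run_observer(seq, records, params)

        # step-by-step scalar recomputation
        from perceptlearn.hgf import hgf_filter
        from perceptlearn.observer import contingency_inputs

        mu1hat = hgf_filter(contingency_inputs(seq, records, "skip"),
                            params.hgf).mu1hat
        prev, last_amb = None, None
        for i, t in enumerate(seq):
            mu_a = 1.0 - mu1hat[i]  # all tones high
            mu_p = 0.5 if prev is None else float(prev)
            mu_s = 0.5 if last_amb is None else float(last_amb)
            pi_prior = 1.0 + 0.5 + 0.25
            mu_prior = (1.0 * mu_a + 0.5 * mu_p + 0.25 * mu_s) / pi_prior
            mu_stereo = {"left": 0.0, "right": 1.0, "none": 0.5}[t.true_rotation]
            pi_m = pi_prior + 2.0
            mu_m = (pi_prior * mu_prior + 2.0 * mu_stereo) / pi_m
            expected = 1.0 / (1.0 + math.exp(-(2.0 * mu_m - 1.0) * pi_m))
            assert run.p_right[i] == pytest.approx(expected, abs=1e-12)
            prev = 1
            if t.trial_type == "ambiguous":
                last_amb = 1
        assert run.trace["mu1hat"].iloc[0] == pytest.approx(0.5)

    def test_misaligned_lengths_rejected(self, simulated_subject):
        seq, records, params = simulated_subject
        with pytest.raises(ValueError):
            run_observer(seq, records[:-1], params)

    def test_history_drop_policy_neutralizes_until_history(self, simulated_subject):
        seq, records, _ = simulated_subject
        params = ObserverParams(pi_a=0.0, pi_p=2.0, pi_s=0.0, pi_stereo=1.0,
                                history_init="drop")
        run = run_observer(seq, records, params)
        # first trial has no percept history: prior precision must be zero
        assert run.trace["pi_prior"].iloc[0] == 0.0
        assert run.trace["pi_prior"].iloc[1] == 2.0


class TestSimulateObserver:
    def test_same_seed_identical_records(self, default_sequence):
        params = ObserverParams()
        a = simulate_observer(default_sequence, params, rng_seed=9)
        b = simulate_observer(default_sequence, params, rng_seed=9)
        assert a == b

    def test_stereo_only_ambiguous_percepts_near_chance(self, default_sequence):
        params = ObserverParams(pi_a=0.0, pi_p=0.0, pi_s=0.0, pi_stereo=2.5)
        rights = total = 0
        for seed in range(30):
            records = simulate_observer(default_sequence, params, rng_seed=seed)
            for t, r in zip(default_sequence, records):
                if t.trial_type == "ambiguous":
                    rights += r.percept
                    total += 1
        assert abs(rights / total - 0.5) < 0.05

    def test_associative_only_observer_shows_positive_assoc_bias(self):
        # Monte-Carlo sign test over many simulated observers
        params = ObserverParams(pi_a=2.0, pi_p=0.0, pi_s=0.0, pi_stereo=2.5)
        biases = _ambiguous_biases(params, "assoc", n=60)
        assert np.mean(biases) > 0
        assert (np.array(biases) > 0).mean() > 0.8

    def test_priming_only_observer_shows_positive_priming_bias(self):
        params = ObserverParams(pi_a=0.0, pi_p=2.0, pi_s=0.0, pi_stereo=2.5)
        biases = _ambiguous_biases(params, "priming", n=60)
        assert np.mean(biases) > 0
        assert (np.array(biases) > 0).mean() > 0.8

    def test_memory_only_observer_shows_positive_memory_bias(self):
        params = ObserverParams(pi_a=0.0, pi_p=0.0, pi_s=2.0, pi_stereo=2.5)
        biases = _ambiguous_biases(params, "memory", n=60)
        assert np.mean(biases) > 0
        assert (np.array(biases) > 0).mean() > 0.8

    def test_percept_coded_policy_runs(self, default_sequence):
        params = ObserverParams(ambiguous_input_policy="percept-coded")
        records = simulate_observer(default_sequence, params, rng_seed=3)
        run = run_observer(default_sequence, records, params)
        assert np.all(np.isfinite(run.p_right))


def _ambiguous_biases(params, source, n):
    seq = pl.generate_sequence(seed=77)
    biases = []
    for seed in range(n):
        records = simulate_observer(seq, params, rng_seed=seed)
        labels = pl.label_expectations(seq, records)
        b = pl.perceptual_bias(labels, source)
        if b.defined:
            biases.append(b.bias_percent)
    return biases
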
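"""Unit and property tests for the SMP generative components."""

import numpy as np
import pytest
from scipy.stats import entropy

from freeassoc.norms import CueNorms
from freeassoc.params import SMPParameters
from freeassoc.smp import (
    ACCEPTANCE_SLOPE,
    DivergentTrialError,
    acceptance_probability,
    generation_distribution,
    generation_time_spec,
    minmax_transform,
    report_probabilities,
    simulate_trial,
    trial_joint_density,
)


class TestGenerationDistribution:
    def test_beta_zero_reproduces_normalized_typicalities(self):
        p = generation_distribution(np.array([0.6, 0.3, 0.1]), beta=0.0)
        assert np.allclose(p, [0.6, 0.3, 0.1])

    def test_strongly_negative_beta_approaches_uniform(self):
        p = generation_distribution(np.array([0.6, 0.3, 0.1]), beta=-20.0)
        assert np.allclose(p, 1 / 3, atol=1e-6)

    def test_tempering_exponent_two(self):
        # exp(beta) = 2: squares typicalities then renormalizes
        p = generation_distribution(np.array([0.6, 0.3, 0.1]), beta=np.log(2.0))
        expected = np.array([0.36, 0.09, 0.01]) / 0.46
        assert np.allclose(p, expected)
        assert np.allclose(p, [0.7826, 0.1957, 0.0217], atol=1e-4)

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            generation_distribution(np.array([]), beta=0.0)

    @pytest.mark.parametrize("beta_pair", [(-2, -1), (-1, 0), (0, 1), (1, 2)])
    def test_entropy_strictly_decreasing_in_beta(self, beta_pair):
        rng = np.random.default_rng(42)
        for _ in range(10):
            typ = rng.dirichlet(np.ones(6))
            if np.ptp(typ) < 1e-3:
                continue
            h_lo = entropy(generation_distribution(typ, beta_pair[0]))
            h_hi = entropy(generation_distribution(typ, beta_pair[1]))
            assert h_hi < h_lo


class TestMinMax:
    def test_hand_example(self):
        assert np.allclose(minmax_transform([0.6, 0.3, 0.1]), [1.0, 0.4, 0.0])

    def test_endpoints_map_to_unit_interval_bounds(self):
        rng = np.random.default_rng(0)
        x = rng.random(10)
        mx = minmax_transform(x)
        assert mx[np.argmin(x)] == 0.0 and mx[np.argmax(x)] == 1.0

    def test_degenerate_vector_maps_to_half(self):
        assert np.allclose(minmax_transform([0.2, 0.2, 0.2]), 0.5)


class TestAcceptance:
    def test_midpoint_is_half(self):
        # alpha_I equal to an element's MX value gives acceptance 0.5
        typ = np.array([0.6, 0.3, 0.1])  # MX = (1, 0.4, 0)
        assert acceptance_probability(typ, 1, alpha_I=0.4, alpha_sign=1) == pytest.approx(0.5)

    def test_most_typical_with_zero_threshold(self):
        typ = np.array([0.6, 0.3, 0.1])
        p = acceptance_probability(typ, 0, alpha_I=0.0, alpha_sign=1)
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-10.0)), abs=1e-10)

    def test_sign_branches_mirror(self):
        # MX is affine, so the -1 branch equals the +1 branch at 1 - MX
        rng = np.random.default_rng(7)
        for _ in range(20):
            typ = rng.random(5) + 0.05
            a = rng.random()
            mx = minmax_transform(typ)
            neg = acceptance_probability(typ, None, a, -1)
            ref = 1.0 / (1.0 + np.exp(-ACCEPTANCE_SLOPE * ((1.0 - mx) - a)))
            assert np.allclose(neg, ref)

    def test_monotone_in_typicality_by_sign(self):
        typ = np.array([0.05, 0.1, 0.2, 0.3, 0.35])
        up = acceptance_probability(typ, None, 0.5, 1)
        dn = acceptance_probability(typ, None, 0.5, -1)
        assert np.all(np.diff(up) >= 0)
        assert np.all(np.diff(dn) <= 0)


class TestGenerationTimes:
    def test_unit_mean_at_e_inverse_probability(self):
        spec = generation_time_spec(np.array([np.exp(-1.0)]), s_mu=0.0, lam=0.5)
        assert spec["mu"][0] == pytest.approx(1.0)

    def test_moment_matching(self):
        # lam=0.5, mu=2 -> sigma=1, shape=4, scale=0.5
        p = np.array([np.exp(-2.0)])
        spec = generation_time_spec(p, s_mu=0.0, lam=0.5)
        assert spec["mu"][0] == pytest.approx(2.0)
        assert spec["sigma"][0] == pytest.approx(1.0)
        assert spec["gamma_shape"][0] == pytest.approx(4.0)
        assert spec["gamma_scale"][0] == pytest.approx(0.5)

    def test_sure_association_is_instantaneous(self):
        spec = generation_time_spec(np.array([1.0]), s_mu=0.3, lam=0.5)
        assert spec["mu"][0] == 0.0 and spec["gamma_scale"][0] == 0.0


class TestSimulateTrial:
    def test_no_rejection_variant_never_rejects(self, five_assoc_cue, moderate_params):
        rng = np.random.default_rng(0)
        for _ in range(200):
            _, rt, n_rej = simulate_trial(
                five_assoc_cue, moderate_params, rng, no_rejection=True
            )
            assert n_rej == 0
            assert rt >= moderate_params.tau0

    def test_seed_determinism(self, five_assoc_cue, moderate_params):
        a = simulate_trial(five_assoc_cue, moderate_params, np.random.default_rng(5))
        b = simulate_trial(five_assoc_cue, moderate_params, np.random.default_rng(5))
        assert a == b

    def test_rejection_count_matches_geometric_law(self):
        # equal typicalities -> MX = 0.5 -> constant acceptance probability,
        # so the rejection count is geometric with mean (1-p)/p
        cn = CueNorms("c", ["a", "b", "c", "d"], np.array([25] * 4),
                      np.array([0.25] * 4), 100)
        params = SMPParameters(beta=0.0, alpha_I=0.53, alpha_sign=1,
                               s_mu=-0.5, lam=0.5, tau0=0.1, tau_r=0.2)
        p_acc = 1.0 / (1.0 + np.exp(-ACCEPTANCE_SLOPE * (0.5 - 0.53)))
        rng = np.random.default_rng(11)
        n = 50_000
        rejections = np.array([simulate_trial(cn, params, rng)[2] for _ in range(n)])
        mean_expected = (1 - p_acc) / p_acc
        se = np.sqrt((1 - p_acc) / p_acc**2 / n)
        assert abs(rejections.mean() - mean_expected) < 3 * se

    def test_vanishing_acceptance_raises_divergence(self, five_assoc_cue):
        # a regulation threshold far above the feasible MX range drives all
        # acceptance probabilities below the divergence guard
        params = SMPParameters(beta=0.0, alpha_I=2.5, alpha_sign=1,
                               s_mu=0.0, lam=0.5, tau0=0.1, tau_r=0.2)
        with pytest.raises(DivergentTrialError):
            simulate_trial(five_assoc_cue, params, np.random.default_rng(3))


class TestJointDensity:
    def test_zero_below_non_decision_floor(self, five_assoc_cue, moderate_params):
        assert trial_joint_density(five_assoc_cue, moderate_params, "orange", 0.2) == 0.0

    def test_total_probability_is_one(self, five_assoc_cue, moderate_params):
        grid = np.linspace(1e-4, 60.0, 1501)
        total = 0.0
        for lemma in five_assoc_cue.lemmas:
            dens = [trial_joint_density(five_assoc_cue, moderate_params, lemma, t)
                    for t in grid]
            total += np.trapezoid(dens, grid)
        assert total == pytest.approx(1.0, abs=0.005)

    def test_rt_marginal_matches_report_probability(self, five_assoc_cue, moderate_params):
        marg = report_probabilities(five_assoc_cue, moderate_params)
        grid = np.linspace(1e-4, 60.0, 1501)
        for j, lemma in enumerate(five_assoc_cue.lemmas[:3]):
            dens = [trial_joint_density(five_assoc_cue, moderate_params, lemma, t)
                    for t in grid]
            assert np.trapezoid(dens, grid) == pytest.approx(marg[j], abs=1e-3)

    def test_unseen_lemma_gets_smoothed_candidate(self, five_assoc_cue, moderate_params):
        d = trial_joint_density(five_assoc_cue, moderate_params, "unheard", 2.0)
        assert d > 0.0


class TestMeanRTMechanisms:
    def _mean_rt(self, cn, params, n, seed):
        rng = np.random.default_rng(seed)
        return np.mean([simulate_trial(cn, params, rng)[1] for _ in range(n)])

    def test_mean_rt_nondecreasing_in_regulation_strength(self, five_assoc_cue):
        # stronger regulation -> more rejections -> slower responding
        means = []
        for a in (0.1, 0.4, 0.7, 0.9):
            params = SMPParameters(beta=0.0, alpha_I=a, alpha_sign=1,
                                   s_mu=0.0, lam=0.5, tau0=0.3, tau_r=0.4)
            means.append(self._mean_rt(five_assoc_cue, params, 12_000, 21))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))

    def test_mean_rt_nonincreasing_in_report_probability(self, five_assoc_cue,
                                                         moderate_params):
        # weaker (less probable) associations take longer to generate
        rng = np.random.default_rng(9)
        sims = [simulate_trial(five_assoc_cue, moderate_params, rng)
                for _ in range(40_000)]
        p = generation_distribution(five_assoc_cue.typicalities, moderate_params.beta)
        by_lemma = {}
        for lemma, rt, _ in sims:
            by_lemma.setdefault(lemma, []).append(rt)
        observed = [(p[five_assoc_cue.index_of(l)], np.mean(rts))
                    for l, rts in by_lemma.items() if len(rts) > 300]
        observed.sort(reverse=True)
        means = [m for _, m in observed]
        assert all(b >= a - 0.05 for a, b in zip(means, means[1:]))


class TestParameterSerialization:
    def test_json_round_trip(self, moderate_params):
        restored = SMPParameters.from_json(moderate_params.to_json())
        assert restored == moderate_params

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            SMPParameters(beta=0, alpha_I=0.5, alpha_sign=0, s_mu=0,
                          lam=0.5, tau0=0.1, tau_r=0.2)
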
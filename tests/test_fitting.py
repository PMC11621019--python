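"""Tests for the hierarchical importance-sampling EM machinery."""

import numpy as np
import pandas as pd
import pytest

from freeassoc.fitting import (
    DEFAULT_N_FINAL_SETTINGS,
    DEFAULT_N_SETTINGS,
    _normalized_weights,
    em_iteration,
    estimate_participants,
    fit_hierarchical,
    participant_loglik,
)
from freeassoc.model import SemiMarkovAssociationModel
from freeassoc.params import GroupPrior, PriorSpec, SMPParameters, default_group_prior
from freeassoc.smp import trial_joint_density
from freeassoc.synthetic import (
    SyntheticConfig,
    generate_cohort,
    generate_cue_norms,
    simulate_dataset,
)


def small_dataset(n_participants=6, seed=0, beta_mean=-0.5):
    cfg = SyntheticConfig(n_cues=15, trials_per_participant=10,
                          n_assoc_per_cue=6, seed=seed)
    norms = generate_cue_norms(cfg)
    prior = GroupPrior({
        "beta": PriorSpec("normal", (beta_mean, 0.4)),
        "alpha_I": PriorSpec("beta", (2.0, 2.0)),
        "alpha_sign": PriorSpec("bernoulli_pm1", (0.7,)),
        "s_mu": PriorSpec("normal", (0.0, 0.3)),
        "lam": PriorSpec("lognormal", (np.log(0.5), 0.2)),
        "tau0": PriorSpec("lognormal", (np.log(0.3), 0.2)),
        "tau_r": PriorSpec("lognormal", (np.log(0.4), 0.2)),
    })
    cohort = generate_cohort(n_participants, prior, seed)
    trials, _ = simulate_dataset(cohort, norms, cfg)
    return trials, norms, cohort, prior


class TestParticipantLoglik:
    def test_matches_per_trial_density_loop(self):
        trials, norms, cohort, _ = small_dataset(n_participants=1, seed=1)
        params = next(iter(cohort.values()))
        p3 = trials.head(3)
        got = participant_loglik(p3, norms, [params])[0]
        expected = sum(
            np.log(trial_joint_density(norms[r.cue_id], params,
                                       r.response_lemma, r.rt_ms / 1000.0))
            for r in p3.itertuples()
        )
        # the batched path uses a coarser inversion grid than the dense
        # reference density; agreement is to likelihood accuracy
        assert got == pytest.approx(expected, abs=0.2)

    def test_zero_trials_gives_zero_loglik(self):
        trials, norms, cohort, _ = small_dataset(n_participants=1, seed=2)
        empty = trials.iloc[0:0]
        ll = participant_loglik(empty, norms, [next(iter(cohort.values()))] * 3)
        assert np.array_equal(ll, np.zeros(3))

    def test_missing_cue_is_data_error(self):
        trials, norms, cohort, _ = small_dataset(n_participants=1, seed=3)
        bad = trials.copy()
        bad.loc[bad.index[0], "cue_id"] = "nonexistent"
        with pytest.raises(KeyError):
            participant_loglik(bad, norms, [next(iter(cohort.values()))])

    def test_rt_below_tau0_hits_log_floor_not_minus_inf(self):
        trials, norms, cohort, _ = small_dataset(n_participants=1, seed=4)
        params = SMPParameters(beta=0.0, alpha_I=0.3, alpha_sign=1,
                               s_mu=0.0, lam=0.5, tau0=50.0, tau_r=0.1)
        ll = participant_loglik(trials.head(2), norms, [params])
        assert np.isfinite(ll[0])


class TestImportanceWeights:
    def test_weights_are_normalized_and_nonnegative(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-100, 30, size=500)
        w = _normalized_weights(ll)
        assert np.all(w >= 0) and w.sum() == pytest.approx(1.0)

    def test_underflow_falls_back_to_uniform(self):
        w = _normalized_weights(np.full(10, -np.inf))
        assert np.allclose(w, 0.1)


class TestEMIteration:
    def test_point_mass_priors_unchanged(self):
        trials, norms, _, _ = small_dataset(n_participants=3, seed=5)
        point = GroupPrior({
            "beta": PriorSpec("normal", (-0.3, 0.0)),
            "alpha_I": PriorSpec("beta", (2.0, 2.0)),
            "alpha_sign": PriorSpec("bernoulli_pm1", (1.0,)),
            "s_mu": PriorSpec("normal", (0.0, 0.0)),
            "lam": PriorSpec("lognormal", (np.log(0.5), 0.0)),
            "tau0": PriorSpec("lognormal", (np.log(0.3), 0.0)),
            "tau_r": PriorSpec("lognormal", (np.log(0.4), 0.0)),
        })
        by = {p: g for p, g in trials.groupby("participant_id")}
        new, _ = em_iteration(by, norms, point, 50, np.random.default_rng(5))
        # point-mass locations are reproduced (dispersion floors excepted)
        assert new["beta"].hyper[0] == pytest.approx(-0.3, abs=1e-9)
        assert new["s_mu"].hyper[0] == pytest.approx(0.0, abs=1e-9)
        assert new["lam"].hyper[0] == pytest.approx(np.log(0.5), abs=1e-9)

    def test_refit_prior_shrinks_toward_generating_mean(self):
        # data generated at group mean beta = -1; EM initialized at 0 must
        # move the beta prior mean strictly into (-1, 0) after one iteration
        cfg = SyntheticConfig(n_cues=20, trials_per_participant=12,
                              n_assoc_per_cue=6, seed=6)
        norms = generate_cue_norms(cfg)
        gen = GroupPrior({
            "beta": PriorSpec("normal", (-1.0, 0.3)),
            "alpha_I": PriorSpec("beta", (2.0, 2.0)),
            "alpha_sign": PriorSpec("bernoulli_pm1", (1.0,)),
            "s_mu": PriorSpec("normal", (0.0, 0.3)),
            "lam": PriorSpec("lognormal", (np.log(0.5), 0.2)),
            "tau0": PriorSpec("lognormal", (np.log(0.3), 0.2)),
            "tau_r": PriorSpec("lognormal", (np.log(0.4), 0.2)),
        })
        cohort = generate_cohort(40, gen, 6)
        trials, _ = simulate_dataset(cohort, norms, cfg)
        init = GroupPrior(dict(gen.specs, beta=PriorSpec("normal", (0.0, 1.0))))
        by = {p: g for p, g in trials.groupby("participant_id")}
        new, _ = em_iteration(by, norms, init, 150, np.random.default_rng(6))
        assert -1.0 < new["beta"].hyper[0] < -0.05

    def test_default_settings_counts_match_procedure_constants(self):
        assert DEFAULT_N_SETTINGS == 1000
        assert DEFAULT_N_FINAL_SETTINGS == 10_000


class TestFitHierarchical:
    def test_ibic_penalty_scales_with_log_trial_count(self):
        # doubling the trial count at fixed hyperparameter count H raises
        # the penalty term by H * ln 2
        prior = default_group_prior("full")
        H = prior.n_hyperparameters
        assert H == 13
        assert default_group_prior("no_rejection").n_hyperparameters == 10
        n = 500
        penalty1 = H * np.log(n)
        penalty2 = H * np.log(2 * n)
        assert penalty2 - penalty1 == pytest.approx(H * np.log(2))

    def test_identical_seed_gives_identical_report(self):
        trials, norms, _, _ = small_dataset(n_participants=4, seed=7)
        kw = dict(n_settings=60, max_iter=2, n_final_settings=80, seed=42)
        a = SemiMarkovAssociationModel(trials, norms).fit(**kw)
        b = SemiMarkovAssociationModel(trials, norms).fit(**kw)
        assert a.ibic_trace == b.ibic_trace
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_ibic_invariant_to_participant_permutation(self):
        trials, norms, _, prior = small_dataset(n_participants=4, seed=8)
        by = {p: g for p, g in trials.groupby("participant_id")}
        _, ib1 = em_iteration(by, norms, prior, 40, np.random.default_rng(8))
        # permuting participant order must not change the iBIC (participants
        # are sampled in sorted order internally)
        shuffled = dict(reversed(list(by.items())))
        _, ib2 = em_iteration(shuffled, norms, prior, 40, np.random.default_rng(8))
        assert ib1 == pytest.approx(ib2)

    def test_requires_two_participants(self):
        trials, norms, _, prior = small_dataset(n_participants=1, seed=9)
        with pytest.raises(ValueError):
            fit_hierarchical(trials, norms, prior, n_settings=20, max_iter=1)


class TestEstimateParticipants:
    def test_degenerate_prior_returns_that_setting(self):
        trials, norms, _, _ = small_dataset(n_participants=2, seed=10)
        point = GroupPrior({
            "beta": PriorSpec("normal", (-0.2, 0.0)),
            "alpha_I": PriorSpec("beta", (1e9, 1e9)),
            "alpha_sign": PriorSpec("bernoulli_pm1", (1.0,)),
            "s_mu": PriorSpec("normal", (0.1, 0.0)),
            "lam": PriorSpec("lognormal", (np.log(0.5), 0.0)),
            "tau0": PriorSpec("lognormal", (np.log(0.3), 0.0)),
            "tau_r": PriorSpec("lognormal", (np.log(0.4), 0.0)),
        })
        est = estimate_participants(trials, norms, point, n_settings=30,
                                    rng=np.random.default_rng(10))
        for p in est.values():
            assert p.beta == pytest.approx(-0.2)
            assert p.s_mu == pytest.approx(0.1)
            assert p.alpha_I == pytest.approx(0.5, abs=1e-3)

    def test_shared_settings_across_participants(self):
        # identical trial sets must produce identical estimates, because the
        # same settings sample is scored for every participant
        trials, norms, _, _ = small_dataset(n_participants=1, seed=11)
        dup = trials.copy()
        dup["participant_id"] = "clone"
        both = pd.concat([trials, dup], ignore_index=True)
        est = estimate_participants(both, norms, default_group_prior(),
                                    n_settings=100, rng=np.random.default_rng(11))
        pids = list(est)
        assert est[pids[0]] == est[pids[1]]


class TestModelSurface:
    def test_summary_reports_variant_and_priors(self):
        trials, norms, _, _ = small_dataset(n_participants=3, seed=12)
        res = SemiMarkovAssociationModel(trials, norms).fit(
            n_settings=40, max_iter=2, n_final_settings=50, seed=12)
        text = res.summary()
        assert "variant: full" in text
        assert "beta" in text and "tau_r" in text
        assert len(res.params) == 3

    def test_no_rejection_variant_drops_regulation_parameters(self):
        trials, norms, _, _ = small_dataset(n_participants=3, seed=13)
        model = SemiMarkovAssociationModel(trials, norms, variant="no_rejection")
        res = model.fit(n_settings=40, max_iter=2, n_final_settings=50, seed=13)
        assert "alpha_I" not in res.group_prior.specs
        assert res.group_prior.n_hyperparameters == 10

    def test_posterior_predictive_simulation_schema(self):
        trials, norms, cohort, _ = small_dataset(n_participants=2, seed=14)
        model = SemiMarkovAssociationModel(trials, norms)
        sim = model.simulate(cohort, seed=14)
        assert set(sim.columns) == {"participant_id", "cue_id", "response_lemma",
                                    "rt_ms", "n_rejected"}
        assert len(sim) == len(trials)
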
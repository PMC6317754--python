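"""Inference engine: state smoothing, free energies, policy posterior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avhsim.engine import (
    ACTION_TIE_TOL,
    compute_expected_free_energy,
    compute_policy_free_energy,
    infer,
    likelihood_entropy,
    marginal_state_beliefs,
    policy_posterior,
    select_action,
    update_state_beliefs,
)
from avhsim.model import GenerativeModel, Observation, Policy
from avhsim.oracle import exact_state_posterior


def model_with(policy_code, **kw):
    pol = Policy.from_string(policy_code)
    kw.setdefault("n_steps", len(policy_code) + 1)
    return GenerativeModel(policy_catalog=[pol], **kw), pol


class TestStateBeliefs:
    def test_precise_likelihood_inverts_observation(self):
        # near-identity likelihood: a single "sound" pins "voice present"
        m, pol = model_with("L", zeta=100.0)
        b = update_state_beliefs(m, pol, [Observation("sound", "none")], 1)
        assert b["auditory"][0, 0] > 0.999

    def test_attenuated_likelihood_carries_no_information(self):
        m, pol = model_with("L", zeta=100.0)
        b = update_state_beliefs(
            m, pol, [Observation("sound", "none")], 1, attenuation_flags=[True]
        )
        np.testing.assert_allclose(b["auditory"][0], [0.5, 0.5], atol=1e-12)

    def test_future_steps_are_prior_rollout(self):
        m, pol = model_with("S", zeta=0.7)
        b = update_state_beliefs(m, pol, [Observation("silence", "none")], 1)
        # speak transition drives speech factor to "speaking" deterministically
        np.testing.assert_allclose(b["speech"][1], [1.0, 0.0], atol=1e-6)

    @pytest.mark.parametrize("zeta", [0.0, 0.3, 0.7, 5.0])
    @pytest.mark.parametrize("code", ["L", "S", "LL", "LS", "SL", "SS"])
    def test_matches_enumeration_oracle(self, zeta, code):
        m, pol = model_with(code, zeta=zeta)
        T = m.n_steps
        obs = [Observation(o, "none") for o in ("sound", "silence", "sound")[:T]]
        b = update_state_beliefs(m, pol, obs, T)
        exact = exact_state_posterior(m, pol, obs)
        for f in ("auditory", "speech"):
            np.testing.assert_allclose(b[f], exact.marginals[f], atol=1e-6)

    def test_observation_count_checked(self):
        m, pol = model_with("L")
        with pytest.raises(ValueError):
            update_state_beliefs(m, pol, [], 1)


class TestPolicyFreeEnergy:
    def test_bound_and_tightness(self):
        # deterministic chains: posterior factorizes, so the bound is tight
        m, pol = model_with("S", zeta=100.0)
        obs = [Observation("silence", "none"), Observation("sound", "speech_movement")]
        b = update_state_beliefs(m, pol, obs, 2)
        F = compute_policy_free_energy(m, pol, b, obs, 2)
        exact = exact_state_posterior(m, pol, obs)
        assert F >= -exact.log_evidence - 1e-10
        assert F == pytest.approx(-exact.log_evidence, abs=1e-6)

    @pytest.mark.parametrize("zeta", [0.0, 0.3, 0.7])
    def test_bound_holds_for_soft_chains(self, zeta):
        m, pol = model_with("LL", zeta=zeta)
        obs = [Observation("sound", "none")] * 3
        b = update_state_beliefs(m, pol, obs, 3)
        F = compute_policy_free_energy(m, pol, b, obs, 3)
        exact = exact_state_posterior(m, pol, obs)
        assert F >= -exact.log_evidence - 1e-10

    def test_equals_evidence_plus_kl_of_factorized_posterior(self):
        # F = -log Z + KL(prod_t q_t || joint posterior), evaluated by
        # enumerating the joint independently of the engine
        pol = Policy.from_string("L")
        m = GenerativeModel(n_steps=2, zeta=0.7, policy_catalog=[pol])
        obs = [Observation("sound", "none"), Observation("silence", "none")]
        b = update_state_beliefs(m, pol, obs, 2)
        F = compute_policy_free_energy(m, pol, b, obs, 2)
        exact = exact_state_posterior(m, pol, obs)
        kl = 0.0
        for f in ("auditory", "speech"):
            post = exact.joint[f]
            for traj in np.ndindex(*post.shape):
                q = np.prod([b[f][t, s] for t, s in enumerate(traj)])
                if q > 0 and post[traj] > 0:
                    kl += q * np.log(q / post[traj])
        assert F == pytest.approx(-exact.log_evidence + kl, abs=1e-6)


class TestExpectedFreeEnergy:
    def test_precise_likelihood_has_no_ambiguity(self):
        m, pol = model_with("L", zeta=100.0)
        H = likelihood_entropy(m.auditory_likelihood())
        np.testing.assert_allclose(H, 0.0, atol=1e-6)

    def test_uniform_likelihood_ambiguity_is_log2(self):
        # zeta = 0 flattens the mapping: each future step contributes log 2
        # of auditory ambiguity regardless of the state belief
        m, pol = model_with("L", zeta=0.0)
        H = likelihood_entropy(m.auditory_likelihood())
        np.testing.assert_allclose(H, np.log(2.0), atol=1e-12)
        obs = [Observation("sound", "none")]
        b = update_state_beliefs(m, pol, obs, 1)
        G = compute_expected_free_energy(m, pol, b, 1)
        # one future listening step: flat predictions carry zero risk in
        # both modalities except the deterministic proprioceptive outcome
        assert G == pytest.approx(np.log(2.0) + np.log(2.0), abs=1e-4)

    def test_flat_prediction_under_flat_preferences_has_zero_risk(self):
        # risk = o . (log o - C) vanishes when o and C are both flat
        o = np.array([0.5, 0.5])
        C = np.log(np.array([0.5, 0.5]))
        assert float(o @ (np.log(o) - C)) == pytest.approx(0.0, abs=1e-12)

    def test_speaking_turn_is_never_riskier_than_listening(self):
        # attenuation flattens predicted auditory outcomes, so under flat
        # preferences a speaking policy's G cannot exceed the all-listen
        # policy's G (the epistemics of conversational turn-taking)
        listen_m, listen_pol = model_with("LLLL", zeta=0.525)
        speak_m, speak_pol = model_with("SLSL", zeta=0.525)
        obs = [Observation("silence", "none")]
        bl = update_state_beliefs(listen_m, listen_pol, obs, 1)
        bs = update_state_beliefs(speak_m, speak_pol, obs, 1)
        G_listen = compute_expected_free_energy(listen_m, listen_pol, bl, 1)
        G_speak = compute_expected_free_energy(speak_m, speak_pol, bs, 1)
        assert G_speak <= G_listen + 1e-10


class TestPolicyPosterior:
    def test_symmetric_inputs_give_uniform(self):
        q = policy_posterior([1.0, 1.0], [2.0, 2.0], 0.0, [True, True])
        np.testing.assert_allclose(q, [0.5, 0.5], atol=1e-12)

    def test_unit_precision_softmax_arithmetic(self):
        q = policy_posterior([0.0, 0.0], [1.0, 2.0], 0.0, [True, True])
        expected = np.exp([-1.0, -2.0])
        expected /= expected.sum()
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert q[0] == pytest.approx(0.731, abs=5e-4)

    def test_zero_precision_limit_is_uniform(self):
        q = policy_posterior([0.0, 0.0], [1.0, 5.0], -50.0, [True, True])
        np.testing.assert_allclose(q, [0.5, 0.5], atol=1e-6)

    def test_masked_policies_get_zero_mass(self):
        q = policy_posterior([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], 0.0, [True, False, True])
        assert q[1] == 0.0
        np.testing.assert_allclose(q.sum(), 1.0)

    def test_all_masked_raises(self):
        with pytest.raises(ValueError):
            policy_posterior([0.0], [0.0], 0.0, [False])

    @settings(deadline=None)
    @given(
        shift=st.floats(-50, 50),
        F=st.lists(st.floats(-5, 5), min_size=2, max_size=6),
    )
    def test_shift_invariance(self, shift, F):
        F = np.asarray(F)
        G = np.zeros_like(F)
        mask = np.ones(len(F), dtype=bool)
        q1 = policy_posterior(F, G, 0.3, mask)
        q2 = policy_posterior(F + shift, G, 0.3, mask)
        np.testing.assert_allclose(q1, q2, atol=1e-9)

    @settings(deadline=None)
    @given(
        gammas=st.lists(st.floats(-3, 3), min_size=2, max_size=2, unique=True),
        G=st.lists(st.floats(0, 4), min_size=3, max_size=3, unique=True),
    )
    def test_precision_monotonicity(self, gammas, G):
        # more precision -> more mass on the best policy
        lo, hi = sorted(gammas)
        G = np.asarray(G)
        mask = np.ones(3, dtype=bool)
        best = int(np.argmin(G))
        q_lo = policy_posterior(np.zeros(3), G, lo, mask)
        q_hi = policy_posterior(np.zeros(3), G, hi, mask)
        assert q_hi[best] >= q_lo[best] - 1e-9


class TestMarginalsAndActions:
    def test_single_policy_marginal_is_its_conditional(self):
        beliefs = [{"auditory": np.array([[0.3, 0.7]]), "speech": np.array([[1.0, 0.0]])}]
        m = marginal_state_beliefs(beliefs, np.array([1.0]))
        np.testing.assert_allclose(m["auditory"], [[0.3, 0.7]])

    def test_weighted_average(self):
        beliefs = [
            {"auditory": np.array([[1.0, 0.0]]), "speech": np.array([[0.5, 0.5]])},
            {"auditory": np.array([[0.0, 1.0]]), "speech": np.array([[0.5, 0.5]])},
        ]
        m = marginal_state_beliefs(beliefs, np.array([0.75, 0.25]))
        np.testing.assert_allclose(m["auditory"], [[0.75, 0.25]])

    @settings(deadline=None)
    @given(w=st.floats(0.0, 1.0), p=st.floats(0.0, 1.0), r=st.floats(0.0, 1.0))
    def test_marginals_normalized(self, w, p, r):
        beliefs = [
            {"auditory": np.array([[p, 1 - p]]), "speech": np.array([[r, 1 - r]])},
            {"auditory": np.array([[r, 1 - r]]), "speech": np.array([[p, 1 - p]])},
        ]
        m = marginal_state_beliefs(beliefs, np.array([w, 1 - w]))
        np.testing.assert_allclose(m["auditory"].sum(axis=1), 1.0, atol=1e-10)

    def test_action_of_map_policy(self):
        catalog = [Policy.from_string("LL"), Policy.from_string("SS")]
        assert select_action(np.array([0.6, 0.4]), catalog, 1) == "listen"
        assert select_action(np.array([0.1, 0.9]), catalog, 2) == "speak"

    def test_near_ties_resolve_by_catalog_order(self):
        catalog = [Policy.from_string("SS"), Policy.from_string("LL")]
        eps = ACTION_TIE_TOL / 10
        post = np.array([0.5 - eps, 0.5 + eps])
        assert select_action(post, catalog, 1) == "speak"


class TestRegimeLimits:
    def test_sensory_dominance_at_high_precision(self):
        # zeta large: observed outcomes pin the marginal at every step
        m = GenerativeModel(
            n_steps=3,
            zeta=100.0,
            policy_catalog=[Policy.from_string("LL"), Policy.from_string("LS")],
        )
        obs = [Observation("silence", "none"), Observation("sound", "none"),
               Observation("silence", "none")]
        state = infer(m, obs, [False] * 3, ["listen", "listen"], 3)
        voice = state.marginal_states["auditory"][:, 0]
        assert voice[0] < 0.01 and voice[1] > 0.99 and voice[2] < 0.01

    def test_prior_dominance_under_attenuation(self):
        # a flat likelihood leaves the transition-propagated prior in charge
        m, pol = model_with("S", zeta=0.7)
        obs = [Observation("silence", "none"), Observation("sound", "speech_movement")]
        b = update_state_beliefs(m, pol, obs, 2, attenuation_flags=[False, True])
        prior = m.transition_model["speak"]["auditory"] @ b["auditory"][0]
        np.testing.assert_allclose(b["auditory"][1], prior, atol=1e-6)

    def test_belief_state_consistency(self):
        m = GenerativeModel(
            n_steps=3,
            zeta=0.525,
            policy_catalog=[Policy.from_string("LL"), Policy.from_string("SL")],
        )
        obs = [Observation("silence", "none"), Observation("sound", "none")]
        state = infer(m, obs, [False, False], ["listen"], 2)
        state.check(atol=1e-8)
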
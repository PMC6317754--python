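"""Variational inference engine: state estimation, free energies, policy
posterior and action selection.

Per policy, each hidden-state factor forms an independent Markov chain
(transitions and likelihoods never couple the two factors), so cavity
message passing along each chain yields the exact smoothing posterior;
the factorization of Q over time enters only the free-energy functional.
Beliefs about states under every policy are then
combined with the policy posterior by Bayesian model averaging to give the
marginal percept — the quantity that can "hallucinate".

Policy evaluation: F(pi) accumulates the evidence of observed steps under
each policy; G(pi) scores future steps by risk (divergence of predicted
outcomes from preferences) plus ambiguity (expected outcome entropy given
states). The posterior over policies is a softmax of the total
log-evidence -(F + G) sharpened by the policy precision gamma, with
policies inconsistent with already-executed actions masked out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    LOG_FLOOR_EPS,
    GenerativeModel,
    Observation,
    Policy,
)

__all__ = [
    "BeliefState",
    "update_state_beliefs",
    "compute_policy_free_energy",
    "compute_expected_free_energy",
    "policy_posterior",
    "marginal_state_beliefs",
    "select_action",
    "likelihood_entropy",
]


#: posterior log-ratio below which policies count as tied during action
#: selection (free-energy resolution of the variational scheme)
ACTION_TIE_TOL = 1e-2

# factor -> (modality, which Observation index to read)
_FACTOR_MODALITY = {"auditory": "auditory", "speech": "proprioceptive"}


def _log(x: np.ndarray) -> np.ndarray:
    """Floored natural log: delta distributions behave like deltas at
    working precision instead of producing -inf."""
    return np.log(np.maximum(x, LOG_FLOOR_EPS))


def _softmax(v: np.ndarray) -> np.ndarray:
    v = v - v.max()
    e = np.exp(v)
    return e / e.sum()


def _likelihood(model: GenerativeModel, modality: str, attenuated: bool) -> np.ndarray:
    if modality == "auditory":
        return model.auditory_likelihood(attenuated=attenuated)
    return model.proprioceptive_likelihood()


def _outcome_index(obs: Observation, modality: str) -> int:
    return obs.auditory_index if modality == "auditory" else obs.proprioceptive_index


def likelihood_entropy(A: np.ndarray) -> np.ndarray:
    """Column entropies H_j = -sum_i A_ij log A_ij (the ambiguity vector)."""
    return -(A * _log(A)).sum(axis=0)


def update_state_beliefs(
    model: GenerativeModel,
    policy: Policy,
    observations: list[Observation],
    current_time: int,
    attenuation_flags: list[bool] | None = None,
) -> dict[str, np.ndarray]:
    """Smoothing posterior Q(s_tau | pi) for tau = 1..T by message passing.

    Each factor's belief at tau combines a likelihood message (observed
    steps only; attenuation-aware for the auditory modality), a forward
    message through the policy's transition, and a backward message from
    future evidence. The messages are cavity messages — the forward
    (backward) message entering a step excludes that step's own backward
    (forward) contribution — so on these chain-structured factors a single
    forward and backward sweep reaches the fixed point and the resulting
    marginals are exact. Future steps carry no likelihood message and
    amount to a pure rollout. Matrices are floored before use so one-hot
    columns behave like deltas at working precision.

    Returns {factor: (T, 2) array of per-step state distributions}.
    """
    T = model.n_steps
    if not (1 <= current_time <= T):
        raise ValueError(f"current_time {current_time} outside 1..{T}")
    if len(observations) < current_time:
        raise ValueError("observations missing for some tau <= current_time")
    if attenuation_flags is None:
        attenuation_flags = [False] * current_time

    beliefs: dict[str, np.ndarray] = {}
    for f, modality in _FACTOR_MODALITY.items():
        D = np.maximum(np.asarray(model.initial_beliefs[f], dtype=float), LOG_FLOOR_EPS)
        B = [
            np.maximum(
                np.asarray(model.transition_model[policy.actions[t]][f], dtype=float),
                LOG_FLOOR_EPS,
            )
            for t in range(T - 1)
        ]
        # per-step likelihood weight over states (ones where unobserved)
        w = np.ones((T, 2))
        for tau in range(current_time):
            A = np.maximum(
                _likelihood(model, modality, attenuation_flags[tau]), LOG_FLOOR_EPS
            )
            o = _outcome_index(observations[tau], modality)
            w[tau] = A[o, :]

        alpha = np.zeros((T, 2))  # filtered forward messages
        v = w[0] * D
        alpha[0] = v / v.sum()
        for tau in range(1, T):
            v = w[tau] * (B[tau - 1] @ alpha[tau - 1])
            alpha[tau] = v / v.sum()
        beta = np.ones((T, 2))  # future-evidence backward messages
        for tau in range(T - 2, -1, -1):
            v = B[tau].T @ (w[tau + 1] * beta[tau + 1])
            beta[tau] = v / v.sum()
        q = alpha * beta
        beliefs[f] = q / q.sum(axis=1, keepdims=True)
    return beliefs


def compute_policy_free_energy(
    model: GenerativeModel,
    policy: Policy,
    beliefs: dict[str, np.ndarray],
    observations: list[Observation],
    current_time: int,
    attenuation_flags: list[bool] | None = None,
) -> float:
    """Variational free energy F(pi) of the observed steps under the policy.

    F = E_Q[ln Q(s|pi) - ln P(o, s|pi)] with P factorizing into initial
    beliefs D, policy transitions B, and the attenuation-aware likelihoods
    of the observed outcomes. F upper-bounds -log evidence; the bound is
    tight when Q is the exact posterior.
    """
    if attenuation_flags is None:
        attenuation_flags = [False] * current_time
    F = 0.0
    for f, modality in _FACTOR_MODALITY.items():
        q = beliefs[f]
        F += float(q[0] @ (_log(q[0]) - _log(np.asarray(model.initial_beliefs[f]))))
        for tau in range(1, current_time):
            Bm = np.asarray(model.transition_model[policy.actions[tau - 1]][f])
            # E_Q[ln q_tau] - E_Q[ln B] cross term
            F += float(q[tau] @ _log(q[tau]) - q[tau] @ _log(Bm) @ q[tau - 1])
        for tau in range(current_time):
            A = _likelihood(model, modality, attenuation_flags[tau])
            o = _outcome_index(observations[tau], modality)
            F -= float(q[tau] @ _log(A[o, :]))
    return F


def compute_expected_free_energy(
    model: GenerativeModel,
    policy: Policy,
    beliefs: dict[str, np.ndarray],
    current_time: int,
) -> float:
    """Expected free energy G(pi) over the remaining steps.

    Per future step and modality, with predicted states s and outcomes
    o = A s: risk = o . (log o - C) and ambiguity = s . H where H holds the
    column entropies of the likelihood mapping. Preferences C are flat by
    default, so policy value is purely epistemic.

    Outcome predictions are attenuation-aware: when the policy itself
    prescribes speaking into a future step, the agent predicts its own
    sensory attenuation and hence a flat auditory outcome — which carries
    zero risk under flat preferences, so taking a speaking turn is never
    penalized. The ambiguity vector H, by contrast, always scores the
    unattenuated state-outcome mapping: it is a property of the world's
    auditory channel, not of the agent's attentional stance.
    """
    T = model.n_steps
    G = 0.0
    for tau in range(current_time, T):  # 0-based future steps
        act = policy.actions[tau - 1]
        for f, modality in _FACTOR_MODALITY.items():
            A_pred = _likelihood(
                model,
                modality,
                attenuated=(act == "speak" and modality == "auditory"),
            )
            A_world = _likelihood(model, modality, attenuated=False)
            s = beliefs[f][tau]
            o = A_pred @ s
            C = np.asarray(model.preferences[modality])
            risk = float(o @ (_log(o) - C))
            ambiguity = float(s @ likelihood_entropy(A_world))
            G += risk + ambiguity
    return G


def policy_posterior(
    F_vector: np.ndarray,
    G_vector: np.ndarray,
    gamma_log: float,
    consistency_mask: np.ndarray,
) -> np.ndarray:
    """Posterior over policies: softmax of gamma * -(F + G) on the unmasked set.

    gamma = exp(gamma_log) acts as an inverse temperature on the total
    policy log-evidence: gamma -> 0 flattens the posterior over all viable
    policies (low precision), large gamma concentrates it on the best one.
    Policies inconsistent with executed actions (mask False) get zero mass.
    """
    F_vector = np.asarray(F_vector, dtype=float)
    G_vector = np.asarray(G_vector, dtype=float)
    mask = np.asarray(consistency_mask, dtype=bool)
    if not mask.any():
        raise ValueError("all policies masked: no viable explanation of behavior")
    gamma = float(np.exp(gamma_log))
    v = gamma * (-(F_vector[mask] + G_vector[mask]))
    q = np.zeros_like(F_vector)
    q[mask] = _softmax(v)
    return q


def marginal_state_beliefs(
    per_policy_states: list[dict[str, np.ndarray]],
    policy_post: np.ndarray,
) -> dict[str, np.ndarray]:
    """Bayesian model averaging: Q(s_tau) = sum_pi Q(s_tau|pi) Q(pi)."""
    policy_post = np.asarray(policy_post, dtype=float)
    out: dict[str, np.ndarray] = {}
    for f in _FACTOR_MODALITY:
        stacked = np.stack([b[f] for b in per_policy_states])  # (n_pi, T, 2)
        out[f] = np.einsum("p,pts->ts", policy_post, stacked)
    return out


def select_action(
    policy_post: np.ndarray,
    policy_catalog: list[Policy],
    current_time: int,
    tie_break_seed: int = 0,
) -> str:
    """Execute the action prescribed by the most probable policy.

    Planning is model selection: the agent commits to the policy with the
    highest posterior (lowest total free energy) and performs the action
    that policy prescribes on the transition out of ``current_time``.

    Policies whose posterior lies within a factor ``exp(-ACTION_TIE_TOL)``
    of the maximum are treated as tied: at this problem size free-energy
    differences below ~0.01 nats are dominated by the fixed-point
    iteration's factorization error, so rank order among them carries no
    information. Ties resolve by catalog order, which keeps runs
    deterministic; the seed is reserved for stochastic selection schemes
    and does not affect the default deterministic rule.
    """
    policy_post = np.asarray(policy_post, dtype=float)
    cutoff = policy_post.max() * float(np.exp(-ACTION_TIE_TOL))
    best = int(np.flatnonzero(policy_post >= cutoff)[0])
    return policy_catalog[best].actions[current_time - 1]


@dataclass
class BeliefState:
    """Snapshot of the engine's beliefs after one perception-action cycle."""

    per_policy_states: list[dict[str, np.ndarray]]
    policy_post: np.ndarray
    policy_free_energy: np.ndarray
    expected_free_energy: np.ndarray
    marginal_states: dict[str, np.ndarray]
    ambiguity: dict[str, np.ndarray] = field(default_factory=dict)

    def check(self, atol: float = 1e-8) -> None:
        """Raise if any stored distribution or the averaging identity fails."""
        if not np.isclose(self.policy_post.sum(), 1.0, atol=atol):
            raise AssertionError("policy posterior does not sum to 1")
        for b in self.per_policy_states:
            for f, q in b.items():
                if not np.allclose(q.sum(axis=1), 1.0, atol=atol):
                    raise AssertionError(f"per-policy beliefs for {f} not normalized")
        recomputed = marginal_state_beliefs(self.per_policy_states, self.policy_post)
        for f, q in self.marginal_states.items():
            if not np.allclose(q, recomputed[f], atol=atol):
                raise AssertionError(f"marginal beliefs for {f} break the averaging identity")


def infer(
    model: GenerativeModel,
    observations: list[Observation],
    attenuation_flags: list[bool],
    executed_actions: list[str],
    current_time: int,
) -> BeliefState:
    """One full perception cycle at ``current_time``: per-policy smoothing,
    free energies, policy posterior (with action-consistency masking) and
    Bayesian model averaging."""
    catalog = model.policy_catalog
    per_policy = []
    F = np.zeros(len(catalog))
    G = np.zeros(len(catalog))
    mask = np.zeros(len(catalog), dtype=bool)
    for i, pol in enumerate(catalog):
        beliefs = update_state_beliefs(
            model, pol, observations, current_time, attenuation_flags
        )
        per_policy.append(beliefs)
        F[i] = compute_policy_free_energy(
            model, pol, beliefs, observations, current_time, attenuation_flags
        )
        G[i] = compute_expected_free_energy(model, pol, beliefs, current_time)
        mask[i] = all(
            pol.actions[t] == executed_actions[t] for t in range(len(executed_actions))
        )
    q_pi = policy_posterior(F, G, model.gamma_log, mask)
    marginals = marginal_state_beliefs(per_policy, q_pi)
    ambiguity = {
        "auditory": likelihood_entropy(model.auditory_likelihood()),
        "proprioceptive": likelihood_entropy(model.proprioceptive_likelihood()),
    }
    return BeliefState(
        per_policy_states=per_policy,
        policy_post=q_pi,
        policy_free_energy=F,
        expected_free_energy=G,
        marginal_states=marginals,
        ambiguity=ambiguity,
    )
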
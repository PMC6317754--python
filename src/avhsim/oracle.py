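"""Brute-force exact inference used to validate the variational engine.

Enumerates every hidden-state trajectory under a policy, scores it with
D x prod(B) x prod(A on observed steps), and normalizes. Small instances
only — the point is correctness, not speed. The same probability floor as
the engine is applied before logs so comparisons are apples-to-apples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .engine import _likelihood, _outcome_index, _softmax
from .model import LOG_FLOOR_EPS, GenerativeModel, Observation, Policy

__all__ = ["EnumerationResult", "exact_state_posterior", "exact_policy_posterior"]

_FACTOR_MODALITY = {"auditory": "auditory", "speech": "proprioceptive"}

MAX_SEQUENCES = 10**5


@dataclass
class EnumerationResult:
    """Exact joint, per-step marginals and log evidence for one policy."""

    joint: dict[str, np.ndarray]  # factor -> (2, 2, ..., 2) over trajectories
    marginals: dict[str, np.ndarray]  # factor -> (T, 2)
    log_evidence: float  # summed over factors/modalities


def exact_state_posterior(
    model: GenerativeModel,
    policy: Policy,
    observations: list[Observation],
    attenuation_flags: list[bool] | None = None,
) -> EnumerationResult:
    """Exact smoothing posterior over state trajectories given a policy.

    The two factors are independent chains, so each is enumerated
    separately; the trial log evidence is the sum of the per-factor log
    evidences.
    """
    T = model.n_steps
    n_obs = len(observations)
    if 2 ** T > MAX_SEQUENCES:
        raise ValueError(
            f"state-sequence count 2^{T} exceeds the enumeration cap {MAX_SEQUENCES}"
        )
    if attenuation_flags is None:
        attenuation_flags = [False] * n_obs

    joint: dict[str, np.ndarray] = {}
    marginals: dict[str, np.ndarray] = {}
    log_evidence = 0.0
    floor = lambda m: np.maximum(np.asarray(m, dtype=float), LOG_FLOOR_EPS)
    for f, modality in _FACTOR_MODALITY.items():
        D = floor(model.initial_beliefs[f])
        B = [
            floor(model.transition_model[policy.actions[t]][f])
            for t in range(T - 1)
        ]
        weights = np.zeros((2,) * T)
        for traj in itertools.product(range(2), repeat=T):
            w = D[traj[0]]
            for t in range(1, T):
                w *= B[t - 1][traj[t], traj[t - 1]]
            for tau in range(n_obs):
                A = floor(_likelihood(model, modality, attenuation_flags[tau]))
                o = _outcome_index(observations[tau], modality)
                w *= A[o, traj[tau]]
            weights[traj] = w
        evidence = weights.sum()
        log_evidence += float(np.log(evidence))
        post = weights / evidence
        joint[f] = post
        marg = np.zeros((T, 2))
        for t in range(T):
            axes = tuple(i for i in range(T) if i != t)
            marg[t] = post.sum(axis=axes)
        marginals[f] = marg
    return EnumerationResult(joint=joint, marginals=marginals, log_evidence=log_evidence)


def exact_policy_posterior(
    model: GenerativeModel,
    observations: list[Observation],
    gamma_log: float,
    attenuation_flags: list[bool] | None = None,
    consistency_mask: np.ndarray | None = None,
    G_vector: np.ndarray | None = None,
) -> np.ndarray:
    """Policy posterior built from exact log evidences in place of -F.

    Applies the same masking and gamma-sharpened softmax as the engine;
    ``G_vector`` defaults to zeros (pure evidence comparison).
    """
    catalog = model.policy_catalog
    n = len(catalog)
    mask = (
        np.ones(n, dtype=bool)
        if consistency_mask is None
        else np.asarray(consistency_mask, dtype=bool)
    )
    if not mask.any():
        raise ValueError("all policies masked")
    G = np.zeros(n) if G_vector is None else np.asarray(G_vector, dtype=float)
    logev = np.array(
        [
            exact_state_posterior(model, pol, observations, attenuation_flags).log_evidence
            for pol in catalog
        ]
    )
    gamma = float(np.exp(gamma_log))
    q = np.zeros(n)
    q[mask] = _softmax(gamma * (logev[mask] - G[mask]))
    return q
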
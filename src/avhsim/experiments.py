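"""Trial loop, hallucination scoring, and the three precision experiments.

A trial couples the agent to the scripted conversational environment for T
steps: observe, update beliefs under every policy, score policies, average,
act. A hallucination is flagged when the agent's marginal belief that a
voice is present exceeds threshold at a step whose true outcome is silence
(and the agent did not just generate the sound itself); the mirror-image
speech-detection error (false negative) is belief in "no voice" while sound
is truly present.

Experiments:

* ``fig4_zeta_sweep`` — lower the auditory likelihood precision zeta through
  {0.7, 0.525, 0.3} on a vulnerable 4-policy catalog.
* ``fig5_gamma`` — cross zeta in {0.7, 0.525} with low/high policy precision
  gamma on the same catalog.
* ``fig6_lesion`` — compare a 6-policy catalog with a "lesioned" 5-policy
  catalog (the best-explaining policy removed) across the zeta sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import environment as env
from .engine import BeliefState, infer, select_action
from .model import GenerativeModel, Observation, Policy, validate_model

__all__ = [
    "TrialRecord",
    "PolicyCatalogFixture",
    "FIXTURES",
    "ZETA_LEVELS",
    "GAMMA_PRESETS",
    "run_trial",
    "detect_hallucinations",
    "detect_false_negatives",
    "run_experiment",
    "summary_table",
]

logger = logging.getLogger(__name__)

#: zeta levels of the precision sweeps: baseline, moderately reduced, low
ZETA_LEVELS = (0.7, 0.525, 0.3)

#: log-gamma presets: near-zero vs. strongly dominant policy precision
GAMMA_PRESETS = {"low_gamma": -4.0, "high_gamma": 4.0, "baseline": 0.0}

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class PolicyCatalogFixture:
    """A named, ordered policy catalog."""

    name: str
    policies: tuple[Policy, ...]

    @classmethod
    def from_strings(cls, name: str, codes: list[str]) -> "PolicyCatalogFixture":
        return cls(name, tuple(Policy.from_string(c) for c in codes))


#: Reconstructed policy catalogs over 4 transitions (L = listen, S = speak).
#: "f4" is the vulnerable space of the precision sweeps: its only policy
#: that takes speaking turns (SLSL) prescribes listening into both silent
#: steps, so the turn-taking expectation of a voice falls exactly on steps
#: 3 and 5. "f6_full" is the 6-policy conversational repertoire, whose
#: best explanation of the scripted exchange (LLSS: listen through the
#: partner's turn, then take one's own) covers the silent steps with the
#: agent's own speech. "f6_lesioned" deletes that originally-inferred
#: policy, leaving exactly two plausible policies that allow speaking at
#: the second step but not the third (SLLS, SLSL) — both of which commit
#: the agent to expecting a voice at the silent third step.
FIXTURES: dict[str, PolicyCatalogFixture] = {
    "f4": PolicyCatalogFixture.from_strings("f4", ["SLSL", "LLLL", "LSLL", "LLSL"]),
    "f6_full": PolicyCatalogFixture.from_strings(
        "f6_full", ["LLLL", "LLSS", "SLLS", "SSLL", "SLSL", "LSLS"]
    ),
    "f6_lesioned": PolicyCatalogFixture.from_strings(
        "f6_lesioned", ["LLLL", "SLLS", "SSLL", "SLSL", "LSLS"]
    ),
}


@dataclass
class TrialRecord:
    """Complete log of one simulated trial."""

    config: dict
    observations: list[Observation]
    executed_actions: list[str]
    attenuation_flags: list[bool]
    marginal_states: list[dict[str, np.ndarray]]  # per tau: factor -> (T, 2)
    policy_posteriors: list[np.ndarray]  # per tau
    policy_catalog: list[Policy]
    belief_states: list[BeliefState] = field(default_factory=list, repr=False)
    hallucination_steps: list[int] = field(default_factory=list)
    false_negative_steps: list[int] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.observations)

    def final_marginals(self) -> dict[str, np.ndarray]:
        """Marginal state beliefs over the whole trial as seen at the last
        step (the quantity plotted as a belief raster)."""
        return self.marginal_states[-1]


def detect_hallucinations(
    record: TrialRecord, threshold: float = DEFAULT_THRESHOLD
) -> list[int]:
    """Steps (1-based) where the agent believes in a voice during true
    silence it did not itself break.

    Flags tau where the final marginal auditory belief in "voice present"
    strictly exceeds ``threshold``, the true auditory outcome at tau is
    silence, and the executed action into tau was not "speak".
    """
    if not (0.5 <= threshold < 1.0):
        raise ValueError(f"threshold must lie in [0.5, 1), got {threshold}")
    voice_belief = record.final_marginals()["auditory"][:, 0]
    out = []
    for tau in range(1, record.n_steps + 1):
        spoke_into = tau > 1 and record.executed_actions[tau - 2] == "speak"
        if (
            voice_belief[tau - 1] > threshold
            and record.observations[tau - 1].auditory == "silence"
            and not spoke_into
        ):
            out.append(tau)
    return out


def detect_false_negatives(
    record: TrialRecord,
    threshold: float = DEFAULT_THRESHOLD,
    include_self_generated: bool = True,
) -> list[int]:
    """Speech-detection errors: belief in "no voice" while sound is present.

    Self-generated sound steps are included by default — an agent that stops
    hearing its own voice while speaking is a reported failure mode, enabled
    by sensory attenuation.
    """
    if not (0.5 <= threshold < 1.0):
        raise ValueError(f"threshold must lie in [0.5, 1), got {threshold}")
    no_voice_belief = record.final_marginals()["auditory"][:, 1]
    out = []
    for tau in range(1, record.n_steps + 1):
        spoke_into = tau > 1 and record.executed_actions[tau - 2] == "speak"
        if no_voice_belief[tau - 1] > threshold and record.observations[
            tau - 1
        ].auditory == "sound":
            if include_self_generated or not spoke_into:
                out.append(tau)
    return out


def run_trial(
    model: GenerativeModel,
    script: env.EnvironmentScript | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    tie_break_seed: int = 0,
) -> TrialRecord:
    """Run one full perception-action trial and score it.

    Per step: the environment emits an observation (with the attenuation
    flag), the engine updates per-policy beliefs, free energies, the policy
    posterior and the marginal percept; before the last step the next
    action is selected from the policy posterior and executed.
    """
    violations = validate_model(model)
    if violations:
        raise ValueError("invalid model: " + "; ".join(violations))
    if script is None:
        base = ("silence", "sound") * model.n_steps
        script = env.EnvironmentScript(base[: model.n_steps])
    if script.n_steps != model.n_steps:
        raise ValueError(
            f"script length {script.n_steps} != model horizon {model.n_steps}"
        )

    observations: list[Observation] = []
    attenuation: list[bool] = []
    executed: list[str] = []
    marginals_log: list[dict[str, np.ndarray]] = []
    posteriors_log: list[np.ndarray] = []
    states_log: list[BeliefState] = []

    for tau in range(1, model.n_steps + 1):
        prev_action = executed[-1] if executed else None
        emitted = env.step(script, prev_action, tau)
        observations.append(emitted.observation)
        attenuation.append(emitted.attenuated)

        state = infer(model, observations, attenuation, executed, tau)
        states_log.append(state)
        marginals_log.append(state.marginal_states)
        posteriors_log.append(state.policy_post)
        ent = -float(
            np.sum(state.policy_post * np.log(np.maximum(state.policy_post, 1e-16)))
        )
        if tau < model.n_steps:
            action = select_action(
                state.policy_post, model.policy_catalog, tau, tie_break_seed
            )
            executed.append(action)
            logger.info(
                "tau=%d action=%s policy-entropy=%.3f", tau, action, ent
            )
        else:
            logger.info("tau=%d (final) policy-entropy=%.3f", tau, ent)

    record = TrialRecord(
        config={
            "n_steps": model.n_steps,
            "zeta": model.zeta,
            "gamma_log": model.gamma_log,
            "kappa": model.auditory_likelihood_base,
            "script": script.to_string(),
            "catalog": [p.to_string() for p in model.policy_catalog],
            "threshold": threshold,
            "tie_break_seed": tie_break_seed,
        },
        observations=observations,
        executed_actions=executed,
        attenuation_flags=attenuation,
        marginal_states=marginals_log,
        policy_posteriors=posteriors_log,
        policy_catalog=list(model.policy_catalog),
        belief_states=states_log,
    )
    record.hallucination_steps = detect_hallucinations(record, threshold)
    record.false_negative_steps = detect_false_negatives(record, threshold)
    return record


def _make_model(
    fixture: PolicyCatalogFixture, zeta: float, gamma_log: float, **overrides
) -> GenerativeModel:
    return GenerativeModel(
        zeta=zeta,
        gamma_log=gamma_log,
        policy_catalog=list(fixture.policies),
        **overrides,
    )


def run_experiment(
    name: str, overrides: dict | None = None
) -> dict[tuple, TrialRecord]:
    """Run one preset experiment; returns records keyed by condition tuples.

    Keys are (catalog_name, zeta, gamma_log). ``overrides`` may replace
    ``script`` (an EnvironmentScript), ``threshold``, or any
    GenerativeModel field passed through to every condition.
    """
    overrides = dict(overrides or {})
    script = overrides.pop("script", env.EnvironmentScript())
    threshold = overrides.pop("threshold", DEFAULT_THRESHOLD)

    conditions: list[tuple[str, float, float]] = []
    if name == "fig4_zeta_sweep":
        conditions = [("f4", z, GAMMA_PRESETS["baseline"]) for z in ZETA_LEVELS]
    elif name == "fig5_gamma":
        conditions = [
            ("f4", z, GAMMA_PRESETS[g])
            for z in (0.7, 0.525)
            for g in ("low_gamma", "high_gamma")
        ]
    elif name == "fig6_lesion":
        conditions = [
            (cat, z, GAMMA_PRESETS["baseline"])
            for cat in ("f6_full", "f6_lesioned")
            for z in ZETA_LEVELS
        ]
    else:
        raise ValueError(
            f"unknown experiment {name!r}; valid: "
            "fig4_zeta_sweep, fig5_gamma, fig6_lesion"
        )

    out: dict[tuple, TrialRecord] = {}
    for cat, zeta, gamma_log in conditions:
        model = _make_model(FIXTURES[cat], zeta, gamma_log, **overrides)
        out[(cat, zeta, gamma_log)] = run_trial(model, script, threshold)
    return out


def summary_table(records: dict[tuple, TrialRecord], experiment: str) -> pd.DataFrame:
    """Flat summary of an experiment's hallucination / false-negative steps."""
    rows = []
    for (cat, zeta, gamma_log), rec in records.items():
        rows.append(
            {
                "experiment": experiment,
                "condition": f"{cat}/zeta={zeta}/gamma_log={gamma_log}",
                "zeta": zeta,
                "gamma_log": gamma_log,
                "catalog": cat,
                "hallucination_steps": " ".join(map(str, rec.hallucination_steps)),
                "false_negative_steps": " ".join(map(str, rec.false_negative_steps)),
            }
        )
    return pd.DataFrame(rows)
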
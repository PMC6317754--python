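"""Discrete generative model of a conversing agent.

The agent entertains two binary hidden-state factors — whether a voice is
present in the environment (auditory factor) and whether it is itself
speaking (speech factor) — each mapped to a binary outcome modality:
hearing sound vs. silence, and sensing speech movements vs. none.

The fidelity of the auditory state→outcome mapping is governed by a
likelihood precision ``zeta``: the likelihood matrix is the column-normalized
elementwise power ``(I + kappa) ** zeta``, which interpolates between the
uniform matrix (``zeta = 0``) and the identity (``zeta`` large). While the
agent speaks, this mapping is replaced by the uniform matrix outright —
sensory attenuation, protecting the intention to speak from contradictory
auditory evidence.

Index convention (everywhere in the package): index 0 is the "positive"
state/outcome (voice present / sound / speaking / speech movement) and
index 1 its negation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


import numpy as np

__all__ = [
    "ACTIONS",
    "LOG_FLOOR_EPS",
    "DEFAULT_KAPPA",
    "Policy",
    "Observation",
    "GenerativeModel",
    "build_auditory_likelihood",
    "build_proprioceptive_likelihood",
    "build_transition",
    "validate_model",
    "default_model",
]

#: Valid action labels. Actions are oppositional: listening is itself an
#: action (orienting, attending) incompatible with talking.
ACTIONS = ("listen", "speak")

#: Probabilities are floored at this value before any logarithm is taken,
#: making one-hot columns behave like delta distributions at working
#: precision without producing -inf.
LOG_FLOOR_EPS = float(np.exp(-16.0))

#: Default imprecision constant kappa of the auditory likelihood family.
DEFAULT_KAPPA = float(np.exp(-3.0))

# state / outcome label tables, index 0 = positive
AUDITORY_STATES = ("voice", "no_voice")
SPEECH_STATES = ("speaking", "not_speaking")
AUDITORY_OUTCOMES = ("sound", "silence")
PROPRIO_OUTCOMES = ("speech_movement", "none")

FACTORS = ("auditory", "speech")


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class InvalidActionError(ValueError):
    """An action label outside {'listen', 'speak'} was supplied."""


@dataclass(frozen=True)
class Policy:
    """A fixed sequence of actions over the trial's transitions.

    A trial of ``T`` time steps has ``T - 1`` transitions, so a policy holds
    ``T - 1`` action labels. Policies are hypotheses the agent infers, not
    just plans it executes.
    """

    actions: tuple[str, ...]

    def __post_init__(self) -> None:
        for a in self.actions:
            if a not in ACTIONS:
                raise InvalidActionError(f"unknown action label {a!r}")

    @classmethod
    def from_string(cls, code: str) -> "Policy":
        """Build a policy from a compact string over {'L', 'S'}, e.g. ``"SLSL"``."""
        table = {"L": "listen", "S": "speak"}
        try:
            return cls(tuple(table[c] for c in code.upper()))
        except KeyError as exc:
            raise InvalidActionError(f"unknown policy letter {exc.args[0]!r}") from exc

    def to_string(self) -> str:
        return "".join("L" if a == "listen" else "S" for a in self.actions)

    def __len__(self) -> int:
        return len(self.actions)


@dataclass(frozen=True)
class Observation:
    """One time step's outcome pair: auditory and proprioceptive labels."""

    auditory: str
    proprioceptive: str

    def __post_init__(self) -> None:
        if self.auditory not in AUDITORY_OUTCOMES:
            raise InvalidParameterError(f"unknown auditory outcome {self.auditory!r}")
        if self.proprioceptive not in PROPRIO_OUTCOMES:
            raise InvalidParameterError(
                f"unknown proprioceptive outcome {self.proprioceptive!r}"
            )

    @property
    def auditory_index(self) -> int:
        return AUDITORY_OUTCOMES.index(self.auditory)

    @property
    def proprioceptive_index(self) -> int:
        return PROPRIO_OUTCOMES.index(self.proprioceptive)


def build_auditory_likelihood(
    zeta: float, base: float = DEFAULT_KAPPA, attenuated: bool = False
) -> np.ndarray:
    """Auditory likelihood matrix ``P(o_a | s_a)`` under precision ``zeta``.

    Columns index the hidden auditory state, rows the outcome. The matrix is
    the column-normalized elementwise power ``(I + base) ** zeta``: diagonal
    entries ``(1 + base)**zeta / Z`` and off-diagonal ``base**zeta / Z``.
    ``zeta = 0`` yields the uniform matrix; large ``zeta`` approaches the
    identity. If ``attenuated`` (the agent is speaking), the uniform matrix
    is returned regardless of ``zeta``.
    """
    if attenuated:
        return np.full((2, 2), 0.5)
    if not np.isfinite(zeta) or zeta < 0:
        raise InvalidParameterError(f"zeta must be >= 0, got {zeta}")
    if not (0.0 < base <= 1.0):
        raise InvalidParameterError(f"base must lie in (0, 1], got {base}")
    raw = (np.eye(2) + base) ** zeta
    return raw / raw.sum(axis=0, keepdims=True)


def build_proprioceptive_likelihood() -> np.ndarray:
    """Proprioceptive likelihood: an identity mapping from speaking state
    to speech-movement outcome (flooring for logs happens in the engine)."""
    return np.eye(2)


#: While listening, the agent expects a voice already present to persist
#: with this probability ...
LISTEN_VOICE_PERSIST = 2.0 / 3.0
#: ... and a voice to onset out of silence with this probability (choosing
#: to listen embodies the expectation of being spoken to, strongest right
#: after one's own conversational turn).
LISTEN_VOICE_ONSET = 0.8


def build_transition(action: str) -> dict[str, np.ndarray]:
    """Per-factor transition matrices ``B(u)`` for one action.

    Speaking drives the speech factor to "speaking" and — because the
    oppositional actions make talking and listening mutually exclusive —
    drives the auditory factor to "no voice"; both deterministically
    (one-hot columns). Listening drives the speech factor to "not speaking"
    deterministically, but drives the auditory factor toward "voice
    present" only *softly*: choosing to listen embodies the expectation
    that there is something to hear, which is how beliefs about policies
    become prior beliefs about auditory states, yet the expectation must
    remain defeasible so that precise sensory evidence can correct it
    (a hard drive would pin the auditory belief regardless of input).
    The soft columns are ``LISTEN_VOICE_PERSIST`` (from a voice-present
    state) and ``LISTEN_VOICE_ONSET`` (from silence).
    """
    if action not in ACTIONS:
        raise InvalidActionError(f"unknown action label {action!r}")
    to_first = np.array([[1.0, 1.0], [0.0, 0.0]])  # every column -> index 0
    to_second = np.array([[0.0, 0.0], [1.0, 1.0]])  # every column -> index 1
    if action == "speak":
        return {"auditory": to_second.copy(), "speech": to_first.copy()}
    a, c = LISTEN_VOICE_PERSIST, LISTEN_VOICE_ONSET
    toward_voice = np.array([[a, c], [1.0 - a, 1.0 - c]])
    return {"auditory": toward_voice, "speech": to_second.copy()}


def _flat(n: int = 2) -> np.ndarray:
    return np.full(n, 1.0 / n)


@dataclass
class GenerativeModel:
    """The agent's full generative model: likelihood family, transitions,
    preferences C, initial beliefs D, policy catalog, and precisions.

    Parameters
    ----------
    n_steps:
        Trial horizon ``T``; observations arrive at tau = 1..T and actions
        occur on the T-1 transitions between them.
    auditory_likelihood_base:
        Imprecision constant kappa in (0, 1] of the likelihood family.
    zeta:
        Auditory likelihood precision (>= 0).
    gamma_log:
        Natural log of the policy precision gamma.
    preferences:
        Per-modality log-preference vectors over outcomes (flat by default,
        so policy value is purely epistemic).
    initial_beliefs:
        Per-factor distributions over initial states (uniform by default).
    """

    n_steps: int = 5
    auditory_likelihood_base: float = DEFAULT_KAPPA
    zeta: float = 0.7
    gamma_log: float = 0.0
    transition_model: dict[str, dict[str, np.ndarray]] = field(
        default_factory=lambda: {a: build_transition(a) for a in ACTIONS}
    )
    preferences: dict[str, np.ndarray] = field(
        default_factory=lambda: {
            "auditory": np.log(_flat()),
            "proprioceptive": np.log(_flat()),
        }
    )
    initial_beliefs: dict[str, np.ndarray] = field(
        default_factory=lambda: {"auditory": _flat(), "speech": _flat()}
    )
    policy_catalog: list[Policy] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.policy_catalog:
            # full turn-taking repertoire is supplied by experiments fixtures;
            # the bare default is the lone "always listen" policy
            self.policy_catalog = [Policy(("listen",) * (self.n_steps - 1))]

    # -- likelihood access -------------------------------------------------
    def auditory_likelihood(self, attenuated: bool = False) -> np.ndarray:
        return build_auditory_likelihood(
            self.zeta, self.auditory_likelihood_base, attenuated
        )

    def proprioceptive_likelihood(self) -> np.ndarray:
        return build_proprioceptive_likelihood()

    @property
    def gamma(self) -> float:
        return float(np.exp(self.gamma_log))

    def with_(self, **changes) -> "GenerativeModel":
        """Functional update (shares transition/preference arrays)."""
        return replace(self, **changes)


def validate_model(model: GenerativeModel) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    Returns an empty list iff the model is valid (violations are reported
    rather than raised so that configuration errors can be listed at once).
    """
    out: list[str] = []
    if model.n_steps < 1:
        out.append(f"n_steps: must be >= 1, got {model.n_steps}")
    if not (0.0 < model.auditory_likelihood_base <= 1.0):
        out.append(
            "auditory_likelihood_base: must lie in (0, 1], got "
            f"{model.auditory_likelihood_base}"
        )
    if not np.isfinite(model.zeta) or model.zeta < 0:
        out.append(f"zeta: must be a finite value >= 0, got {model.zeta}")
    for action, factors in model.transition_model.items():
        for factor, mat in factors.items():
            mat = np.asarray(mat)
            if mat.shape != (2, 2):
                out.append(f"transition_model[{action}][{factor}]: not 2x2")
                continue
            if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-10):
                out.append(
                    f"transition_model[{action}][{factor}]: columns do not sum to 1"
                )
    for factor, d in model.initial_beliefs.items():
        d = np.asarray(d)
        if d.shape != (2,) or not np.isclose(d.sum(), 1.0, atol=1e-10) or (d < 0).any():
            out.append(f"initial_beliefs[{factor}]: not a distribution over 2 states")
    if not model.policy_catalog:
        out.append("policy_catalog: must be nonempty")
    for i, pol in enumerate(model.policy_catalog):
        if len(pol) != model.n_steps - 1:
            out.append(
                f"policy_catalog[{i}] ({pol.to_string()!r}): has {len(pol)} actions, "
                f"expected n_steps - 1 = {model.n_steps - 1}"
            )
    return out


def default_model(**overrides) -> GenerativeModel:
    """Convenience constructor used by the experiments and the CLI."""
    return GenerativeModel(**overrides)
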
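"""The generative process: a scripted conversational partner.

The environment produces a fixed baseline of alternating sounds and
silences (the partner's speech). Whenever the agent itself speaks, that
overrides the baseline — speaking generates sound at the next time step and
attenuates the agent's auditory likelihood. The environment only ever
consults *executed actions*, never the agent's beliefs: the generative
process is distinct from the agent's generative model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Observation

__all__ = ["EnvironmentScript", "EnvironmentStep", "step", "DEFAULT_BASELINE"]

#: Baseline partner script over T = 5 steps: silences at steps 1, 3 and 5.
DEFAULT_BASELINE = ("silence", "sound", "silence", "sound", "silence")


@dataclass(frozen=True)
class EnvironmentScript:
    """A length-T baseline auditory sequence plus the speech-override rule."""

    baseline_sequence: tuple[str, ...] = DEFAULT_BASELINE
    speech_override: bool = True

    def __post_init__(self) -> None:
        for o in self.baseline_sequence:
            if o not in ("sound", "silence"):
                raise ValueError(f"unknown baseline outcome {o!r}")

    @property
    def n_steps(self) -> int:
        return len(self.baseline_sequence)

    @classmethod
    def from_string(cls, code: str, speech_override: bool = True) -> "EnvironmentScript":
        """Parse a compact script over {'-', 'x'} (silence / sound)."""
        table = {"-": "silence", "x": "sound"}
        try:
            seq = tuple(table[c] for c in code)
        except KeyError as exc:
            raise ValueError(f"unknown script character {exc.args[0]!r}") from exc
        return cls(seq, speech_override)

    def to_string(self) -> str:
        return "".join("x" if o == "sound" else "-" for o in self.baseline_sequence)


@dataclass(frozen=True)
class EnvironmentStep:
    """One emitted observation plus the attenuation flag for the engine."""

    observation: Observation
    attenuated: bool


def step(
    script: EnvironmentScript, executed_action: str | None, time: int
) -> EnvironmentStep:
    """Emit the observation for time step ``time`` (1-based).

    ``executed_action`` is the agent's action on the transition *into* this
    step (``None`` at time 1). Speaking forces a sound outcome (if the
    override is enabled), produces a speech-movement proprioceptive outcome,
    and flags sensory attenuation for the engine.
    """
    if not (1 <= time <= script.n_steps):
        raise ValueError(f"time {time} outside 1..{script.n_steps}")
    spoke = executed_action == "speak"
    if spoke and script.speech_override:
        auditory = "sound"
    else:
        auditory = script.baseline_sequence[time - 1]
    proprio = "speech_movement" if spoke else "none"
    return EnvironmentStep(Observation(auditory, proprio), attenuated=spoke)
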
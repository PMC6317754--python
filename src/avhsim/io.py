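"""Configuration files, trial-record serialization, and belief rasters.

Configs are YAML or JSON documents whose keys mirror the generative-model
fields; policy catalogs are written as strings over {"L", "S"} and
environment scripts as strings over {"-", "x"} (silence / sound). Trial
records round-trip through JSON with full float precision; CSV rasters are
printed with 6 decimals for human consumption.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .environment import EnvironmentScript
from .experiments import FIXTURES, TrialRecord
from .model import GenerativeModel, Observation, Policy

__all__ = [
    "load_config",
    "model_from_config",
    "script_from_config",
    "record_to_dict",
    "record_from_dict",
    "save_record",
    "load_record",
    "record_to_frames",
    "plot_belief_raster",
]


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def model_from_config(cfg: dict) -> GenerativeModel:
    """Build a GenerativeModel from config keys; unknown keys are rejected."""
    known = {
        "n_steps",
        "auditory_likelihood_base",
        "zeta",
        "gamma_log",
        "policy_catalog",
        "catalog",
    }
    extra = set(cfg) & {"script", "threshold", "seed", "experiment"}
    unknown = set(cfg) - known - extra
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    kwargs: dict[str, Any] = {
        k: cfg[k]
        for k in ("n_steps", "auditory_likelihood_base", "zeta", "gamma_log")
        if k in cfg
    }
    catalog = cfg.get("policy_catalog", cfg.get("catalog"))
    if isinstance(catalog, str):
        kwargs["policy_catalog"] = list(FIXTURES[catalog].policies)
    elif catalog is not None:
        kwargs["policy_catalog"] = [Policy.from_string(c) for c in catalog]
    return GenerativeModel(**kwargs)


def script_from_config(cfg: dict) -> EnvironmentScript | None:
    if "script" not in cfg:
        return None
    return EnvironmentScript.from_string(cfg["script"])


def record_to_dict(record: TrialRecord) -> dict:
    """JSON-ready dict; belief arrays kept at full float precision."""
    return {
        "config": record.config,
        "observations": [
            {"auditory": o.auditory, "proprioceptive": o.proprioceptive}
            for o in record.observations
        ],
        "executed_actions": list(record.executed_actions),
        "attenuation_flags": list(record.attenuation_flags),
        "marginal_states": [
            {f: m[f].tolist() for f in m} for m in record.marginal_states
        ],
        "policy_posteriors": [q.tolist() for q in record.policy_posteriors],
        "policy_catalog": [p.to_string() for p in record.policy_catalog],
        "hallucination_steps": list(record.hallucination_steps),
        "false_negative_steps": list(record.false_negative_steps),
    }


def record_from_dict(data: dict) -> TrialRecord:
    return TrialRecord(
        config=data["config"],
        observations=[
            Observation(o["auditory"], o["proprioceptive"])
            for o in data["observations"]
        ],
        executed_actions=list(data["executed_actions"]),
        attenuation_flags=list(data["attenuation_flags"]),
        marginal_states=[
            {f: np.asarray(m[f]) for f in m} for m in data["marginal_states"]
        ],
        policy_posteriors=[np.asarray(q) for q in data["policy_posteriors"]],
        policy_catalog=[Policy.from_string(c) for c in data["policy_catalog"]],
        hallucination_steps=list(data["hallucination_steps"]),
        false_negative_steps=list(data["false_negative_steps"]),
    )


def save_record(record: TrialRecord, path: str | Path) -> None:
    Path(path).write_text(json.dumps(record_to_dict(record), indent=2))


def load_record(path: str | Path) -> TrialRecord:
    return record_from_dict(json.loads(Path(path).read_text()))


def record_to_frames(record: TrialRecord) -> dict[str, pd.DataFrame]:
    """Tabulate the final marginal beliefs and the policy posteriors.

    Returns two frames keyed "beliefs" (rows = time steps, columns =
    states of both factors) and "policies" (rows = time steps, columns =
    policy strings; row tau holds the posterior computed at step tau).
    """
    final = record.final_marginals()
    T = record.n_steps
    beliefs = pd.DataFrame(
        {
            "voice": final["auditory"][:, 0],
            "no_voice": final["auditory"][:, 1],
            "speaking": final["speech"][:, 0],
            "not_speaking": final["speech"][:, 1],
        },
        index=pd.Index(range(1, T + 1), name="time"),
    )
    policies = pd.DataFrame(
        np.vstack(record.policy_posteriors),
        index=pd.Index(range(1, T + 1), name="time"),
        columns=[p.to_string() for p in record.policy_catalog],
    )
    return {"beliefs": beliefs, "policies": policies}


def plot_belief_raster(record: TrialRecord, path: str | Path) -> None:
    """Save a two-panel raster (dark = high probability) of the trial:
    marginal beliefs about the auditory state over time, plus the policy
    posterior per step, in the style of the experiment read-outs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frames = record_to_frames(record)
    T = record.n_steps
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(1.2 * T + 2, 5), height_ratios=[2, 3], constrained_layout=True
    )
    ax1.imshow(
        frames["beliefs"][["voice", "no_voice"]].T,
        cmap="Greys",
        vmin=0,
        vmax=1,
        aspect="auto",
    )
    ax1.set_yticks([0, 1], ["voice", "no voice"])
    ax1.set_xticks(range(T), [str(t) for t in range(1, T + 1)])
    ax1.set_title("marginal auditory beliefs")
    outcomes = [o.auditory for o in record.observations]
    for t, o in enumerate(outcomes):
        ax1.text(t, -0.9, "x" if o == "sound" else "-", ha="center")
    ax2.imshow(frames["policies"].T, cmap="Greys", vmin=0, vmax=1, aspect="auto")
    ax2.set_yticks(
        range(len(record.policy_catalog)),
        [p.to_string() for p in record.policy_catalog],
    )
    ax2.set_xticks(range(T), [str(t) for t in range(1, T + 1)])
    ax2.set_title("policy posterior per step")
    ax2.set_xlabel("time step")
    fig.savefig(path, dpi=120)
    plt.close(fig)
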
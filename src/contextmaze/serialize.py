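"""Map export and agent checkpointing.

Successor and convolved-reward maps export to tidy labelled frames (for
occupancy inspection or any plotting layer); a full inference agent —
maps, uncertainties, particle windows, beliefs and RNG state — round-trips
through a single ``.npz`` archive for checkpoint/resume and offline
analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .agents import AgentConfig, InferenceAgent
from .maze import MazeSpec

__all__ = ["feature_labels", "bank_to_frames", "save_agent", "load_agent"]


def feature_labels(spec: MazeSpec) -> list[str]:
    """Human-readable names for every feature dimension."""
    labels = [spec.state_name(s) for s in range(spec.n_locations)]
    labels += [f"cue_{name}" for name in spec.cue_names]
    labels += [f"distractor_{i + 1}" for i in range(spec.n_distractors)]
    return labels


def bank_to_frames(bank, spec: MazeSpec | None = None) -> dict[str, pd.DataFrame]:
    """Labelled dumps of every context's maps.

    Returns one frame per map family: successor maps are stacked with a
    ``context`` column (rows = predicted features, columns = observed
    features), convolved-reward and TD maps one row per context.
    """
    spec = spec if spec is not None else bank.spec
    labels = feature_labels(spec)
    loc_labels = labels[: spec.n_locations]
    sr_frames = []
    for z, smap in enumerate(bank.smaps):
        frame = pd.DataFrame(smap.M, index=labels, columns=labels)
        frame.insert(0, "context", z)
        sr_frames.append(frame)
    return {
        "successor": pd.concat(sr_frames) if sr_frames else pd.DataFrame(),
        "convolved_reward": pd.DataFrame(
            [c.C for c in bank.cmaps], columns=loc_labels
        ).rename_axis("context"),
        "td": pd.DataFrame([t.td for t in bank.tdmaps], columns=labels).rename_axis("context"),
    }


def save_agent(agent: InferenceAgent, path: str | Path) -> Path:
    """Write the agent's full state to a single npz archive."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {
        "particle_windows": agent.particles.windows,
        "z_star": np.array([agent.z_star]),
        "acting_post": agent.last_acting_post,
        "n_contexts": np.array([agent.bank.active_count]),
    }
    for z in range(agent.bank.active_count):
        arrays[f"M_{z}"] = agent.bank.smaps[z].M
        arrays[f"M_var_{z}"] = agent.bank.smaps[z].col_var
        arrays[f"C_{z}"] = agent.bank.cmaps[z].C
        arrays[f"C_var_{z}"] = agent.bank.cmaps[z].var
        arrays[f"C_kvar_{z}"] = agent.bank.cmaps[z].kvar
        arrays[f"TD_{z}"] = agent.bank.tdmaps[z].td
        arrays[f"TD_Sigma_{z}"] = agent.bank.tdmaps[z].kalman.Sigma
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(agent.cfg).items()}
    np.savez(
        path,
        config_json=np.array(repr(cfg)),
        rng_state=np.array(repr(agent.rng.bit_generator.state)),
        maze_config=np.array(repr(agent.spec.to_config())),
        **arrays,
    )
    return path


def load_agent(path: str | Path) -> InferenceAgent:
    """Rebuild an agent from :func:`save_agent` output."""
    import ast

    data = np.load(Path(path), allow_pickle=False)
    spec = MazeSpec.from_config(ast.literal_eval(str(data["maze_config"])))
    cfg_dict = ast.literal_eval(str(data["config_json"]))
    cfg_dict = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg_dict.items()
    }
    agent = InferenceAgent(spec, AgentConfig(**cfg_dict))
    agent.rng.bit_generator.state = ast.literal_eval(str(data["rng_state"]))
    agent.particles.windows = data["particle_windows"]
    for z in range(int(data["n_contexts"][0])):
        agent.bank.spawn()
        agent.bank.smaps[z].M = data[f"M_{z}"]
        agent.bank.smaps[z].col_var = data[f"M_var_{z}"]
        agent.bank.cmaps[z].C = data[f"C_{z}"]
        agent.bank.cmaps[z].var = data[f"C_var_{z}"]
        agent.bank.cmaps[z].kvar = data[f"C_kvar_{z}"]
        agent.bank.tdmaps[z].td = data[f"TD_{z}"]
        agent.bank.tdmaps[z].kalman.Sigma = data[f"TD_Sigma_{z}"]
    agent.z_star = int(data["z_star"][0])
    agent.last_acting_post = data["acting_post"]
    return agent
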
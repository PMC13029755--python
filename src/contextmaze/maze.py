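"""Discrete cued maze environments.

Three task geometries are supported, all built on the same T-shaped graph of
discrete locations: the cued T-maze (one predictive cue on the stem), the
delayed non-match-to-sample task (two cues presented in sequence on the
stem), and the structural (biconditional) discrimination task (ordered pairs
drawn from three cue identities).

Observations are feature vectors: a one-hot over locations followed by cue
features. Predictive cues are scaled relative to the location entries
(``cue_scale``); distractor cues share the same slot and scale but are
identical across trial types, which is what degrades the contextual
signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ACTIONS",
    "MazeSpec",
    "TrialType",
    "build_cued_tmaze",
    "build_sequence_task",
    "step",
    "observe",
    "reward",
    "legal_actions",
    "render_ascii",
]

#: Fixed action set. Indices into this tuple are used internally.
ACTIONS: tuple[str, ...] = ("up", "down", "left", "right")
UP, DOWN, LEFT, RIGHT = range(4)


@dataclass(frozen=True)
class TrialType:
    """One trial type: its cue presentation and which arm pays off."""

    id: str
    cue_sequence: tuple[str, ...]
    rewarded_side: str  # "left" | "right"


@dataclass
class MazeSpec:
    """Parametric description of a discrete maze task.

    States are integers ``0 .. n_locations-1`` in a fixed topological order:
    stem bottom to top (the junction is the last stem state), then the left
    arm from the junction outward, then the right arm. Feature indices
    ``[0, n_locations)`` are locations; cue features follow, predictive cues
    first, distractors last.
    """

    name: str
    stem_length: int
    arm_length: int
    cue_scale: float
    cue_names: tuple[str, ...]
    n_distractors: int
    trial_types: dict[str, TrialType]
    # trial_type id -> list of (location, cue_feature_index, scale)
    cue_slots: dict[str, list[tuple[int, int, float]]]
    # shared across trial types
    distractor_slots: list[tuple[int, int, float]]
    # trial_type id -> terminal state that pays reward
    reward_location: dict[str, int]
    stem_only_up: bool = False

    # Derived, filled in __post_init__.
    n_locations: int = field(init=False)
    n_cue_features: int = field(init=False)
    n_features: int = field(init=False)
    junction: int = field(init=False)
    left_end: int = field(init=False)
    right_end: int = field(init=False)
    terminal_states: frozenset[int] = field(init=False)
    start_state: int = 0

    def __post_init__(self) -> None:
        self.n_locations = self.stem_length + 2 * self.arm_length
        self.n_cue_features = len(self.cue_names) + self.n_distractors
        self.n_features = self.n_locations + self.n_cue_features
        self.junction = self.stem_length - 1
        self.left_end = self.stem_length + self.arm_length - 1
        self.right_end = self.stem_length + 2 * self.arm_length - 1
        self.terminal_states = frozenset({self.left_end, self.right_end})
        self._build_transitions()
        self._build_observations()

    # -- construction ----------------------------------------------------

    def _build_transitions(self) -> None:
        n = self.n_locations
        trans = np.tile(np.arange(n)[:, None], (1, len(ACTIONS)))
        junction = self.junction
        first_left = self.stem_length
        first_right = self.stem_length + self.arm_length
        # Stem: up/down along the corridor; junction branches left/right.
        for s in range(self.stem_length):
            if s < junction:
                trans[s, UP] = s + 1
            if s > 0:
                trans[s, DOWN] = s - 1
        trans[junction, LEFT] = first_left
        trans[junction, RIGHT] = first_right
        # Arms: "left"/"right" move outward along the matching arm,
        # the opposite action moves back toward the junction.
        for o in range(self.arm_length):
            s = first_left + o
            if o + 1 < self.arm_length:
                trans[s, LEFT] = s + 1
            trans[s, RIGHT] = first_left + o - 1 if o > 0 else junction
            s = first_right + o
            if o + 1 < self.arm_length:
                trans[s, RIGHT] = s + 1
            trans[s, LEFT] = first_right + o - 1 if o > 0 else junction
        # Terminal states absorb (transitions out of them are never taken).
        for t in self.terminal_states:
            trans[t, :] = t
        self.transition = trans

        legal: list[tuple[int, ...]] = []
        for s in range(n):
            if self.stem_only_up and s < junction:
                legal.append((UP,))
            elif self.stem_only_up and s == junction:
                legal.append((LEFT, RIGHT))
            else:
                legal.append(tuple(range(len(ACTIONS))))
        self.legal = tuple(legal)

    def _build_observations(self) -> None:
        n, d = self.n_locations, self.n_features
        loc_obs = np.zeros((n, d))
        loc_obs[np.arange(n), np.arange(n)] = 1.0
        self._loc_obs = loc_obs
        self._full_obs = {}
        self._reward_vec = {}
        for tt in self.trial_types:
            full = loc_obs.copy()
            for loc, feat, scale in self.cue_slots[tt]:
                full[loc, feat] = scale
            for loc, feat, scale in self.distractor_slots:
                full[loc, feat] = scale
            self._full_obs[tt] = full
            r = np.zeros(n)
            r[self.reward_location[tt]] = 1.0
            self._reward_vec[tt] = r

    # -- queries ----------------------------------------------------------

    def observe(self, state: int, trial_type: str, channel: str = "full") -> np.ndarray:
        """Observation vector at ``state`` under ``trial_type``.

        ``channel="full"`` is the feature-inference input (location one-hot
        plus any cue entries at this state); ``channel="location_only"`` is
        the outcome-inference input (the bare location one-hot, length
        ``n_locations``).
        """
        if channel == "full":
            return self._full_obs[trial_type][state]
        if channel == "location_only":
            return self._loc_obs[state, : self.n_locations]
        raise ValueError(f"unknown observation channel {channel!r}")

    def reward(self, state: int, trial_type: str) -> float:
        """1 at the rewarded arm end for this trial type, 0 elsewhere."""
        return float(self._reward_vec[trial_type][state])

    def step(self, state: int, action: int | str) -> int:
        """Transition target; moving into a wall returns the same state."""
        a = ACTIONS.index(action) if isinstance(action, str) else action
        return int(self.transition[state, a])

    def legal_actions(self, state: int) -> tuple[int, ...]:
        return self.legal[state]

    def is_terminal(self, state: int) -> bool:
        return state in self.terminal_states

    def state_name(self, state: int) -> str:
        return f"s{state + 1}"

    # -- serialisation -----------------------------------------------------

    def to_config(self) -> dict:
        """Plain-document description sufficient to rebuild the spec."""
        return {
            "name": self.name,
            "stem_length": self.stem_length,
            "arm_length": self.arm_length,
            "cue_scale": self.cue_scale,
            "n_distractors": self.n_distractors,
        }

    @staticmethod
    def from_config(cfg: dict) -> "MazeSpec":
        name = cfg["name"]
        if name == "cued_tmaze":
            return build_cued_tmaze(
                stem_length=cfg.get("stem_length", 3),
                n_distractors=cfg.get("n_distractors", 0),
                cue_scale=cfg.get("cue_scale", 4.0),
                arm_length=cfg.get("arm_length", 3),
            )
        return build_sequence_task(name, stem_length=cfg.get("stem_length", 4))


def build_cued_tmaze(
    stem_length: int = 3,
    n_distractors: int = 0,
    cue_scale: float = 4.0,
    arm_length: int = 3,
) -> MazeSpec:
    """Cued T-maze: one predictive cue at the second stem location.

    The baseline (``stem_length=3``, no distractors) has 9 locations and two
    cue features, so the start observation is ``[1,0,0,0,0,0,0,0,0,0,0]``.
    Increasing ``stem_length`` inserts featureless stem locations between the
    cue and the junction; each distractor appends one cue feature present in
    both trial types at the cue location.
    """
    if stem_length < 3:
        raise ValueError("stem_length must be >= 3 (cue and junction would collide)")
    if n_distractors < 0:
        raise ValueError("n_distractors must be >= 0")
    n_loc = stem_length + 2 * arm_length
    cue_loc = 1  # second stem location
    cue_names = ("cue_L", "cue_R")
    cue_slots = {
        "L": [(cue_loc, n_loc + 0, cue_scale)],
        "R": [(cue_loc, n_loc + 1, cue_scale)],
    }
    distractor_slots = [
        (cue_loc, n_loc + 2 + i, cue_scale) for i in range(n_distractors)
    ]
    left_end = stem_length + arm_length - 1
    right_end = stem_length + 2 * arm_length - 1
    trial_types = {
        "L": TrialType("L", ("cue_L",), "left"),
        "R": TrialType("R", ("cue_R",), "right"),
    }
    return MazeSpec(
        name="cued_tmaze",
        stem_length=stem_length,
        arm_length=arm_length,
        cue_scale=cue_scale,
        cue_names=cue_names,
        n_distractors=n_distractors,
        trial_types=trial_types,
        cue_slots=cue_slots,
        distractor_slots=distractor_slots,
        reward_location={"L": left_end, "R": right_end},
        stem_only_up=False,
    )


# Ordered cue pairs of the structural discrimination task and the arm each
# pair rewards. The cyclic pairs reward right; their reversals reward left.
STRUCTURAL_PAIRS: dict[str, str] = {
    "A-B": "right",
    "B-C": "right",
    "C-A": "right",
    "B-A": "left",
    "C-B": "left",
    "A-C": "left",
}


def build_sequence_task(task: str, stem_length: int = 4, arm_length: int = 3) -> MazeSpec:
    """Sequence tasks: two cues presented successively on the stem.

    ``task="nms"`` — delayed non-match to sample: two cue identities, four
    trial types; matching pairs (A-A, B-B) reward the right arm, non-matching
    pairs the left. Cues are scaled 2x.

    ``task="structural"`` — structural discrimination: three cue identities
    combined into six ordered pairs (no repeats); the meaning of the second
    cue depends on the first. Cues are scaled 4x.

    The two cue presentation locations are the second and third stem
    locations, and stem movement is restricted to ``up`` (the junction offers
    only ``left``/``right``) to mimic cues being presented to a head-fixed
    agent rather than visited.
    """
    if stem_length < 4:
        raise ValueError("sequence tasks need stem_length >= 4 (two cue slots before the junction)")
    n_loc = stem_length + 2 * arm_length
    cue_locs = (1, 2)
    if task == "nms":
        cue_names = ("A", "B")
        scale = 2.0
        pairs = {"A-A": "right", "B-B": "right", "A-B": "left", "B-A": "left"}
    elif task == "structural":
        cue_names = ("A", "B", "C")
        scale = 4.0
        pairs = dict(STRUCTURAL_PAIRS)
    else:
        raise ValueError(f"unknown sequence task {task!r}")
    feat = {name: n_loc + i for i, name in enumerate(cue_names)}
    trial_types = {}
    cue_slots = {}
    left_end = stem_length + arm_length - 1
    right_end = stem_length + 2 * arm_length - 1
    reward_location = {}
    for tt_id, side in pairs.items():
        c1, c2 = tt_id.split("-")
        trial_types[tt_id] = TrialType(tt_id, (c1, c2), side)
        cue_slots[tt_id] = [
            (cue_locs[0], feat[c1], scale),
            (cue_locs[1], feat[c2], scale),
        ]
        reward_location[tt_id] = right_end if side == "right" else left_end
    return MazeSpec(
        name=task,
        stem_length=stem_length,
        arm_length=arm_length,
        cue_scale=scale,
        cue_names=cue_names,
        n_distractors=0,
        trial_types=trial_types,
        cue_slots=cue_slots,
        distractor_slots=[],
        reward_location=reward_location,
        stem_only_up=True,
    )


# -- module-level functional surface --------------------------------------


def step(state: int, action: int | str, spec: MazeSpec) -> int:
    return spec.step(state, action)


def observe(state: int, trial_type: str, spec: MazeSpec, channel: str = "full") -> np.ndarray:
    return spec.observe(state, trial_type, channel)


def reward(state: int, trial_type: str, spec: MazeSpec) -> float:
    return spec.reward(state, trial_type)


def legal_actions(state: int, spec: MazeSpec) -> tuple[int, ...]:
    return spec.legal_actions(state)


def render_ascii(spec: MazeSpec) -> str:
    """ASCII sketch of the maze layout (arms horizontal, stem vertical)."""
    cue_locs = sorted({loc for slots in spec.cue_slots.values() for loc, _, _ in slots})
    arm_l = [spec.state_name(spec.stem_length + o) for o in range(spec.arm_length)]
    arm_r = [spec.state_name(spec.stem_length + spec.arm_length + o) for o in range(spec.arm_length)]
    lines = [" - ".join(reversed(arm_l)) + " - " + spec.state_name(spec.junction) + " - " + " - ".join(arm_r)]
    pad = " " * len(" - ".join(reversed(arm_l)) + " - ")
    for s in range(spec.junction - 1, -1, -1):
        tag = " *cue*" if s in cue_locs else ""
        lines.append(pad + spec.state_name(s) + tag)
    return "\n".join(lines)
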
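"""Generative model of the end-to-end T-maze (H-maze) task.

Each session interleaves three stimulation labels (baseline, peak-triggered,
trough-triggered) uniformly at random across trials.  The reward side is
balanced against choice bias: P(reward in left arm) equals the fraction of
right choices over the last 12 trials.  The mouse's choice model is
specified directly by per-trial-type accuracies — the four types cross the
previous outcome with whether the cue asks the animal to stay or switch
arms — plus an additive stimulation effect per (condition, label).  This is
the minimal model sufficient to reproduce the reported type-conditional
accuracies and stimulation deltas; it contains no latent strategy state.

Trial-type baselines default to the reported values: mice follow a
win-stay/lose-switch bias, so switch-after-error (82%) and stay-after-
reward (72%) trials are easy while switch-after-reward (32%) and
stay-after-error (40%) trials are hard.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_TYPES", "STIM_LABELS", "CONDITIONS", "Trial", "BehaviorParams",
    "assign_reward_side", "simulate_session", "simulate_cohort", "trials_to_frame",
]

TRIAL_TYPES = ("correct/switch", "correct/stay", "incorrect/switch", "incorrect/stay")
STIM_LABELS = ("baseline", "peak", "trough")
CONDITIONS = ("retrieval", "encoding")

DEFAULT_P_CORRECT = {
    "incorrect/switch": 0.82,
    "correct/stay": 0.72,
    "correct/switch": 0.32,
    "incorrect/stay": 0.40,
}

DEFAULT_OCCUPANCY_MEDIANS = {
    "retrieval": 1.5,          # 1-2 s crossing the central arm
    "encoding_inbound": 2.5,   # 2-3 s inbound in the sample arm
    "encoding_outbound": 6.5,  # 5-8 s outbound in the sample arm
    "reward_approach": 1.5,
}

OCCUPANCY_SEGMENTS = tuple(DEFAULT_OCCUPANCY_MEDIANS)


def _zero_effects() -> dict:
    return {c: {s: 0.0 for s in STIM_LABELS} for c in CONDITIONS}


@dataclass
class Trial:
    """One maze traversal."""

    mouse_id: str
    condition: str
    stim: str
    start_arm: str
    correct_arm: str
    choice: str
    correct: bool
    prev_correct: bool | None
    cue_relation: str | None   # stay/switch vs previous correct arm
    trial_type: str | None     # undefined on a session's first trial
    n_pulses: int
    occupancy: dict


@dataclass
class BehaviorParams:
    """Generative parameters for one session.

    ``stim_effect[condition][label]`` is added to the type baseline
    probability on trials with that label (clipped to [0, 1]); a nonzero
    "baseline" entry shifts a mouse's no-stimulation accuracy.  ``window``
    is the reward-side balancing memory (trials).
    """

    p_correct: dict = field(default_factory=lambda: dict(DEFAULT_P_CORRECT))
    stim_effect: dict = field(default_factory=_zero_effects)
    n_trials: int = 150
    p_stim: tuple = (1 / 3, 1 / 3, 1 / 3)
    window: int = 12
    seed: int = 0
    occupancy_medians: dict = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY_MEDIANS))
    occupancy_sigma: float = 0.35
    theta_freq: float = 8.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if set(self.p_correct) != set(TRIAL_TYPES):
            raise ValueError(f"p_correct must have keys {TRIAL_TYPES}")
        for v in self.p_correct.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("baseline probabilities must lie in [0, 1]")
        if abs(sum(self.p_stim) - 1.0) > 1e-9:
            raise ValueError("p_stim must sum to 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    def with_(self, **kwargs) -> "BehaviorParams":
        return replace(self, **kwargs)


def assign_reward_side(history) -> float:
    """P(reward in left arm) given the recent choice history.

    Equals the fraction of right-arm choices over the last ``window``
    (at most 12) trials, 0.5 when no history exists: a mouse biased toward
    one arm is increasingly cued to the other.
    """
    history = list(history)
    if not history:
        return 0.5
    recent = history[-12:]
    return sum(1 for c in recent if c == "R") / len(recent)


def _classify(prev_correct: bool | None, cue_relation: str | None) -> str | None:
    if prev_correct is None or cue_relation is None:
        return None
    return f"{'correct' if prev_correct else 'incorrect'}/{cue_relation}"


def simulate_session(params: BehaviorParams, condition: str,
                     mouse_id: str = "mouse1",
                     rng: np.random.Generator | None = None) -> list[Trial]:
    """Simulate one session of ``params.n_trials`` trials in one condition.

    The first trial has no defined type (no previous outcome); its choice
    is drawn at the mean of the type baselines.  Deterministic for a given
    (params, condition, mouse_id) when ``rng`` is seeded from params.seed.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    effects = params.stim_effect.get(condition, {})
    mean_base = float(np.mean(list(params.p_correct.values())))

    trials: list[Trial] = []
    choices: list[str] = []
    prev_correct: bool | None = None
    prev_correct_arm: str | None = None

    for i in range(params.n_trials):
        p_left = assign_reward_side(choices[-params.window:])
        correct_arm = "L" if rng.random() < p_left else "R"
        start_arm = correct_arm  # the barrier forces the matching sample arm
        stim = STIM_LABELS[rng.choice(3, p=params.p_stim)]

        if prev_correct_arm is None:
            cue_relation = None
        else:
            cue_relation = "stay" if correct_arm == prev_correct_arm else "switch"
        trial_type = _classify(prev_correct, cue_relation)

        base = params.p_correct[trial_type] if trial_type else mean_base
        p = float(np.clip(base + effects.get(stim, 0.0), 0.0, 1.0))
        correct = bool(rng.random() < p)
        choice = correct_arm if correct else ("L" if correct_arm == "R" else "R")

        occupancy = {
            seg: float(np.exp(np.log(med) + params.occupancy_sigma
                              * rng.standard_normal()))
            for seg, med in params.occupancy_medians.items()
        }
        if stim == "baseline":
            n_pulses = 0
        else:
            if condition == "retrieval":
                occ = occupancy["retrieval"]
            else:
                occ = occupancy["encoding_inbound"] + occupancy["encoding_outbound"]
            n_pulses = int(rng.poisson(occ * params.theta_freq))

        trials.append(Trial(mouse_id=mouse_id, condition=condition, stim=stim,
                            start_arm=start_arm, correct_arm=correct_arm,
                            choice=choice, correct=correct,
                            prev_correct=prev_correct, cue_relation=cue_relation,
                            trial_type=trial_type, n_pulses=n_pulses,
                            occupancy=occupancy))
        choices.append(choice)
        prev_correct = correct
        prev_correct_arm = correct_arm
    return trials


def trials_to_frame(trials) -> pd.DataFrame:
    """Flatten Trial records (occupancy as occ_* columns) into a DataFrame."""
    if isinstance(trials, pd.DataFrame):
        return trials
    rows = []
    for t in trials:
        row = {
            "mouse_id": t.mouse_id, "condition": t.condition, "stim": t.stim,
            "start_arm": t.start_arm, "correct_arm": t.correct_arm,
            "choice": t.choice, "correct": t.correct,
            "prev_correct": t.prev_correct, "cue_relation": t.cue_relation,
            "trial_type": t.trial_type, "n_pulses": t.n_pulses,
        }
        for seg in OCCUPANCY_SEGMENTS:
            row[f"occ_{seg}"] = t.occupancy.get(seg, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(base_params: BehaviorParams,
                    effects_by_mouse: dict | None = None,
                    conditions=CONDITIONS,
                    n_mice: int = 4,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate several mice in both conditions; returns one trial frame.

    ``effects_by_mouse`` maps mouse id to a stim_effect dict overriding the
    base parameters (a "baseline" entry models per-mouse baseline shifts).
    Per-session seeds are spawned from ``seed`` so mice are independent but
    the cohort is reproducible.
    """
    if seed is None:
        seed = base_params.seed
    mouse_ids = [f"mouse{i + 1}" for i in range(n_mice)]
    if effects_by_mouse is None:
        effects_by_mouse = {m: base_params.stim_effect for m in mouse_ids}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(mouse_ids) * len(conditions))
    frames = []
    k = 0
    for mouse in mouse_ids:
        params = base_params.with_(stim_effect=effects_by_mouse[mouse])
        for condition in conditions:
            rng = np.random.default_rng(children[k]); k += 1
            frames.append(trials_to_frame(
                simulate_session(params, condition, mouse_id=mouse, rng=rng)))
    return pd.concat(frames, ignore_index=True)
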
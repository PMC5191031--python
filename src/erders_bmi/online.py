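"""Simulated closed-loop control of a one-DOF elbow exoskeleton.

Each online session streams cued trials, decodes the feature-window EEG
with a pre-trained decoder and maps the predicted class to a binary
exoskeleton action (flexion/extension). The elbow angle is clamped to its
mechanical range and mirrored to a feedback display after every step. Motor
imagery is simulated as an attenuated motor execution (scaled ERD depth);
the "wearing the exoskeleton" scenario adds class-independent hand-area
contamination from the passive right-arm movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decoding import DecoderModel, MetricsReport, metrics_from_confusion
from .preprocessing import bandpass_notch, epoch
from .synthetic import (
    ConfigurationError,
    SynthConfig,
    TrialTimeline,
    generate_recording,
    scenario_config,
)

ACTIONS = ("flexion", "extension", "none")
DEFAULT_ACTION_MAP = {"left_hand": "flexion", "both_feet": "extension"}


@dataclass(frozen=True)
class ExoState:
    """Elbow angle (degrees) with its limits and the mirrored feedback bar."""

    elbow_angle: float = 0.0
    min_angle: float = 0.0
    max_angle: float = 120.0
    last_action: str = "none"
    feedback_angle: float = 0.0

    def __post_init__(self) -> None:
        if not self.min_angle <= self.elbow_angle <= self.max_angle:
            raise ValueError("angle outside limits")


def exo_step(state: ExoState, action: str, step_deg: float = 10.0) -> ExoState:
    """Apply one binary action; clamp at the range limits.

    Flexion increases the elbow angle, extension decreases it; the feedback
    angle always mirrors the elbow angle after the step.
    """
    if action not in ("flexion", "extension"):
        raise ValueError(f"invalid action {action!r}")
    delta = step_deg if action == "flexion" else -step_deg
    angle = float(np.clip(state.elbow_angle + delta, state.min_angle, state.max_angle))
    return replace(state, elbow_angle=angle, feedback_angle=angle, last_action=action)


@dataclass
class OnlineSessionConfig:
    """One simulated online-control session (60 actions by default)."""

    decoder: DecoderModel
    n_actions: int = 60
    scenario: str = "without_exo"
    motor_mode: str = "MI"
    synth: SynthConfig = field(default_factory=SynthConfig)
    timeline: TrialTimeline = field(default_factory=TrialTimeline)
    class_action_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ACTION_MAP)
    )
    band: tuple[float, float] = (8.0, 30.0)
    notch: float | None = 50.0
    step_deg: float = 10.0
    mi_depth_scale: float = 0.6
    wearing_contamination: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actions < 1:
            raise ConfigurationError("n_actions must be >= 1")
        if set(self.class_action_map) != set(self.synth.classes):
            raise ConfigurationError("class_action_map must cover every class")


def run_online_session(config: OnlineSessionConfig) -> tuple[MetricsReport, pd.DataFrame]:
    """Stream trials, decode, actuate, and score one online session.

    Returns the decoding metrics against the ground-truth cue labels and a
    time-stamped action log (one row per action: trial index, true and
    predicted class, action taken, resulting elbow angle).
    """
    decoder = config.decoder
    if not decoder.trained:
        raise RuntimeError("decoder is not trained")
    n_per_class = int(np.ceil(config.n_actions / len(config.synth.classes)))
    gen = scenario_config(
        replace(config.synth, n_trials_per_class=n_per_class),
        motor_mode=config.motor_mode,
        scenario=config.scenario,
        mi_depth_scale=config.mi_depth_scale,
        wearing_contamination=config.wearing_contamination,
    )
    if gen.channel_labels != decoder.csp.channel_labels:
        raise ValueError("generator montage does not match the decoder's channels")
    rec, events, _truth = generate_recording(gen, config.timeline, seed=config.seed)
    filtered = bandpass_notch(rec, band=config.band, notch=config.notch)
    epochs = epoch(filtered, events, window_s=(-3.0, 5.0))

    window = decoder.csp.window_s or config.timeline.feature_window_s
    sl = epochs.clock_slice(window)

    state = ExoState()
    rows = []
    cm = np.zeros((2, 2), dtype=int)
    n_actions = min(config.n_actions, epochs.n_trials)
    for i in range(n_actions):
        trial = epochs.data[i, :, sl.start : sl.stop]
        pred = str(decoder.predict(trial[None, :, :])[0])
        true = str(epochs.labels[i])
        action = config.class_action_map[pred]
        state = exo_step(state, action, step_deg=config.step_deg)
        cm[decoder.class_pair.index(true), decoder.class_pair.index(pred)] += 1
        rows.append(
            {
                "trial": i,
                "time_s": float(events.onsets[i] / rec.fs),
                "true_class": true,
                "predicted_class": pred,
                "action": action,
                "elbow_angle_deg": state.elbow_angle,
                "feedback_angle_deg": state.feedback_angle,
            }
        )
    report = metrics_from_confusion(cm, decoder.class_pair)
    return report, pd.DataFrame(rows)


def replay_action_log(log: pd.DataFrame, step_deg: float = 10.0) -> ExoState:
    """Reconstruct the final exoskeleton state by replaying a session log."""
    state = ExoState()
    for action in log["action"]:
        state = exo_step(state, action, step_deg=step_deg)
    return state
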
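"""End-to-end simulation studies used for validation and reporting.

Two canonical experiments mirror the study design:

* :func:`parameter_recovery` — offline decoder training on the left-hand vs
  both-feet paradigm (100 trials/class, 80/20 split, CSP m=2 + LDA) plus
  recovery of the injected C4 band-power modulation via the ERD/ERS%
  estimator.
* :func:`ordering_study` — for each seed, train ME- and MI-mode decoders
  and run the four online sessions (2 motor modes × 2 scenarios); report
  per-seed marginal means so the two main effects (ME > MI,
  without-exoskeleton > wearing) can be counted across seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .decoding import DecoderModel, SplitPlan, evaluate, split, train_decoder
from .erders import erds_timecourse, tf_map
from .online import OnlineSessionConfig, run_online_session
from .preprocessing import preprocess_pipeline
from .synthetic import SynthConfig, TrialTimeline, generate_recording, scenario_config

FEATURE_WINDOW = (4.0, 7.0)
PARADIGM = ("left_hand", "both_feet")


def _epochs_for(config: SynthConfig, timeline: TrialTimeline | None = None):
    rec, events, truth = generate_recording(config, timeline)
    epochs = preprocess_pipeline(rec, events)
    return epochs, truth


def train_offline_decoder(
    config: SynthConfig,
    kind: str = "LDA",
    train_fraction: float = 0.8,
    m: int = 2,
    seed: int | None = None,
) -> tuple[DecoderModel, "object"]:
    """Generate a session, split, and train a decoder; returns (model, report)."""
    epochs, _ = _epochs_for(config)
    data = epochs.data[:, :, epochs.clock_slice(FEATURE_WINDOW)][epochs.retained()]
    labels = epochs.labels[epochs.retained()]
    plan = SplitPlan(
        train_fraction=train_fraction, seed=config.seed if seed is None else seed
    )
    xtr, ytr, xte, yte = split(data, labels, plan)
    model = train_decoder(
        xtr, ytr, kind, plan, class_pair=tuple(config.classes), m=m, fs=epochs.fs,
        channel_labels=epochs.channel_labels, window_s=FEATURE_WINDOW,
    )
    report = evaluate(model, xte, yte)
    return model, report


def parameter_recovery(seed: int = 1, n_trials_per_class: int = 100) -> dict:
    """Offline accuracy and injected-modulation recovery at ERD depth 0.5.

    Returns test accuracy (%), the recovered left-hand C4 mu-band ERD/ERS%
    over the feature window, and the closed-form injected value
    ((1 - 0.5)**2 - 1) * 100 = -75%.
    """
    config = SynthConfig(
        classes=PARADIGM, n_trials_per_class=n_trials_per_class,
        erd_depth=0.5, seed=seed,
    )
    epochs, _ = _epochs_for(config)
    data = epochs.data[:, :, epochs.clock_slice(FEATURE_WINDOW)][epochs.retained()]
    labels = epochs.labels[epochs.retained()]
    plan = SplitPlan(train_fraction=0.8, seed=seed)
    xtr, ytr, xte, yte = split(data, labels, plan)
    model = train_decoder(
        xtr, ytr, "LDA", plan, class_pair=PARADIGM, m=2, fs=epochs.fs,
        channel_labels=epochs.channel_labels, window_s=FEATURE_WINDOW,
    )
    report = evaluate(model, xte, yte)

    series = erds_timecourse(
        tf_map(epochs, label="left_hand"), config.mu_band
    )
    task = (series.segment_times >= FEATURE_WINDOW[0]) & (
        series.segment_times < FEATURE_WINDOW[1]
    )
    c4 = epochs.channel_index("C4")
    recovered = float(series.percent[c4][task].mean())
    return {
        "test_accuracy_percent": report.accuracy,
        "n_test": report.n_test,
        "recovered_c4_erd_percent": recovered,
        "injected_c4_erd_percent": ((1.0 - config.erd_depth) ** 2 - 1.0) * 100.0,
        "report": report,
    }


def online_session_grid(seed: int, n_train_per_class: int = 50,
                        n_actions: int = 60) -> dict[tuple[str, str], float]:
    """Accuracies of the four online sessions (mode × scenario) for one seed.

    A separate decoder is trained per motor mode on uncontaminated data (as
    in the study, where online decoders came from the decoder-training
    phase), then tested in both scenarios.
    """
    accs: dict[tuple[str, str], float] = {}
    for mode in ("ME", "MI"):
        base = SynthConfig(
            classes=PARADIGM, n_trials_per_class=n_train_per_class, seed=seed
        )
        gen = scenario_config(base, motor_mode=mode, scenario="without_exo")
        model, _ = train_offline_decoder(gen)
        for scenario in ("without_exo", "wearing_exo"):
            session = OnlineSessionConfig(
                decoder=model, n_actions=n_actions, scenario=scenario,
                motor_mode=mode, synth=SynthConfig(classes=PARADIGM),
                seed=seed + 10_000,
            )
            report, _ = run_online_session(session)
            accs[(mode, scenario)] = report.accuracy
    return accs


def ordering_study(seeds, n_train_per_class: int = 50, n_actions: int = 60) -> dict:
    """Count seeds where each main effect holds on per-seed marginal means."""
    me_gt_mi = 0
    noexo_gt_exo = 0
    rows = []
    for seed in seeds:
        accs = online_session_grid(int(seed), n_train_per_class, n_actions)
        me = np.mean([accs[("ME", s)] for s in ("without_exo", "wearing_exo")])
        mi = np.mean([accs[("MI", s)] for s in ("without_exo", "wearing_exo")])
        noexo = np.mean([accs[(m, "without_exo")] for m in ("ME", "MI")])
        exo = np.mean([accs[(m, "wearing_exo")] for m in ("ME", "MI")])
        me_gt_mi += int(me > mi)
        noexo_gt_exo += int(noexo > exo)
        rows.append({"seed": int(seed), **{f"{m}_{s}": accs[(m, s)] for m, s in accs}})
    return {
        "n_seeds": len(list(seeds)),
        "me_gt_mi_seeds": me_gt_mi,
        "noexo_gt_exo_seeds": noexo_gt_exo,
        "sessions": rows,
    }
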
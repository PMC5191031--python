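"""Synthetic multichannel EEG with ground-truth ERD/ERS structure.

The generator emulates a cued motor task: each trial shows a warning cross
at second 2 and a cue at second 3 of a trial-internal clock, after which the
subject executes or imagines a movement until second 8. Narrowband mu
(~10-12 Hz) and beta (~20-24 Hz) oscillators sit at the hand areas C3/C4
and the foot area Cz; during the task window the oscillator amplitudes are
scaled per class — a contralateral power *decrease* (ERD) and
ipsilateral/antagonist-area power *increase* (ERS):

* ``left_hand``  - ERD at C4 (mu+beta), weak ERS at C3 (mu), foot-area ERS at Cz
* ``right_hand`` - mirror image of ``left_hand``
* ``both_feet``  - ERD at Cz (mu+beta), ERS at both C3 and C4 (mu)

Sources are mixed into the 28 channels by a Gaussian distance-decay matrix
(volume conduction), on top of 1/f background noise (per-channel plus a
common component). Optional blink-like artifacts and — for the
"wearing the exoskeleton" scenario — a class-independent hand-area amplitude
modulation during the task window (passive right-arm movement) complete the
model. Because the injected amplitude scaling ``a`` is known per trial, the
band-power modulation ``a**2 - 1`` is available as ground truth for every
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal.windows import hann

from .channels import CHANNELS_28, SOURCE_SITES, frontal_weights, mixing_matrix

VALID_CLASSES = ("left_hand", "right_hand", "both_feet")


class ConfigurationError(ValueError):
    """Invalid generator or filter configuration."""


class AliasingError(ConfigurationError):
    """Sampling rate too low for the requested oscillator bands."""


@dataclass(frozen=True)
class TrialTimeline:
    """Trial-internal clock (seconds): warning cross, cue, task window, pause.

    Second 0 is trial start; the cue appears at ``cue_s`` (3.0 s) and the
    task lasts until ``task_end_s`` (8.0 s). The ERD/ERS reference period is
    0-1 s (pre-warning rest) and decoding features come from seconds 4-7
    (1-4 s after the cue). The inter-trial pause is drawn uniformly from
    ``pause_range_s``.
    """

    warning_s: float = 2.0
    cue_s: float = 3.0
    task_end_s: float = 8.0
    pause_range_s: tuple[float, float] = (2.0, 5.0)
    reference_window_s: tuple[float, float] = (0.0, 1.0)
    feature_window_s: tuple[float, float] = (4.0, 7.0)

    def __post_init__(self) -> None:
        if not (0 <= self.warning_s < self.cue_s < self.task_end_s):
            raise ConfigurationError("require 0 <= warning < cue < task_end")
        if not (self.reference_window_s[0] < self.reference_window_s[1] <= self.cue_s):
            raise ConfigurationError("reference window must precede the cue")
        if not (
            self.cue_s <= self.feature_window_s[0] < self.feature_window_s[1] <= self.task_end_s
        ):
            raise ConfigurationError("feature window must lie inside the task window")
        if not (0 <= self.pause_range_s[0] <= self.pause_range_s[1]):
            raise ConfigurationError("invalid pause range")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic motor-task EEG generator.

    Amplitudes are in µV; ``erd_depth`` is the fractional amplitude
    reduction of the task-window oscillation at the class's ERD site (band
    power scales as ``(1 - erd_depth)**2``), ``ers_gain`` the fractional
    amplitude increase at its ERS sites. ``modulation_overrides`` may pin
    the factor of any (class, site, band) directly.
    """

    channel_labels: tuple[str, ...] = CHANNELS_28
    fs: float = 512.0
    classes: tuple[str, ...] = ("left_hand", "both_feet")
    n_trials_per_class: int = 60
    mu_band: tuple[float, float] = (10.0, 12.0)
    beta_band: tuple[float, float] = (20.0, 24.0)
    erd_depth: float = 0.5
    ers_gain: float = 0.4
    ipsilateral_ers_frac: float = 0.15
    foot_ers_frac: float = 0.5
    mu_amp_uv: float = 5.0
    beta_amp_uv: float = 2.5
    amp_jitter_sd: float = 0.3
    depth_jitter_sd: float = 0.4
    noise_rms_uv: float = 3.0
    common_noise_rms_uv: float = 1.5
    noise_exponent: float = 1.0
    mixing_spread: float = 0.5
    artifact_rate: float = 0.0
    passive_arm_contamination: float = 0.0
    beta_rebound_gain: float = 0.3
    include_beta_rebound: bool = True
    modulation_overrides: Mapping[tuple[str, str, str], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for band, name in ((self.mu_band, "mu_band"), (self.beta_band, "beta_band")):
            if band[0] >= band[1]:
                raise ConfigurationError(f"{name}: low edge must be below high edge")
        top = max(self.mu_band[1], self.beta_band[1])
        if self.fs <= 2.0 * top:
            raise AliasingError(f"fs={self.fs} too low for band edge {top} Hz")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigurationError("erd_depth must lie in [0, 1]")
        if self.ers_gain < 0:
            raise ConfigurationError("ers_gain must be >= 0")
        if self.n_trials_per_class < 1:
            raise ConfigurationError("n_trials_per_class must be >= 1")
        if not 0.0 <= self.passive_arm_contamination <= 1.0:
            raise ConfigurationError("passive_arm_contamination must lie in [0, 1]")
        unknown = set(self.classes) - set(VALID_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown classes: {sorted(unknown)}")
        for site in SOURCE_SITES:
            if site not in self.channel_labels:
                raise ConfigurationError(f"montage must contain source site {site}")


@dataclass
class EventList:
    """Cue events of a continuous recording."""

    onsets: np.ndarray  # sample indices, strictly increasing
    labels: list[str]
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        if len(self.onsets) != len(self.labels):
            raise ValueError("onsets and labels must have equal length")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class GroundTruth:
    """Per-trial injected structure for test assertions.

    ``modulation[i, s, b]`` is the amplitude factor applied to source site
    ``sites[s]``, band ``bands[b]`` during the task window of trial ``i``
    (includes any passive-arm contamination).
    """

    labels: list[str]
    trial_starts: np.ndarray
    cue_onsets: np.ndarray
    sites: tuple[str, ...]
    bands: tuple[str, ...]
    modulation: np.ndarray
    artifact_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "trial_starts": self.trial_starts.tolist(),
            "cue_onsets": self.cue_onsets.tolist(),
            "sites": list(self.sites),
            "bands": list(self.bands),
            "modulation": self.modulation.tolist(),
            "artifact_positions": self.artifact_positions.tolist(),
        }


def class_modulation(config: SynthConfig, label: str) -> dict[tuple[str, str], float]:
    """Amplitude factors per (source site, band) for one movement class."""
    d, g = config.erd_depth, config.ers_gain
    weak = 1.0 + config.ipsilateral_ers_frac * g
    foot = 1.0 + config.foot_ers_frac * g
    table: dict[tuple[str, str], float] = {
        (s, b): 1.0 for s in SOURCE_SITES for b in ("mu", "beta")
    }
    if label == "left_hand":
        table[("C4", "mu")] = 1.0 - d
        table[("C4", "beta")] = 1.0 - d
        table[("C3", "mu")] = weak
        table[("Cz", "mu")] = foot
    elif label == "right_hand":
        table[("C3", "mu")] = 1.0 - d
        table[("C3", "beta")] = 1.0 - d
        table[("C4", "mu")] = weak
        table[("Cz", "mu")] = foot
    elif label == "both_feet":
        table[("Cz", "mu")] = 1.0 - d
        table[("Cz", "beta")] = 1.0 - d
        table[("C3", "mu")] = 1.0 + g
        table[("C4", "mu")] = 1.0 + g
    else:
        raise ConfigurationError(f"unknown class {label!r}")
    if config.modulation_overrides:
        for (cls, site, band), factor in config.modulation_overrides.items():
            if cls == label:
                table[(site, band)] = factor
    return table


def _smooth_envelope(env: np.ndarray, fs: float, ramp_s: float = 0.1) -> np.ndarray:
    n = int(round(ramp_s * fs))
    if n < 3:
        return env
    k = hann(n)
    k /= k.sum()
    return np.convolve(np.pad(env, n, mode="edge"), k, mode="same")[n:-n]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                exponent: float, rms: float) -> np.ndarray:
    """1/f^exponent noise per row, scaled to a target RMS."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n, axis=-1)
    scale = rms / np.maximum(x.std(axis=-1, keepdims=True), 1e-30)
    return x * scale


def generate_recording(
    config: SynthConfig,
    timeline: TrialTimeline | None = None,
    seed: int | None = None,
    session_id: str = "synthetic",
):
    """Generate a continuous recording of concatenated cued motor trials.

    Returns ``(Recording, EventList, GroundTruth)``. Deterministic for an
    identical ``(config, seed)`` pair.
    """
    from .preprocessing import Recording  # local import to avoid a cycle

    timeline = timeline or TrialTimeline()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.fs
    n_ch = len(config.channel_labels)

    labels = [c for c in config.classes for _ in range(config.n_trials_per_class)]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    n_trials = len(labels)

    trial_len = int(round(timeline.task_end_s * fs))
    pauses = rng.uniform(*timeline.pause_range_s, size=n_trials)
    pause_len = np.round(pauses * fs).astype(int)
    block_len = trial_len + pause_len
    starts = np.concatenate([[0], np.cumsum(block_len[:-1])])
    total = int(starts[-1] + block_len[-1])

    cue = int(round(timeline.cue_s * fs))
    task_end = trial_len
    reb_start = int(round((timeline.task_end_s - 1.0) * fs))

    mix = mixing_matrix(config.channel_labels, SOURCE_SITES, config.mixing_spread)
    bands = {"mu": (config.mu_band, config.mu_amp_uv),
             "beta": (config.beta_band, config.beta_amp_uv)}
    band_names = tuple(bands)

    signal = np.zeros((n_ch, total))
    modulation = np.ones((n_trials, len(SOURCE_SITES), len(band_names)))

    for s_idx, site in enumerate(SOURCE_SITES):
        mix_col = mix[:, s_idx][:, None]
        for b_idx, bname in enumerate(band_names):
            (lo, hi), base_amp = bands[bname]
            for i in range(n_trials):
                n = block_len[i]
                factor = class_modulation(config, labels[i])[(site, bname)]
                if factor != 1.0 and config.depth_jitter_sd > 0:
                    # trial-to-trial modulation-strength variability
                    # (vigilance/effort); E[factor**2] is preserved so the
                    # trial-averaged band-power modulation stays (1-d)**2 - 1
                    s = config.depth_jitter_sd
                    factor *= np.exp(rng.normal(-s * s, s))
                modulation[i, s_idx, b_idx] = factor
                env = np.ones(n)
                env[cue:task_end] = factor
                if (
                    config.include_beta_rebound
                    and bname == "beta"
                    and factor < 1.0
                ):
                    # post-movement beta rebound in the last task second
                    env[reb_start:task_end] = 1.0 + config.beta_rebound_gain
                env = _smooth_envelope(env, fs)
                freq = rng.uniform(lo, hi)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                amp = base_amp * rng.lognormal(
                    mean=-0.5 * config.amp_jitter_sd**2, sigma=config.amp_jitter_sd
                )
                t = np.arange(n) / fs
                wave = amp * env * np.sin(2.0 * np.pi * freq * t + phase)
                a = starts[i]
                signal[:, a:a + n] += mix_col * wave[None, :]

    # Scenario 2: passive right-arm movement drives its own hand-area
    # oscillation during the task window, independent of the cued class.
    # Added power at C3/C4 pulls hand-class trials toward the feet-class
    # signature (whose hand area is synchronized), so misclassifications
    # concentrate on the left-hand class.
    c = config.passive_arm_contamination
    if c > 0:
        for s_idx, site in enumerate(SOURCE_SITES):
            if site not in ("C3", "C4"):
                continue
            mix_col = mix[:, s_idx][:, None]
            for bname in band_names:
                (lo, hi), base_amp = bands[bname]
                for i in range(n_trials):
                    n = block_len[i]
                    env = np.zeros(n)
                    env[cue:task_end] = 1.0
                    env = _smooth_envelope(env, fs)
                    freq = rng.uniform(lo, hi)
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    amp = c * base_amp * rng.lognormal(
                        mean=-0.5 * config.amp_jitter_sd**2,
                        sigma=config.amp_jitter_sd,
                    )
                    t = np.arange(n) / fs
                    wave = amp * env * np.sin(2.0 * np.pi * freq * t + phase)
                    a = starts[i]
                    signal[:, a : a + n] += mix_col * wave[None, :]

    signal += _pink_noise(rng, (n_ch, total), fs, config.noise_exponent, config.noise_rms_uv)
    if config.common_noise_rms_uv > 0:
        signal += _pink_noise(rng, (1, total), fs, config.noise_exponent,
                              config.common_noise_rms_uv)

    onsets = starts + cue
    events = EventList(onsets=onsets, labels=list(labels), session_id=session_id)
    truth = GroundTruth(
        labels=list(labels),
        trial_starts=starts.astype(np.int64),
        cue_onsets=onsets.astype(np.int64),
        sites=SOURCE_SITES,
        bands=band_names,
        modulation=modulation,
    )
    rec = Recording(
        signal=signal, fs=fs, channel_labels=tuple(config.channel_labels), annotations=events
    )
    if config.artifact_rate > 0:
        rec, positions = inject_artifacts(
            rec, config.artifact_rate, seed=int(rng.integers(2**31 - 1))
        )
        truth.artifact_positions = positions
    return rec, events, truth


def inject_artifacts(
    recording,
    rate: float,
    seed: int = 0,
    amplitude_factor: float = 25.0,
    min_amplitude_uv: float = 150.0,
    duration_s: float = 0.4,
):
    """Add blink-like low-frequency transients at random positions.

    ``rate`` is events per minute. Each transient is a monophasic Hann bump
    whose per-channel peak is ``amplitude_factor`` × that channel's
    pre-injection RMS (with an absolute floor of ``min_amplitude_uv``,
    matching the size of real ocular artifacts), strongest over the frontal
    row and decaying toward parietal channels. The default factor and floor
    keep the injected peak ≥ 5× the background RMS on every channel even
    after superposition with the ongoing EEG. Returns
    ``(new Recording, positions)`` where positions are start-sample indices
    of the injected segments.
    """
    from .preprocessing import Recording

    if rate < 0:
        raise ConfigurationError("artifact rate must be >= 0")
    signal = recording.signal.copy()
    n = signal.shape[1]
    positions = np.array([], dtype=np.int64)
    if rate > 0:
        rng = np.random.default_rng(seed)
        minutes = n / recording.fs / 60.0
        n_events = int(round(rate * minutes))
        seg = int(round(duration_s * recording.fs))
        if n_events > 0 and n > seg:
            positions = np.sort(rng.integers(0, n - seg, size=n_events)).astype(np.int64)
            bump = hann(seg)
            rms = signal.std(axis=1)
            weights = frontal_weights(recording.channel_labels)
            amp = np.maximum(amplitude_factor * rms, min_amplitude_uv) * weights
            for p in positions:
                signal[:, p:p + seg] += amp[:, None] * bump[None, :]
    out = Recording(
        signal=signal,
        fs=recording.fs,
        channel_labels=recording.channel_labels,
        annotations=recording.annotations,
    )
    return out, positions


def scenario_config(
    base: SynthConfig,
    motor_mode: str = "ME",
    scenario: str = "without_exo",
    mi_depth_scale: float = 0.6,
    wearing_contamination: float = 0.6,
) -> SynthConfig:
    """Derive a generator config for one online-control session.

    Motor imagery is simulated as an attenuated motor execution
    (``erd_depth`` scaled by ``mi_depth_scale``); wearing the exoskeleton
    adds the passive-arm hand-area contamination.
    """
    if motor_mode not in ("ME", "MI"):
        raise ConfigurationError("motor_mode must be 'ME' or 'MI'")
    if scenario not in ("without_exo", "wearing_exo"):
        raise ConfigurationError("scenario must be 'without_exo' or 'wearing_exo'")
    depth = base.erd_depth * (mi_depth_scale if motor_mode == "MI" else 1.0)
    contamination = wearing_contamination if scenario == "wearing_exo" else 0.0
    return replace(base, erd_depth=depth, passive_arm_contamination=contamination)
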
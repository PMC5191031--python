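"""ERD/ERS quantification: short-window FFT power maps and percent change.

Event-related desynchronization/synchronization is the percentage change of
band power relative to a pre-event reference period,

    ERD/ERS% = (A - R) / R * 100,

with A the band power in a post-event segment and R the mean band power of
the reference window (trial seconds 0-1 by default). Negative values are
ERD (power decrease), positive values ERS; the quantity is bounded below by
-100% because power is non-negative.

Time-frequency maps use non-overlapping 100 ms Hann-windowed FFT segments.
At 512 Hz a raw 100 ms segment gives ~10 Hz-wide bins, too coarse for 4 Hz
analysis bands, so segments are zero-padded to a 1 s equivalent length
before the FFT (1 Hz bin spacing) while keeping the 100 ms temporal grid.
Band power is the mean of bin powers whose centers fall inside
[low, high], both edges inclusive. Trial averaging happens on power, before
the percent transform (classical ERD methodology); a per-trial mode is
available via ``average=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .channels import SENSORIMOTOR_CHANNELS
from .preprocessing import EpochSet
from .synthetic import ConfigurationError


class DegenerateReferenceError(ZeroDivisionError):
    """Reference-window band power is (numerically) zero."""


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with its provenance (configured vs auto-selected)."""

    low: float
    high: float
    provenance: str = "configured"

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.high:
            raise ConfigurationError(f"invalid band ({self.low}, {self.high})")


@dataclass
class TFMap:
    """Per-segment FFT power: channels × frequencies × time segments (µV²).

    With ``average=False`` an extra leading trials axis is present.
    """

    power: np.ndarray
    freqs: np.ndarray
    segment_times: np.ndarray  # segment centers on the trial clock (s)
    segment_length_s: float
    channel_labels: tuple[str, ...]

    def band_power(self, band: BandSpec | tuple[float, float]) -> np.ndarray:
        """Mean bin power over band (inclusive edges): ... × channels × segments."""
        low, high = (band.low, band.high) if isinstance(band, BandSpec) else band
        keep = (self.freqs >= low) & (self.freqs <= high)
        if not keep.any():
            raise ConfigurationError(f"no FFT bins inside band ({low}, {high})")
        return self.power[..., keep, :].mean(axis=-2)


@dataclass
class ERDSeries:
    """ERD/ERS% time course: ... × channels × time segments."""

    percent: np.ndarray
    segment_times: np.ndarray
    reference_window_s: tuple[float, float]
    band: BandSpec
    channel_labels: tuple[str, ...]


def tf_map(
    epochs: EpochSet,
    freq_range: tuple[float, float] = (2.0, 40.0),
    label: str | None = None,
    segment_length_s: float = 0.1,
    min_resolution_hz: float = 1.0,
    average: bool = True,
) -> TFMap:
    """Non-overlapping Hann-windowed FFT power per 100 ms segment.

    Uses retained trials only; ``label`` restricts to one class. A trailing
    partial segment is truncated. ``average=True`` averages power across
    trials (the default, matching classical ERD estimation).
    """
    if not 0.0 <= freq_range[0] < freq_range[1] <= epochs.fs / 2.0:
        raise ConfigurationError(f"freq_range {freq_range} outside (0, Nyquist)")
    data, labels = epochs.retained_data()
    if label is not None:
        data = data[labels == label]
    if data.shape[0] == 0:
        raise ValueError("no retained trials to analyze")

    seg_len = int(round(segment_length_s * epochs.fs))
    n_seg = data.shape[2] // seg_len
    if n_seg < 1:
        raise ValueError("epoch shorter than one segment")
    nfft = max(seg_len, int(round(epochs.fs / min_resolution_hz)))

    x = data[:, :, : n_seg * seg_len].reshape(data.shape[0], data.shape[1], n_seg, seg_len)
    win = hann(seg_len)
    spec = np.fft.rfft(x * win, n=nfft, axis=-1)
    power = (spec.real**2 + spec.imag**2) / (win**2).sum()
    freqs = np.fft.rfftfreq(nfft, 1.0 / epochs.fs)
    keep = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    power = np.moveaxis(power[..., keep], -1, -2)  # trials × ch × freq × seg
    if average:
        power = power.mean(axis=0)
    times = epochs.trial_clock[0] + (np.arange(n_seg) + 0.5) * seg_len / epochs.fs
    return TFMap(
        power=power,
        freqs=freqs[keep],
        segment_times=times,
        segment_length_s=seg_len / epochs.fs,
        channel_labels=epochs.channel_labels,
    )


def erds_timecourse(
    tf: TFMap,
    band: BandSpec | tuple[float, float],
    reference_window_s: tuple[float, float] = (0.0, 1.0),
) -> ERDSeries:
    """Percent band-power change relative to the reference window.

    ``percent = (A - R) / R * 100`` per segment, with R the mean band power
    over reference segments (segment centers inside the window). Raises
    :class:`DegenerateReferenceError` when R vanishes instead of dividing.
    """
    if not isinstance(band, BandSpec):
        band = BandSpec(*band)
    bp = tf.band_power(band)  # ... × channels × segments
    ref = (tf.segment_times >= reference_window_s[0]) & (
        tf.segment_times < reference_window_s[1]
    )
    if not ref.any():
        raise ConfigurationError("reference window not covered by the segment grid")
    r = bp[..., ref].mean(axis=-1, keepdims=True)
    if np.any(r <= np.finfo(float).tiny * 1e3):
        raise DegenerateReferenceError("reference band power is zero")
    percent = (bp - r) / r * 100.0
    return ERDSeries(
        percent=percent,
        segment_times=tf.segment_times,
        reference_window_s=tuple(reference_window_s),
        band=band,
        channel_labels=tf.channel_labels,
    )


def select_band(
    epochs: EpochSet,
    candidate_bands: list[tuple[float, float]],
    window_s: tuple[float, float] = (4.0, 7.0),
    channels: tuple[str, ...] = SENSORIMOTOR_CHANNELS,
    configured: tuple[float, float] | BandSpec | None = None,
    reference_window_s: tuple[float, float] = (0.0, 1.0),
) -> BandSpec:
    """Choose the band with the strongest between-class ERD/ERS contrast.

    For each candidate the per-class mean ERD/ERS% over the feature window
    is computed at the sensorimotor channels; the score is the mean absolute
    between-class difference of those signed values across channels. Ties
    break deterministically to the lowest band. A ``configured`` band
    bypasses selection and is returned with provenance ``"configured"``.
    """
    if configured is not None:
        if isinstance(configured, BandSpec):
            return BandSpec(configured.low, configured.high, "configured")
        return BandSpec(configured[0], configured[1], "configured")
    if not candidate_bands:
        raise ConfigurationError("no candidate bands supplied")
    classes = sorted(set(epochs.labels[epochs.retained()]))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, found {classes}")
    ch_idx = [epochs.channel_index(c) for c in channels]
    top = max(b[1] for b in candidate_bands)
    # 0.5 s segments: 100 ms Hann windows have ±20 Hz mainlobes, which smear
    # one band's contrast into its neighbours; selection needs the finer
    # spectral (coarser temporal) trade-off
    maps = {
        c: tf_map(
            epochs,
            freq_range=(1.0, min(top + 2.0, epochs.fs / 2 - 1)),
            label=c,
            segment_length_s=0.5,
        )
        for c in classes
    }

    best: tuple[float, float, float] | None = None  # (-score, low, high)
    for low, high in candidate_bands:
        means = []
        for c in classes:
            series = erds_timecourse(maps[c], (low, high), reference_window_s)
            seg = (series.segment_times >= window_s[0]) & (series.segment_times < window_s[1])
            means.append(series.percent[ch_idx][:, seg].mean(axis=1))
        score = float(np.abs(means[0] - means[1]).mean())
        key = (-score, low, high)
        if best is None or key < best:
            best = key
    return BandSpec(best[1], best[2], "auto-selected")


def export_long_csv(series: ERDSeries, path) -> None:
    """ERD/ERS% time course as long-format CSV (channel, time, value)."""
    import pandas as pd

    rows = []
    for i, ch in enumerate(series.channel_labels):
        for j, t in enumerate(series.segment_times):
            rows.append((ch, float(t), float(series.percent[i, j])))
    pd.DataFrame(rows, columns=["channel", "time_s", "erd_ers_percent"]).to_csv(
        path, index=False
    )


def export_tf_csv(tf: TFMap, path) -> None:
    """Time-frequency power map as long-format CSV (channel, freq, time, value)."""
    import pandas as pd

    rows = []
    for i, ch in enumerate(tf.channel_labels):
        for j, f in enumerate(tf.freqs):
            for k, t in enumerate(tf.segment_times):
                rows.append((ch, float(f), float(t), float(tf.power[i, j, k])))
    pd.DataFrame(
        rows, columns=["channel", "freq_hz", "time_s", "power_uv2"]
    ).to_csv(path, index=False)


def plot_timecourse(series: ERDSeries, channels: tuple[str, ...], path) -> None:
    """Line plot of the ERD/ERS% time course for selected channels."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for ch in channels:
        i = series.channel_labels.index(ch)
        ax.plot(series.segment_times, series.percent[i], label=ch)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("trial time (s, cue at 3.0)")
    ax.set_ylabel(f"ERD/ERS% ({series.band.low:g}-{series.band.high:g} Hz)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_tf_map(tf: TFMap, channel: str, path) -> None:
    """Time-frequency power image for one channel."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    i = tf.channel_labels.index(channel)
    fig, ax = plt.subplots(figsize=(7, 4))
    mesh = ax.pcolormesh(tf.segment_times, tf.freqs, tf.power[i], shading="auto")
    ax.set_xlabel("trial time (s, cue at 3.0)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(channel)
    fig.colorbar(mesh, ax=ax, label="power (uV^2)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
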
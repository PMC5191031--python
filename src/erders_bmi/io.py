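"""Reading and writing recordings, events and ground truth.

Continuous signals go to EDF (16-bit European Data Format) via a minimal
writer; reading uses MNE's EDF/BDF reader, which also serves as the
independent round-trip check of the writer. Events travel in a CSV sidecar
(``onset_sample, label, session_id``) next to the signal file, and the
synthetic generator's ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import Recording
from .synthetic import EventList, GroundTruth


class LoadError(RuntimeError):
    """Unreadable file or mismatch with the expected montage."""


_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


def _pad_ascii(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_recording(path: str | Path, recording: Recording) -> Path:
    """Write a recording to EDF (one-second data records, 16-bit).

    The physical range is symmetric around zero and sized to the signal's
    absolute maximum, so quantization error is ``max|x| / 32767`` per
    sample. The sampling rate must be an integer (samples per 1 s record).
    The final partial record, if any, is zero-padded; readers may therefore
    return up to ``fs - 1`` trailing padding samples.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    sig = recording.signal
    n_ch, n_samp = sig.shape
    n_rec = int(np.ceil(n_samp / fs))
    pmax = float(np.max(np.abs(sig))) if sig.size else 1.0
    pmax = max(pmax, 1e-6)
    pmin = -pmax

    header = b"".join(
        [
            _pad_ascii("0", 8),
            _pad_ascii("X X X X", 80),
            _pad_ascii("Startdate 01-JAN-2000 X X X", 80),
            _pad_ascii("01.01.00", 8),
            _pad_ascii("00.00.00", 8),
            _pad_ascii(str(256 * (1 + n_ch)), 8),
            _pad_ascii("", 44),
            _pad_ascii(str(n_rec), 8),
            _pad_ascii("1", 8),
            _pad_ascii(str(n_ch), 4),
        ]
    )
    fields = [
        ("%-16s", [c[:16] for c in recording.channel_labels], 16),
        ("%s", ["" for _ in range(n_ch)], 80),  # transducer
        ("%s", ["uV" for _ in range(n_ch)], 8),
        ("%s", [f"{pmin:.6g}" for _ in range(n_ch)], 8),
        ("%s", [f"{pmax:.6g}" for _ in range(n_ch)], 8),
        ("%s", [str(_EDF_DIG_MIN) for _ in range(n_ch)], 8),
        ("%s", [str(_EDF_DIG_MAX) for _ in range(n_ch)], 8),
        ("%s", ["" for _ in range(n_ch)], 80),  # prefilter
        ("%s", [str(fs) for _ in range(n_ch)], 8),
        ("%s", ["" for _ in range(n_ch)], 32),
    ]
    sig_header = b"".join(
        b"".join(_pad_ascii(v, width) for v in values) for _, values, width in fields
    )

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = sig
    digital = np.clip(
        np.round((padded - pmin) * scale + _EDF_DIG_MIN), _EDF_DIG_MIN, _EDF_DIG_MAX
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())

    if recording.annotations is not None:
        write_events(events_sidecar_path(path), recording.annotations)
    return path


def events_sidecar_path(signal_path: str | Path) -> Path:
    p = Path(signal_path)
    return p.with_suffix(p.suffix + ".events.csv")


def write_events(path: str | Path, events: EventList) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "onset_sample": events.onsets,
            "label": events.labels,
            "session_id": events.session_id,
        }
    ).to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> EventList:
    df = pd.read_csv(path)
    session = str(df["session_id"].iloc[0]) if len(df) else "session"
    return EventList(
        onsets=df["onset_sample"].to_numpy(dtype=np.int64),
        labels=[str(x) for x in df["label"]],
        session_id=session,
    )


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    expected_channels: tuple[str, ...] | None = None,
) -> Recording:
    """Read an EDF or BDF recording (µV) plus its events sidecar, if present.

    ``fmt`` is inferred from the suffix when omitted. If
    ``expected_channels`` is given, any montage mismatch raises
    :class:`LoadError` instead of silently proceeding.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    readers = {"EDF": mne.io.read_raw_edf, "BDF": mne.io.read_raw_bdf}
    if fmt not in readers:
        raise LoadError(f"unknown format {fmt!r}; expected EDF or BDF")
    try:
        raw = readers[fmt](path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise LoadError(f"cannot parse {path}: {exc}") from exc
    labels = tuple(name.strip() for name in raw.ch_names)
    if expected_channels is not None and labels != tuple(expected_channels):
        raise LoadError(
            f"channel mismatch: file has {len(labels)} channels {labels[:4]}..., "
            f"expected {len(expected_channels)}"
        )
    data = raw.get_data(units="uV")
    sidecar = events_sidecar_path(path)
    events = read_events(sidecar) if sidecar.exists() else None
    return Recording(
        signal=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        annotations=events,
    )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_json_dict(), indent=1, sort_keys=True))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        labels=list(d["labels"]),
        trial_starts=np.asarray(d["trial_starts"], dtype=np.int64),
        cue_onsets=np.asarray(d["cue_onsets"], dtype=np.int64),
        sites=tuple(d["sites"]),
        bands=tuple(d["bands"]),
        modulation=np.asarray(d["modulation"], dtype=float),
        artifact_positions=np.asarray(d["artifact_positions"], dtype=np.int64),
    )
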
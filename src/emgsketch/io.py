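"""Data model and file I/O for multichannel surface-EMG recordings.

A recording is a plain ``n_samples x n_channels`` array of voltages plus a
sampling rate and ordered channel labels.  On disk a recording is a pair of
files: ``<name>.csv`` (one time column in seconds followed by one column per
channel) and ``<name>.meta.json`` (sampling rate, channel labels, main
channel, and — for synthetic sessions — ground-truth onsets and trial
labels).

The module also provides the standard conditioning filters of clinical EMG
amplifiers (10–500 Hz band-pass, 50 Hz notch) and full-wave rectification.
Filtering is optional preprocessing: synthetic sessions are generated
already in-band.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "DEFAULT_CHANNELS",
    "Recording",
    "RecordingMeta",
    "EmgFormatError",
    "ParameterError",
    "read_recording",
    "write_recording",
    "bandpass",
    "notch",
    "rectify",
]

#: Forearm/upper-arm muscles recorded during one-stroke sketching:
#: flexor carpi radialis, extensor digitorum, extensor carpi ulnaris,
#: extensor carpi radialis brevis, triceps brachii, biceps brachii.
DEFAULT_CHANNELS = ("FCR", "ED", "ECU", "ECRB", "TB", "BB")

#: The extensor digitorum channel carries the strongest burst during pen
#: strokes and is the default channel for onset detection.
DEFAULT_MAIN_CHANNEL = "ED"


class EmgFormatError(ValueError):
    """A signal/metadata file pair is malformed or inconsistent."""


class ParameterError(ValueError):
    """A processing parameter is outside its valid range."""


@dataclass(frozen=True)
class Recording:
    """Multichannel sampled sEMG.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``, voltages in arbitrary
        units (typically mV).
    fs
        Sampling rate in Hz.
    channels
        Ordered channel labels, one per column.
    main_channel
        Label of the channel used for onset detection.
    """

    samples: np.ndarray
    fs: float
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    main_channel: str = DEFAULT_MAIN_CHANNEL

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[:, None]
        if samples.ndim != 2:
            raise EmgFormatError("samples must be a 2-D array")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channels", tuple(self.channels))
        if samples.shape[0] < 1 or samples.shape[1] < 1:
            raise EmgFormatError("recording needs at least one sample and one channel")
        if samples.shape[1] != len(self.channels):
            raise EmgFormatError(
                f"{samples.shape[1]} sample columns but {len(self.channels)} channel labels"
            )
        if not self.fs > 0:
            raise ParameterError("sampling rate must be positive")
        if self.main_channel not in self.channels:
            raise EmgFormatError(f"main channel {self.main_channel!r} not in {self.channels}")
        if not np.all(np.isfinite(samples)):
            raise EmgFormatError("recording contains non-finite sample values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal of one channel by label."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise EmgFormatError(f"no channel {label!r} in {self.channels}") from None
        return self.samples[:, idx]

    @property
    def main_signal(self) -> np.ndarray:
        return self.channel(self.main_channel)


@dataclass
class RecordingMeta:
    """Sidecar metadata for a recording.

    ``ground_truth_onsets`` and ``labels`` are only present for synthetic
    sessions where the generator planted the bursts; real recordings carry
    neither.
    """

    fs: float
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    main_channel: str = DEFAULT_MAIN_CHANNEL
    subject_id: str = ""
    session_id: str = ""
    ground_truth_onsets: list[int] | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if self.ground_truth_onsets is not None and self.labels is not None:
            if len(self.ground_truth_onsets) != len(self.labels):
                raise EmgFormatError(
                    "ground_truth_onsets and labels must have equal length"
                )


def write_recording(
    rec: Recording,
    signal_path: str | Path,
    meta_path: str | Path,
    meta: RecordingMeta | None = None,
    float_format: str = "%.6f",
) -> None:
    """Write a recording as a CSV signal file plus a JSON metadata sidecar.

    The CSV has a header row, a leading ``time`` column in seconds, then one
    column per channel.  Round-trips through :func:`read_recording` to the
    serialization precision (six decimals by default).
    """
    if meta is None:
        meta = RecordingMeta(fs=rec.fs, channels=rec.channels, main_channel=rec.main_channel)
    t = np.arange(rec.n_samples) / rec.fs
    frame = pd.DataFrame(rec.samples, columns=list(rec.channels))
    frame.insert(0, "time", t)
    frame.to_csv(signal_path, index=False, float_format=float_format)

    payload: dict = {
        "fs": meta.fs,
        "channels": list(meta.channels),
        "main_channel": meta.main_channel,
        "subject_id": meta.subject_id,
        "session_id": meta.session_id,
    }
    if meta.ground_truth_onsets is not None:
        payload["ground_truth_onsets"] = [int(i) for i in meta.ground_truth_onsets]
    if meta.labels is not None:
        payload["labels"] = list(meta.labels)
    Path(meta_path).write_text(json.dumps(payload, indent=1))


def read_meta(meta_path: str | Path) -> RecordingMeta:
    """Read the JSON sidecar alone."""
    try:
        payload = json.loads(Path(meta_path).read_text())
    except json.JSONDecodeError as exc:
        raise EmgFormatError(f"metadata sidecar is not valid JSON: {exc}") from exc
    try:
        return RecordingMeta(
            fs=float(payload["fs"]),
            channels=tuple(payload["channels"]),
            main_channel=payload.get("main_channel", payload["channels"][0]),
            subject_id=payload.get("subject_id", ""),
            session_id=payload.get("session_id", ""),
            ground_truth_onsets=payload.get("ground_truth_onsets"),
            labels=payload.get("labels"),
        )
    except KeyError as exc:
        raise EmgFormatError(f"metadata sidecar missing required key {exc}") from exc


def read_recording(
    signal_path: str | Path, meta_path: str | Path
) -> tuple[Recording, RecordingMeta]:
    """Read a CSV/JSON recording pair.

    The first CSV column (time or sample index) is ignored for the sample
    matrix; the remaining columns must match the sidecar's channel list in
    number.
    """
    meta = read_meta(meta_path)
    try:
        frame = pd.read_csv(signal_path)
    except ValueError as exc:
        raise EmgFormatError(f"cannot parse signal file: {exc}") from exc
    if frame.shape[1] < 2:
        raise EmgFormatError("signal file needs a time column plus at least one channel")
    data = frame.iloc[:, 1:]
    if data.shape[1] != len(meta.channels):
        raise EmgFormatError(
            f"signal file has {data.shape[1]} data columns but sidecar lists "
            f"{len(meta.channels)} channels"
        )
    values = data.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise EmgFormatError("signal file contains non-numeric cells")
    rec = Recording(
        samples=values, fs=meta.fs, channels=meta.channels, main_channel=meta.main_channel
    )
    return rec, meta


# ---------------------------------------------------------------------------
# Conditioning filters


def bandpass(rec: Recording, lo: float = 10.0, hi: float | None = None) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass.

    Applied forward-backward (``sosfiltfilt``) so burst onsets are not
    shifted.  ``hi=None`` requests the conventional 500 Hz upper edge,
    clamped below Nyquist (with a warning) when the sampling rate makes
    500 Hz unrealisable — at 1000 Hz the edge becomes 450 Hz.
    """
    nyq = rec.fs / 2.0
    if hi is None:
        hi = 500.0
        if hi >= nyq:
            hi = 0.9 * nyq
            warnings.warn(
                f"band-pass upper edge clamped to {hi:g} Hz (Nyquist is {nyq:g} Hz)",
                stacklevel=2,
            )
    if not 0 < lo < hi:
        raise ParameterError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ParameterError(
            f"band-pass upper edge {hi} Hz must be below Nyquist ({nyq:g} Hz); "
            "lower hi or resample"
        )
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=0)
    return replace(rec, samples=filtered)


def notch(rec: Recording, freq: float = 50.0, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch removing line interference (default 50 Hz)."""
    nyq = rec.fs / 2.0
    if not 0 < freq < nyq:
        raise ParameterError(f"notch frequency {freq} Hz must lie in (0, {nyq:g}) Hz")
    b, a = sps.iirnotch(freq, q, fs=rec.fs)
    filtered = sps.filtfilt(b, a, rec.samples, axis=0)
    return replace(rec, samples=filtered)


def rectify(rec: Recording) -> Recording:
    """Full-wave rectification (elementwise absolute value)."""
    return replace(rec, samples=np.abs(rec.samples))
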
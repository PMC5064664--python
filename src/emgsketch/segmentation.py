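"""Burst-onset detection and epoch extraction.

The two-step windowing scheme: a short overlapped sliding window (default
20 ms length, 5 ms increment) runs over the main channel computing RMS per
window; an epoch onset is declared when a run of consecutive windows — long
enough to span 300 ms, i.e. 57 windows at the defaults — all reach a
threshold of 0.6x the whole-session RMS of the main channel.  The start
sample of the first window of the run is the epoch onset for all channels,
and the fixed-length (2.5 s) classification epoch is cut there.  Scanning
resumes past the extracted epoch, so emitted onsets never overlap.

All indices are 0-based samples; windows are half-open; milliseconds are
converted to samples by ``round(ms * fs / 1000)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ParameterError, Recording

__all__ = [
    "OnsetConfig",
    "Epoch",
    "sustain_window_count",
    "sliding_rms",
    "session_threshold",
    "detect_onsets",
    "extract_epochs",
]


def _ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


@dataclass(frozen=True)
class OnsetConfig:
    """Parameters of the onset detector and epoch geometry.

    slide_len_ms / slide_inc_ms
        Sliding-window length ``l`` and increment ``s`` for threshold
        crossing (overlapped: ``s <= l``).
    sustain_ms
        How long the sliding-window RMS must stay above threshold before an
        onset is declared.
    threshold_mult
        Multiplier on the whole-session main-channel RMS.
    epoch_len_ms
        Length ``T`` of one classification epoch.
    """

    slide_len_ms: float = 20.0
    slide_inc_ms: float = 5.0
    sustain_ms: float = 300.0
    threshold_mult: float = 0.6
    epoch_len_ms: float = 2500.0

    def __post_init__(self) -> None:
        if min(self.slide_len_ms, self.slide_inc_ms, self.sustain_ms, self.epoch_len_ms) <= 0:
            raise ParameterError("all window lengths must be positive")
        if self.slide_inc_ms > self.slide_len_ms:
            raise ParameterError(
                "slide_inc_ms must not exceed slide_len_ms (overlapped windowing)"
            )
        if self.sustain_ms < self.slide_len_ms:
            raise ParameterError("sustain_ms must be at least one sliding window long")
        if self.threshold_mult <= 0:
            raise ParameterError(
                "threshold_mult must be > 0 (a zero threshold fires everywhere)"
            )


@dataclass(frozen=True)
class Epoch:
    """One fixed-length trial slice anchored at a detected onset."""

    onset_sample: int
    samples: np.ndarray  # (epoch_len, n_channels)
    fs: float
    channels: tuple[str, ...]
    label: str | None = None


def sustain_window_count(cfg: OnsetConfig) -> int:
    """Number of consecutive sliding windows whose union spans ``sustain_ms``.

    With length ``l`` and increment ``s`` this is
    ``floor((sustain - l) / s) + 1`` — 57 windows for 300 ms at the 20/5 ms
    defaults.
    """
    return int((cfg.sustain_ms - cfg.slide_len_ms) // cfg.slide_inc_ms) + 1


def sliding_rms(signal: np.ndarray, cfg: OnsetConfig, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """RMS of each overlapped sliding window over a 1-D signal.

    Returns ``(starts, rms)`` where windows start at ``0, s, 2s, ...`` while
    they fit; both arrays are empty when the signal is shorter than one
    window.
    """
    x = np.asarray(signal, dtype=float)
    l = _ms_to_samples(cfg.slide_len_ms, fs)
    s = _ms_to_samples(cfg.slide_inc_ms, fs)
    if x.shape[0] < l:
        return np.empty(0, dtype=int), np.empty(0)
    starts = np.arange(0, x.shape[0] - l + 1, s)
    css = np.concatenate(([0.0], np.cumsum(x * x)))
    rms = np.sqrt((css[starts + l] - css[starts]) / l)
    return starts, rms


def session_threshold(rec: Recording, cfg: OnsetConfig) -> float:
    """Detection threshold: ``threshold_mult`` x RMS of the entire
    main-channel signal of the session."""
    x = rec.main_signal
    rms = float(np.sqrt(np.mean(x * x)))
    if rms == 0.0:
        raise ParameterError(
            "main channel is all-zero; session RMS threshold is degenerate"
        )
    return cfg.threshold_mult * rms


def detect_onsets(
    rec: Recording, cfg: OnsetConfig | None = None, threshold: float | None = None
) -> list[int]:
    """Find epoch onsets on the (rectified) main channel.

    A run of :func:`sustain_window_count` consecutive windows with RMS at or
    above the threshold emits the start sample of the first window of the
    run; the scan then jumps past the epoch (``onset + epoch_len``).  Onsets
    whose epoch would overrun the recording are dropped.  The threshold is
    relative (a multiple of session RMS), so detection is invariant to
    overall signal scaling.
    """
    cfg = cfg or OnsetConfig()
    if threshold is None:
        threshold = session_threshold(rec, cfg)
    x = np.abs(rec.main_signal)  # RMS is rectification-invariant; kept explicit
    starts, rms = sliding_rms(x, cfg, rec.fs)
    if starts.size == 0:
        return []
    B = sustain_window_count(cfg)
    epoch_len = _ms_to_samples(cfg.epoch_len_ms, rec.fs)
    passing = rms >= threshold

    # runlen[i] = length of the consecutive passing run starting at window i,
    # i.e. distance from i to the next failing window
    n = passing.size
    next_fail = np.where(passing, n, np.arange(n))
    next_fail = np.minimum.accumulate(next_fail[::-1])[::-1]
    runlen = next_fail - np.arange(n)

    onsets: list[int] = []
    i = 0
    n_windows = passing.size
    while i < n_windows:
        if runlen[i] >= B:
            onset = int(starts[i])
            if onset + epoch_len <= rec.n_samples:
                onsets.append(onset)
            # resume past the epoch whether or not it fit the recording
            next_start = onset + epoch_len
            i = int(np.searchsorted(starts, next_start, side="left"))
        else:
            i += 1
    return onsets


def extract_epochs(
    rec: Recording,
    onsets: list[int],
    cfg: OnsetConfig | None = None,
    labels: list[str] | None = None,
) -> list[Epoch]:
    """Cut one fixed-length epoch per onset, all channels.

    Labels are attached positionally when given (their count must match the
    onset count).  Onsets too near the end of the recording are dropped with
    a warning.
    """
    cfg = cfg or OnsetConfig()
    if labels is not None and len(labels) != len(onsets):
        raise ParameterError(
            f"{len(labels)} labels for {len(onsets)} onsets — counts must match"
        )
    epoch_len = _ms_to_samples(cfg.epoch_len_ms, rec.fs)
    epochs: list[Epoch] = []
    for k, onset in enumerate(onsets):
        if onset < 0:
            raise ParameterError(f"negative onset sample {onset}")
        if onset + epoch_len > rec.n_samples:
            warnings.warn(
                f"onset {onset} too near the end of the recording; epoch dropped",
                stacklevel=2,
            )
            continue
        epochs.append(
            Epoch(
                onset_sample=int(onset),
                samples=rec.samples[onset : onset + epoch_len],
                fs=rec.fs,
                channels=rec.channels,
                label=None if labels is None else labels[k],
            )
        )
    return epochs
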
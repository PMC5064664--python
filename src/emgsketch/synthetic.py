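"""Synthetic multichannel sEMG sessions with planted burst structure.

Real one-stroke sketching recordings are not available, so every stage of
the pipeline is exercised on simulated sessions that reproduce the signal
structure the method relies on: a 1000 Hz six-channel recording paced in
3 s trials, each trial holding one muscle-activity burst of 1–2.5 s over a
quiet baseline, with the burst's per-channel amplitude profile depending on
which of the 11 one-stroke shapes the trial represents.

The model is deliberately phenomenological.  The carrier is band-limited
(10–450 Hz) Gaussian noise — the amplitude spectrum of interference-pattern
EMG — and class identity enters only through a per-channel, per-sub-segment
gain envelope.  Amplitude features (mean, RMS, MAV) respond exactly to such
gain structure, which is what the classifier consumes; motor-unit
physiology, electrode shift and fatigue are out of scope.

Every generated session carries ground-truth onsets and trial labels in its
metadata sidecar, so onset detection and classification can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import DEFAULT_CHANNELS, ParameterError, Recording, RecordingMeta

__all__ = [
    "SHAPE_NAMES",
    "ClassProfile",
    "SyntheticConfig",
    "default_profiles",
    "generate_session",
]

#: The 11 one-stroke shapes: four straight lines, four ellipses, the
#: perfect circle, and two smooth curves.
SHAPE_NAMES = (
    "h_line",
    "v_line",
    "line_45",
    "line_135",
    "h_ellipse_20",
    "h_ellipse_40",
    "v_ellipse_20",
    "v_ellipse_40",
    "circle",
    "s_curve",
    "arc",
)

#: Burst duration range in seconds.  Strokes last 1-2.5 s; the range
#: describes the population of shapes (an S-curve takes longer to draw
#: than a short line), so :func:`default_profiles` assigns each class a
#: characteristic duration from this range and individual trials jitter
#: around it.  A profile with ``duration_s=None`` instead draws every
#: trial's duration uniformly from the range.
DURATION_RANGE_S = (1.0, 2.5)

#: Gain of the attack phase (first ~30% of the burst), shared by all
#: classes: the pen-down acceleration is a ballistic movement with strong
#: activation regardless of the shape about to be drawn.  Keeping the
#: attack identical and above the stroke average also keeps the first
#: 300 ms of every burst well clear of the 0.6-RMS detection threshold.
ATTACK_GAIN = 1.5

#: Linear cross-fade between envelope sub-segments, seconds.
CROSSFADE_S = 0.025


@dataclass
class ClassProfile:
    """Per-class burst shape: an ``n_channels x K`` gain envelope.

    Each channel's burst amplitude is modulated by ``K`` piecewise-constant
    sub-segment gains spread evenly over the burst duration.  ``duration_s``
    pins the burst length for this class; ``None`` means each trial draws
    uniformly from :data:`DURATION_RANGE_S`.
    """

    name: str
    envelope: np.ndarray
    duration_s: float | None = None

    def __post_init__(self) -> None:
        env = np.asarray(self.envelope, dtype=float)
        if env.ndim != 2 or env.shape[1] < 1:
            raise ParameterError("envelope must be a 2-D (n_channels x K) array, K >= 1")
        if not np.all(np.isfinite(env)):
            raise ParameterError("envelope values must be finite")
        if not np.any(env > 0):
            raise ParameterError("envelope needs at least one positive entry")
        if np.any(env < 0):
            raise ParameterError("envelope gains must be non-negative")
        self.envelope = env


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic recording session.

    Defaults mirror the recorded protocol being emulated: 1000 Hz sampling,
    six muscles, 3 s trial cadence, 11 shape classes with 100 repetitions
    each (1100 trials).  ``separation`` scales how far apart the class
    envelopes lie; ``burst_sd``/``baseline_sd`` set active and rest noise
    amplitudes (default ratio 8).
    """

    fs: float = 1000.0
    n_channels: int = 6
    trial_period_s: float = 3.0
    classes: list[ClassProfile] | None = None
    reps_per_class: int = 100
    baseline_sd: float = 0.01
    burst_sd: float = 0.08
    separation: float = 1.5
    jitter_max_s: float = 0.5
    duration_jitter_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps_per_class < 1:
            raise ParameterError("reps_per_class must be >= 1")
        if not self.burst_sd > self.baseline_sd >= 0:
            raise ParameterError("need burst_sd > baseline_sd >= 0")
        if self.fs <= 0 or self.n_channels < 1 or self.trial_period_s <= 0:
            raise ParameterError("fs, n_channels and trial_period_s must be positive")
        if self.separation < 0 or self.jitter_max_s < 0:
            raise ParameterError("separation and jitter_max_s must be >= 0")
        if not 0 <= self.duration_jitter_frac < 1:
            raise ParameterError("duration_jitter_frac must be in [0, 1)")
        max_dur = max(
            (p.duration_s for p in self.classes or [] if p.duration_s is not None),
            default=DURATION_RANGE_S[1],
        ) * (1.0 + self.duration_jitter_frac)
        if self.trial_period_s < max_dur:
            raise ParameterError(
                f"trial period {self.trial_period_s} s shorter than burst duration "
                f"{max_dur:g} s (incl. jitter)"
            )


def default_profiles(
    n_classes: int = 11,
    n_channels: int = 6,
    K: int = 10,
    separation: float = 1.5,
    seed: int = 0,
) -> list[ClassProfile]:
    """Draw ``n_classes`` distinct activation envelopes.

    The first ~30% of sub-segments form the shared attack phase at
    :data:`ATTACK_GAIN`; the remaining sub-segments get gains
    ``1 + separation * u`` with ``u ~ U(-1/2, 1/2)`` per channel, clipped at
    zero.  The minimum pairwise envelope distance therefore grows
    proportionally with ``separation``, and ``separation=0`` collapses all
    classes onto one envelope.

    Each class also receives a characteristic stroke duration drawn from
    :data:`DURATION_RANGE_S` — drawing a circle takes consistently longer
    than flicking a short line — around which individual trials jitter.
    """
    if n_classes < 2:
        raise ParameterError("need at least two classes")
    if K < 1 or n_channels < 1:
        raise ParameterError("K and n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    n_attack = int(round(0.3 * K)) if K > 1 else 0
    names = list(SHAPE_NAMES[:n_classes])
    names += [f"shape_{i}" for i in range(len(names), n_classes)]
    profiles = []
    for name in names:
        env = np.ones((n_channels, K))
        env[:, :n_attack] = ATTACK_GAIN
        u = rng.uniform(-0.5, 0.5, size=(n_channels, K - n_attack))
        # Remove the per-channel mean so classes differ in the time COURSE
        # of each muscle's drive, not in its stroke-averaged level: shapes
        # are drawn with the same muscles at comparable overall effort, and
        # it is the within-stroke modulation that distinguishes them.
        u -= u.mean(axis=1, keepdims=True)
        env[:, n_attack:] = np.clip(1.0 + separation * u, 0.0, None)
        duration = float(rng.uniform(*DURATION_RANGE_S))
        profiles.append(ClassProfile(name=name, envelope=env, duration_s=duration))
    return profiles


def _gain_curve(envelope_row: np.ndarray, n_burst: int, fs: float) -> np.ndarray:
    """Piecewise-constant sub-segment gains over a burst, with short linear
    cross-fades at interior boundaries.  The attack (t=0) is not faded in."""
    K = envelope_row.shape[0]
    bounds = np.round(np.arange(K + 1) * n_burst / K).astype(int)
    gain = np.empty(n_burst)
    for k in range(K):
        gain[bounds[k] : bounds[k + 1]] = envelope_row[k]
    fade_n = int(round(CROSSFADE_S * fs))
    for k in range(1, K):
        b = bounds[k]
        n = min(fade_n, n_burst - b, bounds[k + 1] - bounds[k])
        if n > 1:
            gain[b : b + n] = np.linspace(envelope_row[k - 1], envelope_row[k], n)
    return gain


def generate_session(cfg: SyntheticConfig) -> tuple[Recording, RecordingMeta]:
    """Generate one full session: ``n_classes * reps_per_class`` paced trials.

    Each rep-block presents every class once in a freshly randomized order
    (mirroring randomized template sheets).  Within a trial the burst onset
    is jittered uniformly in ``[0, min(jitter_max_s, period - duration)]``;
    the jitter cap keeps every 2.5 s classification epoch inside the trial
    cadence so no planted burst can shadow its successor.

    Returns the recording and a metadata sidecar carrying ground-truth
    onset samples and per-trial class labels.
    """
    profiles = cfg.classes
    if profiles is None:
        profiles = default_profiles(
            11, cfg.n_channels, separation=cfg.separation, seed=cfg.seed
        )
    for p in profiles:
        if p.envelope.shape[0] != cfg.n_channels:
            raise ParameterError(
                f"profile {p.name!r} has {p.envelope.shape[0]} channel rows, "
                f"config says {cfg.n_channels}"
            )
    by_name = {p.name: p for p in profiles}
    if len(by_name) != len(profiles):
        raise ParameterError("class profile names must be unique")

    rng = np.random.default_rng(cfg.seed + 1)
    n_trial = int(round(cfg.trial_period_s * cfg.fs))
    n_trials = len(profiles) * cfg.reps_per_class
    n_total = n_trials * n_trial

    # Trial order: each rep-block is a random permutation of the classes.
    order: list[str] = []
    for _ in range(cfg.reps_per_class):
        order.extend(rng.permutation([p.name for p in profiles]))

    # Quiet-baseline instrument noise over the whole session.
    samples = rng.normal(0.0, cfg.baseline_sd, size=(n_total, cfg.n_channels))

    # Band-limited unit-variance carrier, cut per burst below.
    carrier = rng.standard_normal((n_total, cfg.n_channels))
    sos = sps.butter(4, [10.0, 0.45 * cfg.fs], btype="bandpass", fs=cfg.fs, output="sos")
    carrier = sps.sosfiltfilt(sos, carrier, axis=0)
    carrier /= carrier.std(axis=0, keepdims=True)

    onsets: list[int] = []
    for i, name in enumerate(order):
        profile = by_name[name]
        if profile.duration_s is None:
            dur = rng.uniform(*DURATION_RANGE_S)
        else:
            jit = cfg.duration_jitter_frac
            dur = profile.duration_s * (1.0 + rng.uniform(-jit, jit))
        jit_hi = min(cfg.jitter_max_s, cfg.trial_period_s - dur)
        jitter = rng.uniform(0.0, jit_hi) if jit_hi > 0 else 0.0
        onset = i * n_trial + int(round(jitter * cfg.fs))
        n_burst = int(round(dur * cfg.fs))
        for ch in range(cfg.n_channels):
            gain = _gain_curve(profile.envelope[ch], n_burst, cfg.fs)
            samples[onset : onset + n_burst, ch] += (
                cfg.burst_sd * gain * carrier[onset : onset + n_burst, ch]
            )
        onsets.append(onset)

    if cfg.n_channels <= len(DEFAULT_CHANNELS):
        channels = DEFAULT_CHANNELS[: cfg.n_channels]
    else:
        channels = tuple(f"CH{i + 1}" for i in range(cfg.n_channels))
    main = "ED" if "ED" in channels else channels[0]
    rec = Recording(samples=samples, fs=cfg.fs, channels=channels, main_channel=main)
    meta = RecordingMeta(
        fs=cfg.fs,
        channels=channels,
        main_channel=main,
        session_id=f"synthetic-seed{cfg.seed}",
        ground_truth_onsets=onsets,
        labels=order,
    )
    return rec, meta
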
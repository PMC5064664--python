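"""Time-domain feature extraction and dimensionality reduction.

Three amplitude features are computed per analysis window of length ``N``
samples with voltages ``v_i``:

    aEMG = (1/N) sum v_i          (signed mean)
    RMS  = sqrt((1/N) sum v_i^2)
    MAV  = (1/N) sum |v_i|

Windows are placed adjacently (increment = length) over each 2.5 s epoch,
under two regimes: the short 250 ms window (10 segments -> 10 x 3 x 6 = 180
features for six channels) and the long 2500 ms window (1 segment -> 18
features).  Features default to the rectified signal — the recordings are
rectified before segmentation — which makes aEMG coincide with MAV; set
``on_rectified=False`` to compute on the raw signal instead.

Reduction is a two-stage transform fitted on training data only: per-column
min-max scaling to the interval [0.05, 0.95], then PCA (defaults: 12
components for the short window, 5 for the long).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ParameterError
from .segmentation import Epoch

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "FeatureMatrix",
    "Reducer",
    "window_features",
    "segments_per_epoch",
    "extract_features",
    "epochs_to_matrix",
    "fit_reducer",
    "apply_reducer",
]

FEATURE_NAMES = ("aEMG", "RMS", "MAV")

#: Default PCA width per analysis-window regime (short 250 ms keeps 12
#: components out of 180 features; long 2500 ms keeps 5 out of 18).
DEFAULT_N_COMPONENTS = {250.0: 12, 2500.0: 5}


@dataclass(frozen=True)
class FeatureConfig:
    """Analysis-window regime for feature extraction.

    ``analysis_inc_ms`` defaults to the window length (adjacent windowing);
    values below the length give overlapped windowing.  Windows that do not
    fit entirely inside the epoch are dropped (floor rule).
    """

    analysis_len_ms: float = 250.0
    analysis_inc_ms: float | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES
    on_rectified: bool = True

    def __post_init__(self) -> None:
        if self.analysis_len_ms <= 0:
            raise ParameterError("analysis window length must be positive")
        inc = self.analysis_inc_ms
        if inc is None:
            object.__setattr__(self, "analysis_inc_ms", self.analysis_len_ms)
        elif not 0 < inc <= self.analysis_len_ms:
            raise ParameterError(
                "analysis increment must be in (0, length] (adjacent or overlapped)"
            )
        unknown = set(self.feature_names) - set(FEATURE_NAMES)
        if unknown:
            raise ParameterError(f"unknown feature names: {sorted(unknown)}")
        if not self.feature_names:
            raise ParameterError("need at least one feature name")
        object.__setattr__(self, "feature_names", tuple(self.feature_names))


def window_features(window: np.ndarray) -> tuple[float, float, float]:
    """(aEMG, RMS, MAV) of a single 1-D window."""
    v = np.asarray(window, dtype=float)
    if v.size == 0:
        raise ParameterError("empty analysis window")
    aemg = float(np.mean(v))
    rms = float(np.sqrt(np.mean(v * v)))
    mav = float(np.mean(np.abs(v)))
    return aemg, rms, mav


def segments_per_epoch(epoch_len_ms: float, cfg: FeatureConfig) -> int:
    """Number of analysis windows placed in an epoch (floor rule).

    For adjacent placement with increment ``S`` and length ``L`` this is
    ``floor((epoch_len - L) / S) + 1`` — e.g. 10 short windows or 1 long
    window per 2.5 s epoch.
    """
    if epoch_len_ms < cfg.analysis_len_ms:
        return 0
    return int((epoch_len_ms - cfg.analysis_len_ms) // cfg.analysis_inc_ms) + 1


def extract_features(epoch: Epoch, cfg: FeatureConfig | None = None) -> pd.Series:
    """Feature vector of one epoch with a (segment, feature, channel) index.

    The vector is flattened with segment varying slowest, then feature, then
    channel: 10 segments x 3 features x 6 channels = 180 values for the
    short window.
    """
    cfg = cfg or FeatureConfig()
    L = int(round(cfg.analysis_len_ms * epoch.fs / 1000.0))
    S = int(round(cfg.analysis_inc_ms * epoch.fs / 1000.0))
    n = epoch.samples.shape[0]
    if L > n:
        raise ParameterError(
            f"analysis window of {L} samples exceeds epoch length {n}"
        )
    x = np.abs(epoch.samples) if cfg.on_rectified else epoch.samples
    starts = np.arange(0, n - L + 1, S)
    feat_idx = [FEATURE_NAMES.index(f) for f in cfg.feature_names]
    values = np.empty((starts.size, len(feat_idx), x.shape[1]))
    for si, start in enumerate(starts):
        w = x[start : start + L]
        trio = np.stack(
            [np.mean(w, axis=0), np.sqrt(np.mean(w * w, axis=0)), np.mean(np.abs(w), axis=0)]
        )
        values[si] = trio[feat_idx]
    index = pd.MultiIndex.from_product(
        [range(starts.size), list(cfg.feature_names), list(epoch.channels)],
        names=["segment", "feature", "channel"],
    )
    return pd.Series(values.ravel(), index=index)


@dataclass
class FeatureMatrix:
    """Trials x features table with a structured column index and labels."""

    values: pd.DataFrame  # columns: MultiIndex (segment, feature, channel)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.values):
            raise ParameterError("label count must match trial count")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ParameterError("feature matrix contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def epochs_to_matrix(epochs: Sequence[Epoch], cfg: FeatureConfig | None = None) -> FeatureMatrix:
    """Extract features for a list of epochs into one FeatureMatrix."""
    if not epochs:
        raise ParameterError("no epochs to extract features from")
    cfg = cfg or FeatureConfig()
    rows = [extract_features(e, cfg) for e in epochs]
    values = pd.DataFrame(rows).reset_index(drop=True)
    labels = [e.label for e in epochs]
    if any(lbl is None for lbl in labels):
        labels = None
    return FeatureMatrix(values=values, labels=labels)


@dataclass
class Reducer:
    """Frozen normalization + PCA transform fitted on a training set.

    Columns are min-max scaled to ``[lo, hi]`` using training minima and
    maxima (constant columns map to the interval midpoint), then projected
    onto the leading principal components of the scaled training data.
    Test data passes through the same frozen transform and may legitimately
    fall outside the interval.
    """

    col_min: np.ndarray
    col_max: np.ndarray
    lo: float
    hi: float
    pca: PCA
    columns: pd.Index

    @property
    def n_components(self) -> int:
        return int(self.pca.n_components_)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        safe = np.where(span == 0, 1.0, span)
        scaled = self.lo + (X - self.col_min) / safe * (self.hi - self.lo)
        mid = (self.lo + self.hi) / 2.0
        return np.where(span == 0, mid, scaled)


def fit_reducer(
    train: FeatureMatrix,
    n_components: int | None = None,
    interval: tuple[float, float] = (0.05, 0.95),
    variance_fraction: float | None = None,
) -> Reducer:
    """Fit the normalization interval and PCA on training features only.

    ``n_components`` defaults to the regime convention (12 when 180
    features are present, 5 when 18) via a simple heuristic: ``min(12, D)``
    scaled to the feature count; pass it explicitly for full control, or
    pass ``variance_fraction`` (e.g. 0.95) to let PCA choose the width.
    """
    X = train.values.to_numpy(dtype=float)
    n, D = X.shape
    if variance_fraction is not None:
        if not 0 < variance_fraction < 1:
            raise ParameterError("variance_fraction must be in (0, 1)")
        n_comp: float | int = variance_fraction
    else:
        if n_components is None:
            n_components = 12 if D >= 180 else min(5, D)
        if not 1 <= n_components <= D:
            raise ParameterError(f"n_components must be in [1, {D}]")
        if n_components > n:
            raise ParameterError(
                f"n_components={n_components} exceeds the {n} training trials"
            )
        n_comp = n_components
    lo, hi = interval
    if not lo < hi:
        raise ParameterError("normalization interval must satisfy lo < hi")
    reducer = Reducer(
        col_min=X.min(axis=0),
        col_max=X.max(axis=0),
        lo=float(lo),
        hi=float(hi),
        pca=PCA(n_components=n_comp, svd_solver="full", random_state=0),
        columns=train.values.columns,
    )
    reducer.pca.fit(reducer._scale(X))
    return reducer


def apply_reducer(reducer: Reducer, matrix: FeatureMatrix) -> np.ndarray:
    """Project a feature matrix through the frozen scaler + PCA.

    Returns an ``(n_trials, n_components)`` array.
    """
    if not matrix.values.columns.equals(reducer.columns):
        raise ParameterError("feature columns do not match the fitted reducer")
    X = matrix.values.to_numpy(dtype=float)
    return reducer.pca.transform(reducer._scale(X))
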
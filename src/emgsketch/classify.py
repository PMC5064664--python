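"""Multiclass shape recognition: one-against-all GEP plus neural baselines.

The 11-class problem is decomposed into 11 binary problems (class j versus
the rest); each binary problem is solved by evolving a GEP chromosome whose
terminals are the reduced principal-component features.  At prediction
time a test vector is assigned the unique class whose binary classifier
fires (output at or above the rounding threshold); if none or several fire,
the class with the largest raw continuous output wins, which keeps
prediction total.

Two baselines mirror common practice: a three-layer back-propagation
network (BPNN) and an Elman recurrent network (ENN), both with a sigmoid
hidden layer and a tanh output layer, trained by gradient descent with
momentum until the training MSE drops below 0.01 or 2000 iterations pass.
Class targets are encoded as +0.9 (own class) / -0.9 (rest) to sit inside
the tanh range.

Performance is reported as the per-class accuracy rate AR = c/C x 100%
(correctly classified test samples over all test samples of that class)
and AR11, the unweighted mean AR over the 11 shape classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gep
from .features import FeatureMatrix, Reducer
from .io import ParameterError

__all__ = [
    "NNConfig",
    "OneVsAllModel",
    "NeuralModel",
    "EvalReport",
    "split",
    "ova_problems",
    "train_ova_gep",
    "predict",
    "train_bpnn",
    "train_elman",
    "evaluate",
]


def split(
    matrix: FeatureMatrix,
    train_frac: float = 0.7,
    seed: int = 0,
    blocks: list[int] | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified train/test split: ``train_frac`` of each class trains.

    With 1100 labeled trials (100 per class) at the default 0.7 this yields
    770 training and 330 test samples.  ``blocks`` optionally refines the
    strata to (class, block) — the stand-in for a per-day split when
    sessions carry day/block structure.
    """
    if matrix.labels is None:
        raise ParameterError("split requires a labeled feature matrix")
    if not 0 < train_frac < 1:
        raise ParameterError("train_frac must lie strictly between 0 and 1")
    labels = np.asarray(matrix.labels)
    if blocks is not None:
        if len(blocks) != len(labels):
            raise ParameterError("block ids must match trial count")
        strata = [f"{l}|{b}" for l, b in zip(labels, blocks)]
    else:
        strata = list(labels)
    strata = np.asarray(strata)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        if idx.size < 2:
            raise ParameterError(
                f"stratum {s!r} has {idx.size} member(s); need at least 2 to split"
            )
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx.sort()
    test_idx.sort()

    def take(ix: list[int]) -> FeatureMatrix:
        return FeatureMatrix(
            values=matrix.values.iloc[ix].reset_index(drop=True),
            labels=[matrix.labels[i] for i in ix],
        )

    return take(train_idx), take(test_idx)


def ova_problems(labels: list[str], class_names: list[str]) -> dict[str, np.ndarray]:
    """One binary {1, 0} target vector per class (class j vs. the rest)."""
    labels_arr = np.asarray(labels)
    unseen = set(labels_arr) - set(class_names)
    if unseen:
        raise ParameterError(f"labels not in class_names: {sorted(unseen)}")
    return {name: (labels_arr == name).astype(float) for name in class_names}


@dataclass
class OneVsAllModel:
    """Eleven binary GEP chromosomes plus the frozen feature reducer."""

    class_names: list[str]
    binaries: dict[str, gep.Chromosome]
    sset: gep.SymbolSet
    reducer: Reducer | None = None
    rounding_threshold: float = 0.5
    reports: dict[str, gep.FitnessReport] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.binaries) != set(self.class_names):
            raise ParameterError("need exactly one binary classifier per class")

    def raw_outputs(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_classes) continuous outputs, class order preserved."""
        cols = [
            np.asarray(gep.evaluate(self.binaries[name], self.sset, X))
            for name in self.class_names
        ]
        return np.column_stack(cols)


def train_ova_gep(
    X: np.ndarray,
    labels: list[str],
    class_names: list[str],
    cfg: gep.GEPConfig | None = None,
    reducer: Reducer | None = None,
) -> OneVsAllModel:
    """Evolve one binary GEP classifier per class on reduced features.

    ``X`` is the reduced (n_trials, n_components) training matrix; the GEP
    terminal set is sized to its width.  Each binary problem is evolved
    independently with a seed offset so runs are reproducible yet distinct.
    """
    cfg = cfg or gep.GEPConfig()
    X = np.asarray(X, dtype=float)
    sset = gep.default_symbol_set(X.shape[1])
    problems = ova_problems(labels, class_names)
    binaries: dict[str, gep.Chromosome] = {}
    reports: dict[str, gep.FitnessReport] = {}
    for k, name in enumerate(class_names):
        sub_cfg = gep.GEPConfig(**{**cfg.__dict__, "seed": cfg.seed + 101 * (k + 1)})
        best, report, _ = gep.evolve(X, problems[name], sset, sub_cfg)
        binaries[name] = best
        reports[name] = report
    return OneVsAllModel(
        class_names=list(class_names),
        binaries=binaries,
        sset=sset,
        reducer=reducer,
        rounding_threshold=cfg.rounding_threshold,
        reports=reports,
    )


def predict(model: OneVsAllModel, X: np.ndarray) -> list[str]:
    """Assign one class label per row of the reduced feature matrix.

    Exactly one binary firing wins outright; zero or multiple firings fall
    back to the argmax of the raw continuous outputs (non-finite outputs
    rank lowest), so every input receives exactly one label.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    raw = model.raw_outputs(X)
    finite = np.isfinite(raw)
    fired = finite & (raw >= model.rounding_threshold)
    safe_raw = np.where(finite, raw, -np.inf)
    out: list[str] = []
    for i in range(X.shape[0]):
        hits = np.flatnonzero(fired[i])
        if hits.size == 1:
            out.append(model.class_names[hits[0]])
        else:
            row = safe_raw[i]
            if hits.size > 1:
                masked = np.full_like(row, -np.inf)
                masked[hits] = row[hits]
                row = masked
            out.append(model.class_names[int(np.argmax(row))])
    return out


# ---------------------------------------------------------------------------
# Neural baselines


@dataclass
class NNConfig:
    """Architecture and training settings for the BPNN/ENN baselines.

    ``hidden_nodes`` follows the window-regime convention: 25 for the short
    analysis window, 11 for the long one.  Training stops at
    ``max_iterations`` or when training MSE falls below ``target_mse``.
    """

    hidden_nodes: int = 25
    max_iterations: int = 2000
    target_mse: float = 0.01
    learning_rate: float = 0.01
    momentum: float = 0.9
    target_scale: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ParameterError("hidden_nodes must be >= 1")
        if not 0 < self.target_scale < 1:
            raise ParameterError("target_scale must sit strictly inside the tanh range")
        if self.learning_rate <= 0 or not 0 <= self.momentum < 1:
            raise ParameterError("learning_rate must be > 0 and momentum in [0, 1)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NeuralModel:
    """A trained feed-forward (or Elman) network over reduced features.

    The Elman variant adds a context layer carrying the hidden activations
    of the previously presented sample into the current forward pass; with
    zero context weights it reduces exactly to the BPNN forward pass.
    """

    class_names: list[str]
    W1: np.ndarray  # (d, H)
    b1: np.ndarray  # (H,)
    Wc: np.ndarray | None  # (H, H) context weights, Elman only
    W2: np.ndarray  # (H, O)
    b2: np.ndarray  # (O,)
    final_mse: float = float("nan")
    iterations: int = 0

    @property
    def is_elman(self) -> bool:
        return self.Wc is not None

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Raw tanh outputs, (n, n_classes).  For the Elman network the
        context state threads through the samples in row order, starting
        from a zero context."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.Wc is None:
            H = _sigmoid(X @ self.W1 + self.b1)
            return np.tanh(H @ self.W2 + self.b2)
        ctx = np.zeros(self.W1.shape[1])
        rows = []
        for x in X:
            h = _sigmoid(x @ self.W1 + ctx @ self.Wc + self.b1)
            rows.append(np.tanh(h @ self.W2 + self.b2))
            ctx = h
        return np.vstack(rows)

    def predict(self, X: np.ndarray) -> list[str]:
        out = self.forward(X)
        return [self.class_names[i] for i in np.argmax(out, axis=1)]


def _encode_targets(
    labels: list[str], class_names: list[str], scale: float
) -> np.ndarray:
    T = np.full((len(labels), len(class_names)), -scale)
    index = {name: i for i, name in enumerate(class_names)}
    for r, lbl in enumerate(labels):
        T[r, index[lbl]] = scale
    return T


def _train_network(
    X: np.ndarray,
    labels: list[str],
    class_names: list[str],
    cfg: NNConfig,
    elman: bool,
) -> NeuralModel:
    X = np.asarray(X, dtype=float)
    T = _encode_targets(labels, class_names, cfg.target_scale)
    n, d = X.shape
    H, O = cfg.hidden_nodes, len(class_names)
    rng = np.random.default_rng(cfg.seed)
    W1 = rng.normal(0, 1.0 / np.sqrt(d), (d, H))
    b1 = np.zeros(H)
    Wc = rng.normal(0, 0.1 / np.sqrt(H), (H, H)) if elman else None
    W2 = rng.normal(0, 1.0 / np.sqrt(H), (H, O))
    b2 = np.zeros(O)
    vel = {k: 0.0 for k in ("W1", "b1", "Wc", "W2", "b2")}
    mse = float("inf")
    it = 0
    ctx0 = np.zeros((n, H))
    for it in range(1, cfg.max_iterations + 1):
        if elman:
            # context = hidden state of the previously presented sample
            # (zero for the first), treated as a constant input (truncated
            # gradient, standard Elman training)
            Z1 = X @ W1 + ctx0 @ Wc + b1
        else:
            Z1 = X @ W1 + b1
        Hid = _sigmoid(Z1)
        Y = np.tanh(Hid @ W2 + b2)
        err = Y - T
        mse = float(np.mean(err**2))
        if not np.isfinite(mse):
            raise ParameterError(
                "network training diverged (non-finite loss); lower the learning rate"
            )
        if mse < cfg.target_mse:
            break
        dY = 2.0 * err * (1.0 - Y**2) / (n * O)
        gW2 = Hid.T @ dY
        gb2 = dY.sum(axis=0)
        dH = (dY @ W2.T) * Hid * (1.0 - Hid)
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}
        if elman:
            grads["Wc"] = ctx0.T @ dH
        params = {"W1": W1, "b1": b1, "W2": W2, "b2": b2}
        if elman:
            params["Wc"] = Wc
        for k, g in grads.items():
            vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * g
            params[k] += vel[k]
        if elman:
            ctx0 = np.vstack([np.zeros(H), Hid[:-1]])
    return NeuralModel(
        class_names=list(class_names),
        W1=W1,
        b1=b1,
        Wc=Wc,
        W2=W2,
        b2=b2,
        final_mse=mse,
        iterations=it,
    )


def train_bpnn(
    X: np.ndarray, labels: list[str], class_names: list[str], cfg: NNConfig | None = None
) -> NeuralModel:
    """Train the three-layer back-propagation baseline."""
    return _train_network(X, labels, class_names, cfg or NNConfig(), elman=False)


def train_elman(
    X: np.ndarray, labels: list[str], class_names: list[str], cfg: NNConfig | None = None
) -> NeuralModel:
    """Train the Elman (context-layer recurrent) baseline."""
    return _train_network(X, labels, class_names, cfg or NNConfig(), elman=True)


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvalReport:
    """Per-class accuracy rates, their mean, and the confusion matrix."""

    per_class_ar: dict[str, float]  # percent; NaN when a class has no test data
    ar_mean: float  # percent, unweighted mean over classes with test data
    confusion: pd.DataFrame  # rows: true class, columns: predicted
    n_samples: int

    def __str__(self) -> str:  # pragma: no cover - display helper
        lines = [f"{k}: AR = {v:.2f}%" for k, v in self.per_class_ar.items()]
        lines.append(f"mean AR over {len(self.per_class_ar)} classes = {self.ar_mean:.2f}%")
        return "\n".join(lines)


def evaluate(
    true_labels: list[str], predicted: list[str], class_names: list[str]
) -> EvalReport:
    """Score predictions: AR per class (= diagonal / row sum x 100) and the
    unweighted mean AR over classes, regardless of class counts."""
    if len(true_labels) != len(predicted):
        raise ParameterError("true and predicted label counts differ")
    if not true_labels:
        raise ParameterError("empty test set")
    confusion = pd.DataFrame(
        0, index=list(class_names), columns=list(class_names), dtype=int
    )
    for t, p in zip(true_labels, predicted):
        confusion.loc[t, p] += 1
    per_class: dict[str, float] = {}
    for name in class_names:
        row_sum = int(confusion.loc[name].sum())
        if row_sum == 0:
            per_class[name] = float("nan")  # AR undefined: no test samples
        else:
            per_class[name] = 100.0 * confusion.loc[name, name] / row_sum
    defined = [v for v in per_class.values() if np.isfinite(v)]
    ar_mean = float(np.mean(defined)) if defined else float("nan")
    return EvalReport(
        per_class_ar=per_class,
        ar_mean=ar_mean,
        confusion=confusion,
        n_samples=len(true_labels),
    )
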
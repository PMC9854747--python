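"""Self-organizing-map quality classifier.

An 8x8 neuron lattice is trained online on (standardized) selected
feature vectors: each iteration draws one sample, the neuron with the
nearest weight vector wins, and the winner plus its bubble neighborhood
move toward the sample.  After training, each neuron is labeled from a
handful of annotated samples (three per neuron), so the whole classifier
needs labels for only a small fraction of the data; classification of a
new segment is the label of its winning neuron.

Defaults follow the study configuration: 8x8 grid, initial learning rate
0.5, 100,000 iterations, bubble neighborhood.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FecgSqaError, NotTrainedError
from .synthetic_fecg import QualityLevel

__all__ = [
    "SOMModel",
    "BalancedDataset",
    "balance_dataset",
    "train_som",
    "winning_neuron",
    "label_neurons",
    "classify",
    "quantization_error",
    "save_som",
    "load_som",
]


@dataclass
class SOMModel:
    """Trained neuron lattice with optional per-neuron class labels."""

    weights: np.ndarray                # (rows, cols, dim), standardized space
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    feature_names: list
    learning_rate_initial: float
    iterations: int
    neighborhood: str
    seed: int
    qe_trace: list = field(default_factory=list)
    neuron_labels: np.ndarray | None = None   # (rows, cols) ints, -1 unlabeled

    @property
    def grid(self) -> tuple:
        return self.weights.shape[:2]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_std


@dataclass
class BalancedDataset:
    """Class-balanced view of a feature matrix (random undersampling)."""

    X: pd.DataFrame
    labels: list
    kept_indices: np.ndarray
    seed: int

    def __post_init__(self):
        counts = Counter(self.labels)
        if len(set(counts.values())) > 1:
            raise ConfigurationError("BalancedDataset classes are not equal")


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{j}" for j in range(X.shape[1])]


def balance_dataset(X, labels, seed: int = 0) -> BalancedDataset:
    """Randomly undersample majority classes down to the minority count."""
    labels = list(labels)
    if isinstance(X, pd.DataFrame):
        frame = X
    else:
        frame = pd.DataFrame(np.asarray(X, dtype=float))
    if len(frame) != len(labels):
        raise ConfigurationError("X and labels lengths differ")
    counts = Counter(labels)
    for level in QualityLevel:
        if counts[level] == 0:
            raise ConfigurationError(f"class {level.name} absent from labels")
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = []
    for level in (QualityLevel.HIGH, QualityLevel.MEDIUM, QualityLevel.LOW):
        idx = np.flatnonzero([lab == level for lab in labels])
        if len(idx) > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        keep.append(idx)
    kept = np.concatenate(keep)
    return BalancedDataset(
        X=frame.iloc[kept], labels=[labels[i] for i in kept],
        kept_indices=kept, seed=seed)


def train_som(X, grid=(8, 8), learning_rate_initial: float = 0.5,
              iterations: int = 100_000, neighborhood: str = "bubble",
              seed: int = 0, initial_radius: float | None = None,
              qe_trace_points: int = 20) -> SOMModel:
    """Train an online SOM on feature rows.

    Features are standardized with statistics stored in the model, so new
    segments are classified in training-time scale.  Per iteration one
    sample is drawn uniformly with replacement; the winner (minimal
    Euclidean distance, lexicographic tie-break) and all neurons within
    the bubble radius receive the full update ``lr(t) * (x - W)``.  The
    learning rate decays as ``lr0 / (1 + t / (T/2))`` and the radius
    linearly from half the grid down to 1.  Deterministic given ``seed``.
    """
    if neighborhood != "bubble":
        raise ConfigurationError("only the bubble neighborhood is implemented")
    values, names = _as_matrix(X)
    if values.size == 0:
        raise ConfigurationError("empty training matrix")
    if not np.isfinite(values).all():
        raise ConfigurationError("training matrix contains NaN or inf")
    n, d = values.shape
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    std[std == 0] = 1.0
    Z = (values - mean) / std

    rng = np.random.default_rng(seed)
    rows_g, cols_g = grid
    W = rng.standard_normal((rows_g, cols_g, d))
    gi, gj = np.meshgrid(np.arange(rows_g), np.arange(cols_g), indexing="ij")

    r0 = initial_radius if initial_radius is not None else max(grid) / 2.0
    trace_every = max(iterations // max(qe_trace_points, 1), 1)
    qe_trace = [(0, _qe(W, Z))]
    half_t = iterations / 2.0
    for t in range(iterations):
        x = Z[rng.integers(n)]
        diff = W - x
        dist2 = (diff ** 2).sum(axis=2)
        w_flat = int(np.argmin(dist2))            # row-major = lexicographic
        wi, wj = divmod(w_flat, cols_g)
        lr = learning_rate_initial / (1.0 + t / half_t)
        radius = max(1.0, r0 - (r0 - 1.0) * t / iterations)
        mask = (np.abs(gi - wi) <= radius) & (np.abs(gj - wj) <= radius)
        W[mask] += lr * (x - W[mask])
        if (t + 1) % trace_every == 0:
            qe_trace.append((t + 1, _qe(W, Z)))

    return SOMModel(
        weights=W, scaler_mean=mean, scaler_std=std, feature_names=names,
        learning_rate_initial=learning_rate_initial, iterations=iterations,
        neighborhood=neighborhood, seed=seed, qe_trace=qe_trace)


def _qe(W: np.ndarray, Z: np.ndarray) -> float:
    flat = W.reshape(-1, W.shape[-1])
    d2 = ((Z[:, None, :] - flat[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def _winners(model: SOMModel, Z: np.ndarray) -> np.ndarray:
    flat = model.weights.reshape(-1, model.weights.shape[-1])
    d2 = ((Z[:, None, :] - flat[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)                      # row-major tie-break


def winning_neuron(model: SOMModel, x) -> tuple:
    """Grid coordinates of the nearest neuron (lexicographic tie-break)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.weights.shape[-1],):
        raise ConfigurationError(
            f"expected feature dimension {model.weights.shape[-1]}, "
            f"got {x.shape}")
    z = model.standardize(x)
    flat = _winners(model, z[None])[0]
    return divmod(int(flat), model.grid[1])


def quantization_error(model: SOMModel, X) -> float:
    """Mean Euclidean distance from samples to their winning neurons."""
    values, _ = _as_matrix(X)
    if len(values) == 0:
        raise ConfigurationError("empty matrix")
    return _qe(model.weights, model.standardize(values))


def label_neurons(model: SOMModel, X, labels, samples_per_neuron: int = 3,
                  seed: int = 0) -> SOMModel:
    """Assign a quality level to every neuron from a few labeled samples.

    Per neuron: gather the training samples it wins; if at least
    ``samples_per_neuron`` of them, draw that many without replacement and
    take the majority label; with fewer, take the majority of all its
    members.  Ties (all labels distinct, or a 1-1 split) resolve to LOW,
    biasing toward removal sensitivity.  Neurons that win nothing inherit
    the label of the nearest labeled neuron in grid coordinates
    (lexicographic tie-break), so classification always returns a label.
    """
    values, _ = _as_matrix(X)
    labels = list(labels)
    Z = model.standardize(values)
    winners = _winners(model, Z)
    rows_g, cols_g = model.grid
    rng = np.random.default_rng(seed)
    out = np.full((rows_g, cols_g), -1, dtype=int)
    any_winner = False
    for flat in range(rows_g * cols_g):
        members = np.flatnonzero(winners == flat)
        if len(members) == 0:
            continue
        any_winner = True
        if len(members) >= samples_per_neuron:
            chosen = rng.choice(members, size=samples_per_neuron, replace=False)
        else:
            chosen = members
        votes = Counter(int(labels[i]) for i in chosen)
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            label = int(QualityLevel.LOW)          # tie -> conservative
        else:
            label = top[0][0]
        out[divmod(flat, cols_g)] = label
    if not any_winner:
        raise FecgSqaError("no neuron won any training sample")

    # fill empty neurons from the nearest labeled neuron on the grid
    labeled = np.argwhere(out >= 0)
    for i in range(rows_g):
        for j in range(cols_g):
            if out[i, j] >= 0:
                continue
            d2 = ((labeled - np.array([i, j])) ** 2).sum(axis=1)
            best = labeled[np.lexsort((labeled[:, 1], labeled[:, 0], d2))[0]]
            out[i, j] = out[best[0], best[1]]
    model.neuron_labels = out
    return model


def classify(model: SOMModel, X):
    """Quality level(s) of the winning neuron for each input row.

    Accepts a single feature vector or a matrix; returns a single
    ``QualityLevel`` or a list.
    """
    if model.neuron_labels is None:
        raise NotTrainedError("label_neurons must run before classify")
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
        else np.asarray(X, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None]
    Z = model.standardize(arr)
    winners = _winners(model, Z)
    flat_labels = model.neuron_labels.reshape(-1)
    if np.any(flat_labels[winners] < 0):
        raise FecgSqaError("classification hit an unlabeled neuron")
    preds = [QualityLevel(int(flat_labels[w])) for w in winners]
    return preds[0] if single else preds


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def save_som(model: SOMModel, path) -> None:
    payload = {
        "weights": model.weights.tolist(),
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_std": model.scaler_std.tolist(),
        "feature_names": model.feature_names,
        "learning_rate_initial": model.learning_rate_initial,
        "iterations": model.iterations,
        "neighborhood": model.neighborhood,
        "seed": model.seed,
        "qe_trace": [[int(t), float(q)] for t, q in model.qe_trace],
        "neuron_labels": None if model.neuron_labels is None
        else model.neuron_labels.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_som(path) -> SOMModel:
    payload = json.loads(Path(path).read_text())
    model = SOMModel(
        weights=np.asarray(payload["weights"], dtype=float),
        scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
        scaler_std=np.asarray(payload["scaler_std"], dtype=float),
        feature_names=payload["feature_names"],
        learning_rate_initial=payload["learning_rate_initial"],
        iterations=payload["iterations"],
        neighborhood=payload["neighborhood"],
        seed=payload["seed"],
        qe_trace=[tuple(x) for x in payload["qe_trace"]],
    )
    if payload["neuron_labels"] is not None:
        model.neuron_labels = np.asarray(payload["neuron_labels"], dtype=int)
    return model
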
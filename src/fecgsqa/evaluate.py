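"""Classification metrics and the FHR-improvement experiment.

Two evaluation surfaces:

* three-level classification quality (per-class precision/recall/F1,
  weighted averages, confusion matrix);
* fetal-heart-rate estimation error with and without removal of the
  segments classified LOW.  Fetal RR intervals (FRRI, in samples at the
  recording rate) are estimated by a simple documented peak detector;
  FHR = 60 * Fs / FRRI in beats/min.  Reported metrics are the RMSE of
  FRRI (native units: samples), the averaged absolute FHR error (AAE,
  beats/min) and the removal rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .exceptions import ConfigurationError, FecgSqaError
from .synthetic_fecg import QualityLevel

__all__ = [
    "LEVEL_ORDER",
    "ClassificationReport",
    "FHREvaluation",
    "classification_report",
    "estimate_frri",
    "reference_frri",
    "rmse_frri",
    "aae_fhr",
    "removal_rate",
    "fhr_improvement_experiment",
]

#: Fixed class order for confusion matrices and per-class metric tables.
LEVEL_ORDER = (QualityLevel.HIGH, QualityLevel.MEDIUM, QualityLevel.LOW)


@dataclass
class ClassificationReport:
    """Per-class and weighted precision/recall/F1 plus a confusion matrix.

    Confusion-matrix rows are true classes, columns predicted, both in
    ``LEVEL_ORDER``.
    """

    per_class: dict                    # level -> dict(precision, recall, f1)
    weighted: dict                     # dict(precision, recall, f1)
    confusion: np.ndarray              # (3, 3) counts
    support: dict                      # level -> true count

    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def classification_report(true, pred) -> ClassificationReport:
    """Standard multi-class metrics for the three quality levels.

    Classes never predicted get precision 0 with a warning.
    """
    true = list(true)
    pred = list(pred)
    if len(true) != len(pred):
        raise ConfigurationError("true and pred lengths differ")
    order = [int(l) for l in LEVEL_ORDER]
    t = [int(l) for l in true]
    p = [int(l) for l in pred]
    if set(p) - set(order) or set(t) - set(order):
        raise ConfigurationError("labels outside the three-level set")
    if set(order) - set(p):
        missing = [QualityLevel(c).name for c in set(order) - set(p)]
        warnings.warn(f"classes never predicted: {missing}; precision set to 0")
    prec, rec, f1, support = precision_recall_fscore_support(
        t, p, labels=order, zero_division=0)
    wprec, wrec, wf1, _ = precision_recall_fscore_support(
        t, p, labels=order, average="weighted", zero_division=0)
    conf = _sk_confusion(t, p, labels=order)
    per_class = {
        level: {"precision": float(prec[i]), "recall": float(rec[i]),
                "f1": float(f1[i])}
        for i, level in enumerate(LEVEL_ORDER)
    }
    return ClassificationReport(
        per_class=per_class,
        weighted={"precision": float(wprec), "recall": float(wrec),
                  "f1": float(wf1)},
        confusion=conf,
        support={level: int(support[i]) for i, level in enumerate(LEVEL_ORDER)},
    )


def estimate_frri(segment, fs: float | None = None,
                  smooth_ms: float = 50.0, refractory_ms: float = 250.0,
                  threshold_fraction: float = 0.4) -> float:
    """Mean fetal RR interval of a segment, in samples.

    Detector: square the signal, smooth with a ``smooth_ms`` moving
    average, pick local maxima above ``threshold_fraction`` of the
    smoothed maximum with a ``refractory_ms`` minimum spacing, and return
    the mean successive-peak interval.  Returns NaN (missing-estimate
    sentinel) when fewer than two peaks are found.
    """
    x = np.asarray(getattr(segment, "samples", segment), dtype=float)
    if fs is None:
        fs = segment.sampling_frequency
    if len(x) == 0 or not np.any(x):
        return math.nan
    energy = x ** 2
    k = max(int(round(smooth_ms * 1e-3 * fs)), 1)
    smooth = np.convolve(energy, np.ones(k) / k, mode="same")
    height = threshold_fraction * smooth.max()
    peaks, _ = find_peaks(smooth, height=height,
                          distance=max(int(round(refractory_ms * 1e-3 * fs)), 1))
    if len(peaks) < 2:
        return math.nan
    return float(np.diff(peaks).mean())


def reference_frri(beat_times: np.ndarray, fs: float) -> float:
    """Ground-truth mean RR interval in samples from known beat times."""
    beat_times = np.asarray(beat_times, dtype=float)
    if len(beat_times) < 2:
        return math.nan
    return float(np.diff(beat_times).mean() * fs)


def rmse_frri(estimates, references) -> float:
    """Root mean square error between estimated and reference FRRI."""
    e = np.asarray(estimates, dtype=float)
    r = np.asarray(references, dtype=float)
    if e.shape != r.shape:
        raise ConfigurationError("estimates and references lengths differ")
    if e.size == 0:
        raise ConfigurationError("empty FRRI arrays")
    if np.isnan(e).any() or np.isnan(r).any():
        raise ConfigurationError("missing-estimate sentinels must be filtered out")
    return float(np.sqrt(((e - r) ** 2).mean()))


def aae_fhr(estimates_frri, references_frri, fs: float) -> float:
    """Averaged absolute FHR error |60*Fs/est - 60*Fs/ref| in beats/min."""
    e = np.asarray(estimates_frri, dtype=float)
    r = np.asarray(references_frri, dtype=float)
    if e.shape != r.shape or e.size == 0:
        raise ConfigurationError("estimates and references must be equal-length, non-empty")
    if np.any(e <= 0) or np.any(r <= 0):
        raise ConfigurationError("FRRI values must be positive")
    return float(np.abs(60.0 * fs / e - 60.0 * fs / r).mean())


def removal_rate(mask) -> float:
    """Fraction of estimated FHRs removed."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ConfigurationError("empty removal mask")
    return float(mask.mean())


@dataclass
class FHREvaluation:
    """FHR-estimation error summary over a set of evaluated segments."""

    estimates_frri: np.ndarray     # samples
    references_frri: np.ndarray    # samples
    removal_mask: np.ndarray       # True = removed before error computation
    sampling_frequency: float
    rmse: float = field(init=False)
    aae: float = field(init=False)
    removal: float = field(init=False)
    n_segments: int = field(init=False)

    def __post_init__(self):
        keep = ~self.removal_mask
        self.n_segments = int(keep.sum())
        if self.n_segments == 0:
            raise FecgSqaError("all segments were removed; nothing to evaluate")
        self.rmse = rmse_frri(self.estimates_frri[keep],
                              self.references_frri[keep])
        self.aae = aae_fhr(self.estimates_frri[keep],
                           self.references_frri[keep],
                           self.sampling_frequency)
        self.removal = removal_rate(self.removal_mask)


def fhr_improvement_experiment(recordings, som_model, ae_model,
                               selected_features, entropy_params=None,
                               spectrogram_size: int | None = None,
                               window: float = 3.0):
    """Compare FHR error with and without removal of detected LOW segments.

    Each recording is pre-processed, cut into non-overlapping ``window``
    second segments, classified with the trained pipeline artifacts, and
    its FRRI estimated.  Reference FRRI comes from the generator's
    ground-truth beat times.  Segments with a missing estimate or fewer
    than two reference beats are excluded from both branches.

    Returns ``(no_removal, with_removal, info)``; ``info`` records the
    number of evaluated segments and, when the recordings carry
    ground-truth per-block quality labels, the true LOW fraction among
    the evaluated segments (the fair comparator for the removal rate,
    since segments without an FHR estimate produce nothing to remove).
    """
    from .features import build_feature_matrix
    from .preprocess import make_spectrogram, preprocess_recording, segment_signal
    from .som_classifier import classify

    if spectrogram_size is None:
        spectrogram_size = ae_model.architecture.image_size

    estimates, references, predicted_low, true_low = [], [], [], []
    n_total = 0
    for rec in recordings:
        beat_times = rec.meta.get("beat_times")
        if beat_times is None:
            raise ConfigurationError(
                "recordings must carry ground-truth beat_times metadata")
        block_labels = rec.meta.get("block_labels")
        proc = preprocess_recording(rec)
        segments = segment_signal(proc, window=window, overlap=0.0)
        specs = [make_spectrogram(s, size=spectrogram_size) for s in segments]
        X = build_feature_matrix(segments, specs, ae_model, entropy_params)
        preds = classify(som_model, X[selected_features])
        fs = proc.sampling_frequency
        for i, (seg, pred) in enumerate(zip(segments, preds)):
            n_total += 1
            in_win = (beat_times >= seg.start_time) & \
                     (beat_times < seg.start_time + window)
            ref = reference_frri(beat_times[in_win] - seg.start_time, fs)
            est = estimate_frri(seg, fs)
            if math.isnan(ref) or math.isnan(est):
                continue
            estimates.append(est)
            references.append(ref)
            predicted_low.append(pred == QualityLevel.LOW)
            if block_labels is not None and i < len(block_labels):
                true_low.append(block_labels[i] == QualityLevel.LOW)

    estimates = np.asarray(estimates)
    references = np.asarray(references)
    predicted_low = np.asarray(predicted_low, dtype=bool)
    fs = recordings[0].sampling_frequency
    no_removal = FHREvaluation(estimates, references,
                               np.zeros_like(predicted_low), fs)
    with_removal = FHREvaluation(estimates, references, predicted_low, fs)
    info = {
        "n_evaluated": int(len(estimates)),
        "n_segments": int(n_total),
        "true_low_fraction": float(np.mean(true_low)) if true_low else math.nan,
    }
    return no_removal, with_removal, info
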
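"""Signal pre-processing for abdominal fetal-ECG quality assessment.

Raw single-channel recordings are centered and normalized to [-1, 1],
band-pass filtered with a linear-phase Kaiser-window FIR, despiked with a
running-median rule, cut into 3 s windows with 1.5 s overlap, and rendered
as fixed-size 3-channel spectrogram images for the autoencoder feature.

The pipeline order is fixed: center/normalize -> band-pass -> despike ->
segment -> spectrogram.  Filtering always happens at the recording level;
segments are cut from the already-filtered recording.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.transform import resize as _sk_resize

from .exceptions import ConfigurationError, DegenerateSignalError

__all__ = [
    "Recording",
    "Segment",
    "SpectrogramImage",
    "center_normalize",
    "bandpass_filter",
    "remove_spikes",
    "segment_signal",
    "spectrogram_matrix",
    "make_spectrogram",
    "preprocess_recording",
    "read_recording",
    "write_recording",
    "write_segments",
    "read_segments",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """One channel of a sampled FECG signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude values (arbitrary units).
    sampling_frequency : float
        Sampling rate in Hz.
    channel_id, subject_id : str
        Provenance identifiers.
    meta : dict
        Free-form metadata.  The synthetic generator stores ground-truth
        fetal beat times under ``"beat_times"`` (seconds) and, optionally,
        its additive components under ``"components"``.
    """

    samples: np.ndarray
    sampling_frequency: float
    channel_id: str = "ch0"
    subject_id: str = "subject0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_frequency <= 0:
            raise ConfigurationError("sampling_frequency must be > 0")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_frequency

    def replace_samples(self, samples: np.ndarray) -> "Recording":
        return Recording(
            samples=np.asarray(samples, dtype=float),
            sampling_frequency=self.sampling_frequency,
            channel_id=self.channel_id,
            subject_id=self.subject_id,
            meta=dict(self.meta),
        )


@dataclass
class Segment:
    """A 3 s windowed excerpt of a processed recording.

    ``start_time`` is inclusive; windows are half-open
    ``[start_time, start_time + duration)``; sample indices are 0-based.
    """

    samples: np.ndarray
    sampling_frequency: float
    start_time: float = 0.0
    segment_id: str = "seg0"
    label: Optional["QualityLevel"] = None  # noqa: F821 - see synthetic_fecg
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_frequency


@dataclass
class SpectrogramImage:
    """Fixed-size 3-channel rendering of a segment's STFT magnitude."""

    pixels: np.ndarray                 # (size, size, 3), values in [0, 1]
    frequency_range: tuple             # (low_hz, high_hz)
    time_range: tuple                  # (start_s, end_s)
    segment_id: str = "seg0"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ConfigurationError("pixels must have shape (H, W, 3)")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def center_normalize(recording: Recording) -> Recording:
    """Subtract the mean and scale so that max |amplitude| equals 1."""
    x = recording.samples
    if x.size == 0:
        raise DegenerateSignalError("empty recording")
    centered = x - x.mean()
    peak = np.max(np.abs(centered))
    if peak == 0:
        raise DegenerateSignalError("all-constant recording cannot be normalized")
    return recording.replace_samples(centered / peak)


def _kaiser_bandpass_taps(fs: float, low: float, high: float,
                          attenuation_db: float = 60.0,
                          transition_hz: float = 1.0) -> np.ndarray:
    numtaps, beta = signal.kaiserord(attenuation_db, transition_hz / (0.5 * fs))
    numtaps |= 1  # odd length -> integer group delay, exactly linear phase
    return signal.firwin(numtaps, [low, high], pass_zero=False,
                         window=("kaiser", beta), fs=fs)


def bandpass_filter(recording: Recording, low: float = 2.0,
                    high: float = 46.0) -> Recording:
    """Linear-phase Kaiser-window FIR band-pass, group delay compensated.

    Default band [2, 46] Hz retains fetal cardiac activity while rejecting
    baseline wander and mains interference.
    """
    fs = recording.sampling_frequency
    if not (0 < low < high < fs / 2):
        raise ConfigurationError(
            f"band ({low}, {high}) Hz invalid for sampling_frequency {fs} Hz")
    taps = _kaiser_bandpass_taps(fs, low, high)
    # 'same' convolution with an odd symmetric kernel centres the output,
    # i.e. compensates the (numtaps-1)/2 group delay.
    filtered = signal.fftconvolve(recording.samples, taps, mode="same")
    return recording.replace_samples(filtered)


def remove_spikes(recording: Recording, window: int = 9,
                  threshold_sds: float = 8.0) -> Recording:
    """Hampel-style despiking: replace outliers by the running median.

    A sample is a spike when it deviates from the running median (window
    ``window`` samples) by more than ``threshold_sds`` robust standard
    deviations of the residuals.  The robust scale is the larger of
    1.4826 x MAD and the 90th percentile / 1.2816 of the absolute
    residuals; on smooth band-limited signals the running median equals
    the signal over locally monotone stretches, collapsing the MAD to
    zero, and the percentile estimate takes over.  The short default
    window targets millisecond-scale electrode pops while leaving QRS
    complexes (tens of ms wide) intact; if every residual is zero except
    at isolated spikes, exactly those samples are replaced.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 3")
    x = recording.samples
    run_med = ndimage.median_filter(x, size=window, mode="nearest")
    resid = np.abs(x - run_med)
    scale = max(1.4826 * np.median(resid),
                np.percentile(resid, 99) / 2.576)
    mask = resid > threshold_sds * scale if scale > 0 else resid > 0
    out = x.copy()
    out[mask] = run_med[mask]
    return recording.replace_samples(out)


def segment_signal(recording: Recording, window: float = 3.0,
                   overlap: float = 1.5) -> list:
    """Cut a recording into fixed-length windows.

    Hop equals ``window - overlap``; only full windows are emitted and
    start times are exact multiples of the hop.
    """
    if not (0 <= overlap < window):
        raise ConfigurationError("need 0 <= overlap < window")
    fs = recording.sampling_frequency
    win_n = int(round(window * fs))
    hop_n = int(round((window - overlap) * fs))
    n = len(recording.samples)
    if n < win_n:
        warnings.warn("recording shorter than one window; no segments emitted")
        return []
    segments = []
    n_seg = (n - win_n) // hop_n + 1
    for i in range(n_seg):
        s0 = i * hop_n
        segments.append(Segment(
            samples=recording.samples[s0:s0 + win_n].copy(),
            sampling_frequency=fs,
            start_time=s0 / fs,
            segment_id=f"{recording.subject_id}_{recording.channel_id}_{i:04d}",
        ))
    return segments


# -- spectrogram rendering ---------------------------------------------------

def _viridis_lut() -> np.ndarray:
    """256 x 3 colormap lookup table (fixed, perceptually uniform)."""
    import matplotlib
    cmap = matplotlib.colormaps["viridis"]
    return np.asarray(cmap(np.linspace(0.0, 1.0, 256)))[:, :3]


_LUT = None


def _colormap(values: np.ndarray) -> np.ndarray:
    global _LUT
    if _LUT is None:
        _LUT = _viridis_lut()
    idx = np.clip(np.round(values * 255).astype(int), 0, 255)
    return _LUT[idx]


def spectrogram_matrix(segment: Segment, stft_window_ms: float = 128.0,
                       step_ms: float = 5.0, band=(2.0, 60.0),
                       floor_db: float = 40.0):
    """STFT magnitude of a segment, band-limited and normalized to [0, 1].

    Returns ``(freqs, times, matrix)`` with ``matrix`` shaped
    (n_band_bins, n_frames).  Magnitudes are mapped to decibels relative to
    the per-image maximum, floored at ``-floor_db`` dB, then min-max scaled.
    A zero segment yields an all-zero matrix (normalization denominator of
    zero replaced by 1).  The default -40 dB floor clips everything more
    than 40 dB below the per-image peak to one level, so recordings with
    "almost no noise" render identically however small the residual noise
    is; without the clip the rendering is hypersensitive to irrelevant
    sub-noise-floor detail.
    """
    fs = segment.sampling_frequency
    if not (0 <= band[0] < band[1] <= fs / 2):
        raise ConfigurationError(f"band {band} outside (0, Nyquist={fs / 2}) Hz")
    nperseg = int(round(stft_window_ms * 1e-3 * fs))
    step = int(round(step_ms * 1e-3 * fs))
    if nperseg >= len(segment.samples):
        raise ConfigurationError("stft window must be shorter than the segment")
    freqs, times, sxx = signal.spectrogram(
        segment.samples, fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg - step, detrend=False, mode="magnitude")
    keep = (freqs >= band[0]) & (freqs <= band[1])
    sxx = sxx[keep]
    freqs = freqs[keep]
    peak = sxx.max()
    if peak == 0:
        return freqs, times, np.zeros_like(sxx)
    db = 20.0 * np.log10(np.maximum(sxx, peak * 10 ** (-floor_db / 20)) / peak)
    lo, hi = db.min(), db.max()
    denom = (hi - lo) if hi > lo else 1.0
    return freqs, times, (db - lo) / denom


def make_spectrogram(segment: Segment, stft_window_ms: float = 128.0,
                     step_ms: float = 5.0, band=(2.0, 60.0),
                     size: int = 128,
                     floor_db: float = 40.0) -> SpectrogramImage:
    """Render a segment as a ``size x size x 3`` spectrogram image.

    The normalized band-limited STFT magnitude is passed through a fixed
    perceptually uniform colormap and bilinearly resized.  The rendering is
    a pure function of the segment.
    """
    freqs, times, mat = spectrogram_matrix(segment, stft_window_ms,
                                           step_ms, band, floor_db)
    rgb = _colormap(mat)
    pixels = _sk_resize(rgb, (size, size), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    return SpectrogramImage(
        pixels=np.clip(pixels, 0.0, 1.0),
        frequency_range=(float(freqs[0]), float(freqs[-1])),
        time_range=(segment.start_time, segment.start_time + segment.duration),
        segment_id=segment.segment_id,
    )


def preprocess_recording(recording: Recording, low: float = 2.0,
                         high: float = 46.0, spike_window: int = 9,
                         spike_threshold: float = 8.0) -> Recording:
    """Center/normalize, band-pass and despike a recording, in that order."""
    rec = center_normalize(recording)
    rec = bandpass_filter(rec, low=low, high=high)
    return remove_spikes(rec, window=spike_window, threshold_sds=spike_threshold)


# ---------------------------------------------------------------------------
# I/O: two-column delimited text and segment directories
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path) -> None:
    """Write as two-column delimited text ``time_s<TAB>amplitude``."""
    t = np.arange(len(recording.samples)) / recording.sampling_frequency
    np.savetxt(path, np.column_stack([t, recording.samples]),
               fmt="%.6f\t%.8g", header="time_s\tamplitude")


def read_recording(path, channel_id: str = "ch0",
                   subject_id: str = "subject0") -> Recording:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ConfigurationError(f"{path}: expected two columns (time_s, amplitude)")
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-3):
        raise ConfigurationError(f"{path}: time column is not uniformly sampled")
    return Recording(samples=x, sampling_frequency=1.0 / dt[0],
                     channel_id=channel_id, subject_id=subject_id)


def write_segments(segments, directory) -> None:
    """Write per-segment delimited files plus a CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg in segments:
        fname = f"{seg.segment_id}.txt"
        t = seg.start_time + np.arange(len(seg.samples)) / seg.sampling_frequency
        np.savetxt(directory / fname, np.column_stack([t, seg.samples]),
                   fmt="%.6f\t%.8g")
        rows.append({
            "segment_id": seg.segment_id,
            "start_s": seg.start_time,
            "label": "" if seg.label is None else seg.label.name,
            "file": fname,
            "sampling_frequency": seg.sampling_frequency,
        })
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def read_segments(directory) -> list:
    from .synthetic_fecg import QualityLevel

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    segments = []
    for _, row in manifest.iterrows():
        data = np.loadtxt(directory / row["file"])
        label = None
        if isinstance(row["label"], str) and row["label"]:
            label = QualityLevel[row["label"]]
        segments.append(Segment(
            samples=data[:, 1], sampling_frequency=row["sampling_frequency"],
            start_time=row["start_s"], segment_id=row["segment_id"], label=label))
    return segments


def write_spectrogram(image: SpectrogramImage, path) -> None:
    """Write a lossless PNG plus a JSON sidecar with axis ranges."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, image.pixels)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({
        "segment_id": image.segment_id,
        "frequency_range": list(image.frequency_range),
        "time_range": list(image.time_range),
    }))
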
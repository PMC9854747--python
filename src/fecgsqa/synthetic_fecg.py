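"""Synthetic abdominal fetal-ECG generator with graded signal quality.

Real abdominal FECG is a weak quasi-periodic fetal QRS train (roughly
110-160 bpm) buried under a stronger, slower maternal ECG (60-100 bpm),
baseline wander and broadband noise from electrode motion and fetal
movement.  This module emulates those ingredients so that the whole
quality-assessment pipeline can be exercised and tested without clinical
recordings.

Quality levels follow the amplitude of the additive noise relative to the
fetal QRS peak:

* HIGH   - almost no noise (ratio in [0, 0.05] by default),
* MEDIUM - visible noise, far below the heartbeat amplitude ([0.15, 0.4]),
* LOW    - noise amplitude close to the heartbeat amplitude ([0.8, 1.2]),
  plus occasional high-amplitude burst artifacts.

By default the maternal component is omitted, emulating a signal after
maternal-ECG cancellation; a switch turns it back on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError
from .preprocess import Recording, Segment, preprocess_recording, segment_signal

__all__ = [
    "QualityLevel",
    "SynthesisConfig",
    "DEFAULT_QUALITY_RANGES",
    "generate_recording",
    "generate_quality_dataset",
    "generate_mixed_recording",
]


class QualityLevel(IntEnum):
    """Ordinal signal-quality levels, HIGH > MEDIUM > LOW."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


#: Noise-amplitude-to-fetal-QRS-peak ratio ranges defining each level.
DEFAULT_QUALITY_RANGES = {
    QualityLevel.HIGH: (0.0, 0.05),
    QualityLevel.MEDIUM: (0.15, 0.4),
    QualityLevel.LOW: (0.8, 1.2),
}


@dataclass(frozen=True)
class SynthesisConfig:
    """Parameters of one synthetic recording.

    ``noise_amplitude_ratio`` is the typical noise peak (3 standard
    deviations of the band-limited Gaussian noise) divided by the fetal
    QRS peak amplitude.
    """

    duration: float = 60.0               # s
    sampling_frequency: float = 1000.0   # Hz
    fetal_rate: float = 140.0            # beats/min
    maternal_rate: float = 80.0          # beats/min
    fetal_amplitude: float = 1.0         # arbitrary units
    maternal_amplitude: float = 3.0      # arbitrary units
    noise_amplitude_ratio: float = 0.1   # noise peak / fetal QRS peak
    baseline_wander_amplitude: float = 0.3
    rr_jitter_sd: float = 0.01           # s
    include_maternal: bool = False
    include_bursts: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.sampling_frequency <= 0:
            raise ConfigurationError("sampling_frequency must be > 0")
        for name in ("fetal_rate", "maternal_rate"):
            rate = getattr(self, name)
            if not (30.0 < rate < 300.0):
                raise ConfigurationError(f"{name} must lie in (30, 300) bpm")
        if self.noise_amplitude_ratio < 0:
            raise ConfigurationError("noise_amplitude_ratio must be >= 0")
        if self.rr_jitter_sd < 0:
            raise ConfigurationError("rr_jitter_sd must be >= 0")
        if self.fetal_amplitude <= 0:
            raise ConfigurationError("fetal_amplitude must be > 0")


def _ricker(t: np.ndarray, sigma: float) -> np.ndarray:
    """Mexican-hat wavelet with unit peak: (1 - (t/s)^2) exp(-t^2 / 2s^2)."""
    u = (t / sigma) ** 2
    return (1.0 - u) * np.exp(-u / 2.0)


def _beat_times(rate_bpm: float, duration: float, jitter_sd: float,
                rng: np.random.Generator) -> np.ndarray:
    mean_rr = 60.0 / rate_bpm
    t = rng.uniform(0.0, mean_rr)
    times = []
    while t < duration:
        times.append(t)
        rr = mean_rr + rng.normal(0.0, jitter_sd)
        t += max(rr, 0.25 * mean_rr)   # guard against non-physical intervals
    return np.asarray(times)


def _pulse_train(beat_times: np.ndarray, amplitude: float, sigma: float,
                 n: int, fs: float) -> np.ndarray:
    out = np.zeros(n)
    half = int(round(4 * sigma * fs))
    support = np.arange(-half, half + 1)
    wavelet = amplitude * _ricker(support / fs, sigma)
    centers = np.round(beat_times * fs).astype(int)
    for c in centers:
        lo, hi = c - half, c + half + 1
        a, b = max(lo, 0), min(hi, n)
        if a < b:
            out[a:b] += wavelet[a - lo:b - lo]
    return out


def _band_limited_noise(n: int, fs: float, rng: np.random.Generator,
                        low: float = 2.0, high: float = 60.0) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, white)


def generate_recording(config: SynthesisConfig,
                       keep_components: bool = True) -> Recording:
    """Synthesize one abdominal-FECG channel.

    The signal is the sum of a fetal QRS-like Mexican-hat pulse train
    (width ~40 ms) with per-beat RR jitter, an optional maternal pulse
    train (width ~80 ms), a sub-1 Hz sinusoidal baseline wander and
    band-limited (2-60 Hz) Gaussian noise scaled so that its typical peak
    (3 sigma) equals ``noise_amplitude_ratio`` times the fetal QRS peak.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_frequency
    n = int(round(config.duration * fs))

    fetal_beats = _beat_times(config.fetal_rate, config.duration,
                              config.rr_jitter_sd, rng)
    fetal = _pulse_train(fetal_beats, config.fetal_amplitude, 0.007, n, fs)

    maternal = np.zeros(n)
    if config.include_maternal:
        maternal_beats = _beat_times(config.maternal_rate, config.duration,
                                     config.rr_jitter_sd, rng)
        maternal = _pulse_train(maternal_beats, config.maternal_amplitude,
                                0.014, n, fs)
    else:
        rng.uniform(0.0, 1.0)  # keep stream layout stable across the switch

    t = np.arange(n) / fs
    wander_freq = rng.uniform(0.15, 0.45)   # < 1 Hz
    wander_phase = rng.uniform(0.0, 2 * np.pi)
    baseline = config.baseline_wander_amplitude * np.sin(
        2 * np.pi * wander_freq * t + wander_phase)

    noise = np.zeros(n)
    if config.noise_amplitude_ratio > 0:
        noise = _band_limited_noise(n, fs, rng)
        target_peak = config.noise_amplitude_ratio * config.fetal_amplitude
        noise *= target_peak / (3.0 * noise.std())
        if config.include_bursts:
            n_bursts = rng.poisson(config.duration / 10.0)
            for _ in range(n_bursts):
                width = int(rng.uniform(0.3, 1.0) * fs)
                start = rng.integers(0, max(n - width, 1))
                burst = _band_limited_noise(width, fs, rng)
                burst *= 3.0 * target_peak / (3.0 * burst.std())
                noise[start:start + width] += burst

    samples = fetal + maternal + baseline + noise
    meta = {"beat_times": fetal_beats, "config": config}
    if keep_components:
        meta["components"] = {
            "fetal": fetal, "maternal": maternal,
            "baseline": baseline, "noise": noise,
        }
    return Recording(samples=samples, sampling_frequency=fs,
                     channel_id="synthetic", subject_id=f"sim{config.seed}",
                     meta=meta)


def _segment_noise_ratio(components: dict, s0: int, s1: int,
                         fetal_amplitude: float) -> float:
    """Measured within-segment noise-peak / fetal-QRS-peak ratio."""
    noise = components["noise"][s0:s1]
    fetal = components["fetal"][s0:s1]
    qrs_peak = np.max(np.abs(fetal)) if np.any(fetal) else fetal_amplitude
    return float(3.0 * noise.std() / qrs_peak) if noise.size else 0.0


def generate_quality_dataset(n_per_class: int, seed: int = 0,
                             quality_ranges: dict | None = None,
                             base_config: SynthesisConfig | None = None,
                             window: float = 3.0, overlap: float = 1.5,
                             preprocess: bool = True):
    """Generate a balanced, labeled set of 3 s segments.

    For each quality level, 60 s recordings are synthesized with the
    noise-amplitude ratio drawn uniformly from that level's range (LOW
    additionally receives burst artifacts), optionally run through the
    standard pre-processing chain, and cut into overlapping windows; the
    first ``n_per_class`` segments per level are kept.

    Returns ``(segments, labels)`` with exactly ``3 * n_per_class``
    entries, balanced by construction and deterministic given ``seed``.
    Each segment's ``meta`` records its true beat times (relative to the
    segment start), the recording's configured noise ratio and the
    measured within-segment noise-to-QRS ratio.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    ranges = dict(DEFAULT_QUALITY_RANGES)
    if quality_ranges:
        ranges.update(quality_ranges)
    base = base_config or SynthesisConfig()
    rng = np.random.default_rng(seed)

    segments, labels = [], []
    hop = window - overlap
    per_rec = int((base.duration - window) // hop) + 1
    for level in (QualityLevel.HIGH, QualityLevel.MEDIUM, QualityLevel.LOW):
        lo, hi = ranges[level]
        need = n_per_class
        rec_idx = 0
        while need > 0:
            cfg = replace(
                base,
                noise_amplitude_ratio=float(rng.uniform(lo, hi)),
                fetal_rate=float(rng.uniform(110.0, 160.0)),
                include_bursts=(level == QualityLevel.LOW),
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            rec = generate_recording(cfg, keep_components=True)
            components = rec.meta["components"]
            beat_times = rec.meta["beat_times"]
            proc = preprocess_recording(rec) if preprocess else rec
            proc.meta = rec.meta
            for seg in segment_signal(proc, window=window, overlap=overlap):
                if need == 0:
                    break
                s0 = int(round(seg.start_time * proc.sampling_frequency))
                s1 = s0 + len(seg.samples)
                in_win = (beat_times >= seg.start_time) & \
                         (beat_times < seg.start_time + window)
                seg.label = level
                seg.segment_id = f"{level.name.lower()}_{rec_idx:03d}_{seg.segment_id.rsplit('_', 1)[-1]}"
                seg.meta = {
                    "beat_times": beat_times[in_win] - seg.start_time,
                    "configured_noise_ratio": cfg.noise_amplitude_ratio,
                    "noise_qrs_ratio": _segment_noise_ratio(
                        components, s0, s1, cfg.fetal_amplitude),
                    "fetal_rate": cfg.fetal_rate,
                }
                segments.append(seg)
                labels.append(level)
                need -= 1
            rec_idx += 1
            if rec_idx > 10 * (n_per_class // per_rec + 1):
                raise RuntimeError("dataset generation failed to converge")
    return segments, labels


def generate_mixed_recording(low_fraction: float = 0.3, seed: int = 0,
                             base_config: SynthesisConfig | None = None,
                             block: float = 3.0,
                             quality_ranges: dict | None = None) -> Recording:
    """Synthesize a recording whose quality alternates between blocks.

    The recording is divided into consecutive ``block``-second blocks; a
    deterministic fraction ``low_fraction`` of them receives LOW-range
    noise (plus a burst), the rest HIGH-range noise.  Block labels are
    stored under ``meta["block_labels"]``.  Intended for the
    FHR-improvement experiment with non-overlapping segmentation.
    """
    if not (0.0 <= low_fraction <= 1.0):
        raise ConfigurationError("low_fraction must lie in [0, 1]")
    ranges = dict(DEFAULT_QUALITY_RANGES)
    if quality_ranges:
        ranges.update(quality_ranges)
    base = base_config or SynthesisConfig()
    rng = np.random.default_rng(seed)
    cfg = replace(base, noise_amplitude_ratio=0.0,
                  fetal_rate=float(rng.uniform(110.0, 160.0)),
                  seed=int(rng.integers(0, 2 ** 31 - 1)))
    rec = generate_recording(cfg, keep_components=True)
    fs = rec.sampling_frequency
    n = len(rec.samples)
    block_n = int(round(block * fs))
    n_blocks = n // block_n
    n_low = int(round(low_fraction * n_blocks))
    low_blocks = set(rng.choice(n_blocks, size=n_low, replace=False).tolist())

    noise = _band_limited_noise(n, fs, rng)
    noise /= 3.0 * noise.std()          # unit typical-peak noise
    scale = np.zeros(n)
    labels = []
    for b in range(n_blocks):
        level = QualityLevel.LOW if b in low_blocks else QualityLevel.HIGH
        lo, hi = ranges[level]
        ratio = float(rng.uniform(lo, hi))
        scale[b * block_n:(b + 1) * block_n] = ratio * cfg.fetal_amplitude
        labels.append(level)
    scale[n_blocks * block_n:] = scale[n_blocks * block_n - 1] if n_blocks else 0.0
    scaled_noise = noise * scale
    for b in low_blocks:                 # one burst artifact per LOW block
        width = int(0.5 * fs)
        start = b * block_n + int(rng.uniform(0, block_n - width))
        burst = _band_limited_noise(width, fs, rng)
        scaled_noise[start:start + width] += \
            burst * (3.0 * cfg.fetal_amplitude / (3.0 * burst.std()))

    rec.meta["components"]["noise"] = scaled_noise
    rec.meta["block_labels"] = labels
    rec.meta["block_seconds"] = block
    out = rec.replace_samples(rec.samples + scaled_noise)
    out.meta = rec.meta
    return out
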
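"""Per-segment signal-quality features.

Twelve features are computed per 3 s segment, in this fixed order:

====== =====================================================
AppEn  approximate entropy (m=2, r=0.2*sd, Chebyshev)
SampEn sample entropy (self-matches excluded)
SpecEn normalized Shannon entropy of the Welch power spectrum
PEn    normalized permutation entropy (order 3, delay 1)
DFA    detrended fluctuation analysis scaling exponent (DFA-1)
FD     Katz fractal dimension
HFD    Higuchi fractal dimension
kSQI   kurtosis (Pearson, non-excess)
sSQI   skewness
pSQI   relative QRS-band power: P[5,15] / P[5,40] Hz
basSQI one minus relative baseline power: 1 - P[0,1] / P[0,40] Hz
AE_MSE autoencoder spectrogram reconstruction error
====== =====================================================

Low-quality segments are more irregular, so the entropy and fractal
features rise while basSQI falls as noise grows.  All estimators here are
written from their standard definitions; AppEn/SampEn use a KD-tree for
the template counts and are oracle-tested against direct double loops.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import welch
from scipy.spatial import cKDTree

from .exceptions import ConfigurationError, DegenerateSignalError

__all__ = [
    "FEATURE_NAMES",
    "EntropyParams",
    "FeatureVector",
    "approximate_entropy",
    "sample_entropy",
    "spectral_entropy",
    "permutation_entropy",
    "dfa_alpha",
    "katz_fd",
    "higuchi_fd",
    "moment_sqis",
    "psqi",
    "bassqi",
    "extract_features",
    "build_feature_matrix",
]

#: Fixed feature order used everywhere downstream.
FEATURE_NAMES = ["AppEn", "SampEn", "SpecEn", "PEn", "DFA", "FD", "HFD",
                 "kSQI", "sSQI", "pSQI", "basSQI", "AE_MSE"]


@dataclass(frozen=True)
class EntropyParams:
    """Tolerance and embedding settings for the entropy features.

    ``decimation_factor`` down-samples the segment (zero-phase FIR
    anti-aliased) before the time-domain entropy features (AppEn, SampEn,
    PEn) are computed.  At 1 kHz a band-limited (< 46 Hz) segment is
    heavily oversampled, so consecutive-sample embeddings see only the
    smooth local trend; decimating to ~250 Hz matches the embedding time
    scale to the in-band dynamics, which is what makes these entropies
    respond to stochastic noise rather than to the sampling rate.
    """

    embedding_dim: int = 2          # m for AppEn / SampEn
    tolerance_fraction: float = 0.2  # r as a fraction of the segment sd
    permutation_order: int = 3
    permutation_delay: int = 1
    decimation_factor: int = 4

    def __post_init__(self):
        if self.decimation_factor < 1:
            raise ConfigurationError("decimation_factor must be >= 1")
        if self.embedding_dim < 1:
            raise ConfigurationError("embedding_dim must be >= 1")
        if self.tolerance_fraction <= 0:
            raise ConfigurationError("tolerance_fraction must be > 0")
        if self.permutation_order < 2:
            raise ConfigurationError("permutation_order must be >= 2")
        if self.permutation_delay < 1:
            raise ConfigurationError("permutation_delay must be >= 1")


@dataclass
class FeatureVector:
    """Named 12-feature vector for one segment."""

    values: np.ndarray
    segment_id: str = "seg0"
    names: tuple = tuple(FEATURE_NAMES)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """Delay-embedding matrix of shape (n - m + 1, m)."""
    return np.lib.stride_tricks.sliding_window_view(x, m)


def approximate_entropy(x, m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy with self-matches, Chebyshev distance.

    ``r`` is a fraction of the sample standard deviation.  A constant
    sequence returns 0 (every template matches every other).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ConfigurationError(f"sequence too short for AppEn (n={n}, m={m})")
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd

    def phi(mm: int) -> float:
        emb = _embed(x, mm)
        tree = cKDTree(emb)
        counts = tree.query_ball_point(emb, tol, p=np.inf, return_length=True)
        return float(np.mean(np.log(counts / len(emb))))

    return phi(m) - phi(m + 1)


def sample_entropy(x, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy -ln(A/B), self-matches excluded, Chebyshev distance.

    Both template lengths use the first ``n - m`` delay vectors (the
    Richman-Moorman convention).  A constant sequence returns 0; if no
    template pairs match at either length the function returns ``inf``
    (capped later when assembling a feature matrix).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ConfigurationError(f"sequence too short for SampEn (n={n}, m={m})")
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd

    def pair_count(mm: int) -> int:
        emb = _embed(x, mm)[: n - m]
        tree = cKDTree(emb)
        total = tree.count_neighbors(tree, tol, p=np.inf)
        return (total - len(emb)) // 2   # drop self-pairs, unordered

    b = pair_count(m)
    a = pair_count(m + 1)
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def _welch_psd(x: np.ndarray, fs: float):
    # 2 s Hann windows, 50% overlap: 0.5 Hz resolution, enough to separate
    # the 0-1 Hz baseline band of basSQI from the rest of the spectrum
    nperseg = min(len(x), int(round(2 * fs)))
    return welch(x, fs=fs, window="hann", nperseg=nperseg,
                 noverlap=nperseg // 2, detrend="constant")


def spectral_entropy(x, fs: float) -> float:
    """Shannon entropy of the normalized Welch PSD, scaled to [0, 1]."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        raise DegenerateSignalError("constant signal has no spectral entropy")
    _, pxx = _welch_psd(x, fs)
    p = pxx / pxx.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(len(pxx)))


def permutation_entropy(x, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy of ordinal patterns, in [0, 1].

    Ties are broken by order of appearance (stable argsort).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < order * delay + 1:
        raise ConfigurationError("sequence too short for permutation entropy")
    strided = np.lib.stride_tricks.sliding_window_view(x, (order - 1) * delay + 1)
    windows = strided[:, ::delay]
    patterns = np.argsort(windows, axis=1, kind="stable")
    base = order ** np.arange(order)
    codes = (patterns * base).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / math.log(math.factorial(order)))


def dfa_alpha(x, n_sizes: int = 16) -> float:
    """DFA-1 scaling exponent.

    Cumulative-sum profile, per-box linear detrending over ~``n_sizes``
    log-spaced box sizes from 4 to n/4, least-squares slope of
    log F(s) vs log s.  White noise gives alpha ~ 0.5, a random walk
    ~ 1.5.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 64:
        raise ConfigurationError("sequence too short for DFA (need >= 64)")
    profile = np.cumsum(x - x.mean())
    sizes = np.unique(np.geomspace(4, n // 4, n_sizes).astype(int))
    flucts = []
    for s in sizes:
        n_boxes = n // s
        boxes = profile[: n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s)
        # per-box linear fit via closed-form least squares
        t_mean = t.mean()
        denom = ((t - t_mean) ** 2).sum()
        slope = ((boxes - boxes.mean(axis=1, keepdims=True)) * (t - t_mean)).sum(axis=1) / denom
        intercept = boxes.mean(axis=1) - slope * t_mean
        resid = boxes - (slope[:, None] * t + intercept[:, None])
        flucts.append(np.sqrt((resid ** 2).mean()))
    coeffs = np.polyfit(np.log(sizes), np.log(flucts), 1)
    return float(coeffs[0])


def katz_fd(x) -> float:
    """Katz fractal dimension log10(n) / (log10(n) + log10(d/L))."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ConfigurationError("need at least 2 samples for Katz FD")
    dists = np.abs(np.diff(x))
    path = dists.sum()
    if path == 0:
        return 1.0
    d = np.max(np.abs(x - x[0]))
    n = len(x) - 1
    if d == 0:
        return 1.0
    return float(math.log10(n) / (math.log10(n) + math.log10(d / path)))


def higuchi_fd(x, kmax: int = 10) -> float:
    """Higuchi fractal dimension from curve lengths L(k), k = 1..kmax."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 * kmax:
        raise ConfigurationError(f"sequence too short for Higuchi FD (n={n}, kmax={kmax})")
    lengths = []
    for k in range(1, kmax + 1):
        lk = 0.0
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            norm = (n - 1) / ((len(idx) - 1) * k)
            lk += np.abs(np.diff(x[idx])).sum() * norm / k
        lengths.append(lk / k)
    ks = np.arange(1, kmax + 1)
    coeffs = np.polyfit(np.log(1.0 / ks), np.log(lengths), 1)
    return float(coeffs[0])


def moment_sqis(x) -> tuple:
    """(kSQI, sSQI): Pearson kurtosis and skewness of the signal."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        raise DegenerateSignalError("constant signal has undefined moments")
    k = float(stats.kurtosis(x, fisher=False, bias=True))
    s = float(stats.skew(x, bias=True))
    return k, s


def _band_power(freqs: np.ndarray, pxx: np.ndarray, lo: float, hi: float) -> float:
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return float(pxx[mask].sum())
    return float(np.trapezoid(pxx[mask], freqs[mask]))


def psqi(x, fs: float) -> float:
    """Relative QRS-band power P[5,15] / P[5,40] (Welch + trapezoid)."""
    if fs < 80:
        raise ConfigurationError("psqi requires sampling_frequency >= 80 Hz")
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        raise DegenerateSignalError("constant signal")
    freqs, pxx = _welch_psd(x, fs)
    denom = _band_power(freqs, pxx, 5.0, 40.0)
    if denom == 0:
        raise DegenerateSignalError("no power in the 5-40 Hz band")
    return float(np.clip(_band_power(freqs, pxx, 5.0, 15.0) / denom, 0.0, 1.0))


def bassqi(x, fs: float) -> float:
    """One minus the relative baseline power: 1 - P[0,1] / P[0,40]."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        raise DegenerateSignalError("constant signal")
    freqs, pxx = _welch_psd(x, fs)
    denom = _band_power(freqs, pxx, 0.0, 40.0)
    if denom == 0:
        raise DegenerateSignalError("no power in the 0-40 Hz band")
    return float(np.clip(1.0 - _band_power(freqs, pxx, 0.0, 1.0) / denom, 0.0, 1.0))


def extract_features(segment, spectrogram=None, ae=None,
                     params: EntropyParams | None = None) -> FeatureVector:
    """Compute the 12-feature vector for one segment.

    ``AE_MSE`` requires a trained autoencoder and the segment's
    spectrogram; pass ``ae=None`` to fill it with NaN (e.g. before the
    autoencoder is trained).  Errors from individual features are
    re-raised with the feature name attached.
    """
    params = params or EntropyParams()
    x = segment.samples
    fs = segment.sampling_frequency
    m, r = params.embedding_dim, params.tolerance_fraction
    q = params.decimation_factor
    if q > 1:
        from scipy.signal import decimate
        xe = decimate(x, q, ftype="fir", zero_phase=True)
    else:
        xe = x

    calculators = {
        "AppEn": lambda: approximate_entropy(xe, m, r),
        "SampEn": lambda: sample_entropy(xe, m, r),
        "SpecEn": lambda: spectral_entropy(x, fs),
        "PEn": lambda: permutation_entropy(xe, params.permutation_order,
                                           params.permutation_delay),
        "DFA": lambda: dfa_alpha(x),
        "FD": lambda: katz_fd(x),
        "HFD": lambda: higuchi_fd(x),
    }
    values = {}
    for name, fn in calculators.items():
        try:
            values[name] = fn()
        except Exception as exc:
            raise type(exc)(f"feature {name}: {exc}") from exc
    try:
        values["kSQI"], values["sSQI"] = moment_sqis(x)
        values["pSQI"] = psqi(x, fs)
        values["basSQI"] = bassqi(x, fs)
    except Exception as exc:
        raise type(exc)(f"feature SQI: {exc}") from exc
    if ae is not None:
        from .spectrogram_ae import ae_mse
        if spectrogram is None:
            raise ConfigurationError("AE_MSE requires the segment's spectrogram")
        values["AE_MSE"] = ae_mse(ae, spectrogram)
    else:
        values["AE_MSE"] = math.nan
    return FeatureVector(
        values=np.array([values[n] for n in FEATURE_NAMES]),
        segment_id=segment.segment_id)


def build_feature_matrix(segments, spectrograms=None, ae=None,
                         params: EntropyParams | None = None) -> pd.DataFrame:
    """Assemble per-segment feature vectors into a DataFrame.

    Infinite sample-entropy sentinels (no template matches) are capped at
    ln of the template-pair-count upper bound so downstream selection and
    classification receive finite numbers; a warning is logged when the
    cap fires.
    """
    params = params or EntropyParams()
    spectrograms = spectrograms or [None] * len(segments)
    rows, ids = [], []
    for seg, spec in zip(segments, spectrograms):
        fv = extract_features(seg, spec, ae, params)
        rows.append(fv.values)
        ids.append(seg.segment_id)
    X = pd.DataFrame(np.vstack(rows), index=ids, columns=FEATURE_NAMES)
    if np.isinf(X["SampEn"]).any():
        n = len(segments[0].samples) - params.embedding_dim
        cap = math.log(n * (n - 1) / 2)
        warnings.warn("SampEn had no template matches for some segments; "
                      f"capping at ln(pair bound) = {cap:.3f}")
        X["SampEn"] = X["SampEn"].replace(math.inf, cap)
    return X
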
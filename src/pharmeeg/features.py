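"""Amplitude-spectral characterisation of 6-channel ECoG.

Each recording is reduced to a fixed vector of 132 named values: per
channel, four whole-signal statistics (mean amplitude, maximum
amplitude, amplitude SD, Lempel-Ziv compression ratio) and, for each of
six rhythm entities (delta, theta, alpha, the full beta range and its
low/high-frequency halves), the mean band-filtered amplitude, the
rhythm index and the mean spectral power.  A drug administration is
then summarised by the element-wise ratio of the post-injection vector
to the pre-injection vector ("effect vector").

Spectral estimation follows the averaged tapered-epoch periodogram: the
recording is cut into 5-s epochs with 30 % overlap, each epoch is
truncated to the first 2048 samples (keeping the FFT bin spacing at
fs/2048), Hann-tapered and transformed; squared magnitudes are
normalised so the one-sided spectrum sums to the window-gain-corrected
variance (Parseval) and averaged across epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sps

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InputError,
    SchemaError,
)
from .io import CHANNELS, EcogRecording

#: Canonical passband of the acquisition chain, Hz.
PASSBAND: tuple[float, float] = (0.5, 35.0)

#: Half-open rhythm intervals that partition the passband exactly.
PARTITION_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta_lf": (14.0, 20.0),
    "beta_hf": (20.0, 35.0),
}

#: Band entities reported per channel; ``beta`` is the union of its halves.
BAND_ENTITIES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 35.0),
    "beta_lf": (14.0, 20.0),
    "beta_hf": (20.0, 35.0),
}

SIGNAL_METRICS: tuple[str, ...] = ("mean_amplitude", "max_amplitude", "sd_amplitude", "lz_ratio")
BAND_METRICS: tuple[str, ...] = ("mean_amplitude", "rhythm_index", "mean_power")


@dataclass(frozen=True)
class BandScheme:
    """Frequency-band layout used for all spectral features."""

    passband: tuple[float, float] = PASSBAND
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_ENTITIES)
    )
    partition: tuple[str, ...] = ("delta", "theta", "alpha", "beta_lf", "beta_hf")

    def __post_init__(self) -> None:
        lo, hi = self.passband
        if not 0 < lo < hi:
            raise ConfigurationError(f"invalid passband {self.passband}")
        for name, (b_lo, b_hi) in self.bands.items():
            if not lo <= b_lo < b_hi <= hi:
                raise ConfigurationError(f"band {name!r}={b_lo, b_hi} outside passband {self.passband}")
        edges = [self.bands[name] for name in self.partition]
        if edges[0][0] != lo or edges[-1][1] != hi:
            raise ConfigurationError("partition bands do not span the passband")
        for (a_lo, a_hi), (b_lo, b_hi) in zip(edges, edges[1:]):
            if a_hi != b_lo:
                raise ConfigurationError("partition bands are not contiguous")


@dataclass(frozen=True)
class SpectralParams:
    """Averaged-periodogram parameters (5-s epochs, 30 % overlap, 2048-pt FFT)."""

    fs: float = 500.0
    epoch_s: float = 5.0
    overlap_frac: float = 0.30
    nfft: int = 2048
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.epoch_s <= 0:
            raise ConfigurationError("fs and epoch_s must be positive")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ConfigurationError(f"overlap_frac must lie in [0, 1), got {self.overlap_frac}")
        if self.nfft < 8:
            raise ConfigurationError(f"nfft too small: {self.nfft}")


def feature_names(scheme: BandScheme | None = None) -> list[str]:
    """Canonical ordered names of the 132 features (``channel|entity|metric``)."""
    scheme = scheme or BandScheme()
    names: list[str] = []
    for ch in CHANNELS:
        names.extend(f"{ch}|signal|{m}" for m in SIGNAL_METRICS)
        for band in scheme.bands:
            names.extend(f"{ch}|{band}|{m}" for m in BAND_METRICS)
    return names


# ---------------------------------------------------------------------------
# spectral estimation


def compute_psd(
    rec: EcogRecording | np.ndarray,
    params: SpectralParams | None = None,
    *,
    fs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged tapered-epoch power spectrum.

    Returns ``(freqs, psd)`` where ``psd`` has one row per channel (or is
    1-D for a 1-D input) in uV^2 per frequency bin; summing the bins of
    one row recovers the window-gain-corrected variance of the analysed
    epochs.
    """
    params = params or SpectralParams()
    if isinstance(rec, EcogRecording):
        x = rec.samples
        fs = rec.fs
    else:
        x = np.asarray(rec, dtype=float)
        fs = params.fs if fs is None else fs
    if abs(fs - params.fs) > 1e-9:
        raise ConfigurationError(
            f"sampling rate {fs} Hz does not match SpectralParams.fs={params.fs} Hz"
        )
    n = x.shape[-1]
    epoch_len = int(round(params.epoch_s * fs))
    if n < epoch_len:
        raise InputError(
            f"recording of {n} samples is shorter than one {params.epoch_s}-s epoch "
            f"({epoch_len} samples)"
        )
    step = max(1, int(round(epoch_len * (1.0 - params.overlap_frac))))
    m = min(params.nfft, epoch_len)  # epochs longer than nfft are truncated
    w = sps.get_window(params.window, m, fftbins=True)
    wss = float(np.sum(w * w))
    acc = None
    count = 0
    for start in range(0, n - epoch_len + 1, step):
        seg = x[..., start : start + m]
        seg = seg - seg.mean(axis=-1, keepdims=True)
        spec = np.fft.rfft(seg * w, n=params.nfft, axis=-1)
        p = spec.real**2 + spec.imag**2
        # one-sided: double everything except DC (and Nyquist when nfft even)
        p[..., 1:] *= 2.0
        if params.nfft % 2 == 0:
            p[..., -1] /= 2.0
        acc = p if acc is None else acc + p
        count += 1
    # DFT Parseval: sum_k |X_k|^2 = nfft * sum_t y_t^2, and sum_t (w x)_t^2
    # ~= wss * var(x); dividing by nfft*wss makes the bins sum to the
    # window-gain-corrected variance of the analysed epochs.
    psd = acc / (count * params.nfft * wss)
    freqs = np.fft.rfftfreq(params.nfft, d=1.0 / fs)
    return freqs, psd


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (freqs >= lo) & (freqs < hi)


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Mean spectral power (uV^2) over the bins whose centre lies in ``band``."""
    mask = _band_mask(freqs, band)
    if not mask.any():
        raise ConfigurationError(f"band {band} contains no frequency bins")
    return np.asarray(psd)[..., mask].mean(axis=-1)


def rhythm_index(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float],
    passband: tuple[float, float] = PASSBAND,
) -> np.ndarray:
    """Fraction of the spectral area inside ``band`` relative to the passband."""
    band_mask = _band_mask(freqs, band)
    total_mask = _band_mask(freqs, passband)
    if not band_mask.any():
        raise ConfigurationError(f"band {band} contains no frequency bins")
    psd = np.asarray(psd)
    total = psd[..., total_mask].sum(axis=-1)
    if np.any(total <= 0):
        raise DegenerateInputError("zero total spectral area in passband")
    return psd[..., band_mask].sum(axis=-1) / total


# ---------------------------------------------------------------------------
# amplitude statistics


def amplitude_stats(x: np.ndarray) -> tuple[float, float, float]:
    """(mean amplitude, max amplitude, amplitude SD) of one channel.

    Amplitude is the absolute deviation from the mean; the SD is the
    population standard deviation of the samples.
    """
    x = np.asarray(x, dtype=float)
    d = x - x.mean()
    a = np.abs(d)
    return float(a.mean()), float(a.max()), float(d.std())


@lru_cache(maxsize=64)
def _band_sos(lo: float, hi: float, fs: float, order: int = 4) -> np.ndarray:
    return sps.butter(order, [lo, hi], btype="bandpass", output="sos", fs=fs)


def band_filtered(
    x: np.ndarray,
    band: tuple[float, float],
    fs: float,
    *,
    order: int = 4,
    trim_s: float = 1.0,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, edge transients trimmed."""
    x = np.asarray(x, dtype=float)
    y = sps.sosfiltfilt(_band_sos(band[0], band[1], float(fs), order), x, axis=-1)
    trim = int(round(trim_s * fs))
    if y.shape[-1] > 2 * trim + 1:
        y = y[..., trim : y.shape[-1] - trim]
    return y


# ---------------------------------------------------------------------------
# Lempel-Ziv compression ratio


@njit(cache=False)
def _lz76_phrases(s: np.ndarray) -> int:  # pragma: no cover - jitted
    """Number of phrases in the LZ76 exhaustive history of a symbol array."""
    n = s.size
    if n == 0:
        return 0
    if n == 1:
        return 1
    c = 1
    l = 1
    i = 0
    k = 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lz76_complexity(symbols: Sequence[int] | np.ndarray | str) -> int:
    """LZ76 phrase count ``c(n)`` of a symbol sequence.

    Accepts a binary string (e.g. ``"0001101001000101"``) or an integer
    array.  The count follows the exhaustive-history production parsing,
    including the final (possibly incomplete) phrase.
    """
    if isinstance(symbols, str):
        arr = np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)
    else:
        arr = np.ascontiguousarray(symbols, dtype=np.uint8)
    return int(_lz76_phrases(arr))


def lz_ratio(x: np.ndarray) -> float:
    """Compression ratio ``n / (c(n) * log2 n)`` of the median-binarised signal.

    Oriented so that more repeatable signals score *higher*: an i.i.d.
    random binary sequence tends to 1 for large ``n`` while a constant
    signal attains the maximum for its length.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise InputError(f"lz_ratio needs at least 2 samples, got {n}")
    binary = (x > np.median(x)).astype(np.uint8)
    c = int(_lz76_phrases(binary))
    return n / (c * math.log2(n))


# ---------------------------------------------------------------------------
# assembly


def extract_features(
    rec: EcogRecording,
    scheme: BandScheme | None = None,
    params: SpectralParams | None = None,
) -> pd.Series:
    """Compute the canonical 132-value feature vector of one recording."""
    scheme = scheme or BandScheme()
    params = params or SpectralParams(fs=rec.fs)
    rec.validate()
    freqs, psd = compute_psd(rec, params)
    values: dict[str, float] = {}
    for ci, ch in enumerate(rec.channels):
        x = rec.samples[ci]
        mean_a, max_a, sd_a = amplitude_stats(x)
        values[f"{ch}|signal|mean_amplitude"] = mean_a
        values[f"{ch}|signal|max_amplitude"] = max_a
        values[f"{ch}|signal|sd_amplitude"] = sd_a
        values[f"{ch}|signal|lz_ratio"] = lz_ratio(x)
    for band_name, band in scheme.bands.items():
        filtered = band_filtered(rec.samples, band, rec.fs)  # all channels at once
        d = filtered - filtered.mean(axis=-1, keepdims=True)
        band_amp = np.abs(d).mean(axis=-1)
        ri = rhythm_index(freqs, psd, band, scheme.passband)
        bp = band_power(freqs, psd, band)
        for ci, ch in enumerate(rec.channels):
            values[f"{ch}|{band_name}|mean_amplitude"] = float(band_amp[ci])
            values[f"{ch}|{band_name}|rhythm_index"] = float(ri[ci])
            values[f"{ch}|{band_name}|mean_power"] = float(bp[ci])
    out = pd.Series(values, name=rec.record_id)
    return out.reindex(feature_names(scheme))


def effect_ratio(
    pre: pd.Series,
    post: pd.Series,
    *,
    tiny: float = 1e-12,
) -> pd.Series:
    """Element-wise post/pre feature ratio (the per-record drug-effect vector)."""
    if list(pre.index) != list(post.index):
        raise SchemaError("pre and post feature vectors have different schemas")
    pre_v = pre.to_numpy(float)
    post_v = post.to_numpy(float)
    if np.any(pre_v <= tiny):
        name = pre.index[int(np.argmax(pre_v <= tiny))]
        raise DegenerateInputError(
            f"degenerate baseline: pre-injection feature {name!r} is <= {tiny}"
        )
    return pd.Series(post_v / pre_v, index=pre.index, name=post.name)


def pair_effect_vector(
    pre: EcogRecording,
    post: EcogRecording,
    scheme: BandScheme | None = None,
    params: SpectralParams | None = None,
) -> pd.Series:
    """Extract features from a pre/post pair and return their ratio vector."""
    return effect_ratio(
        extract_features(pre, scheme, params), extract_features(post, scheme, params)
    )


def panel_effect_matrix(
    pairs: Iterable[tuple[EcogRecording, EcogRecording]],
    scheme: BandScheme | None = None,
    params: SpectralParams | None = None,
) -> pd.DataFrame:
    """Effect matrix for a collection of paired recordings.

    Returns one row per pair with the metadata columns ``record_id``,
    ``animal_id`` and ``group`` followed by the 132 ratio features.
    """
    rows = []
    for pre, post in pairs:
        ratios = pair_effect_vector(pre, post, scheme, params)
        row = {"record_id": post.record_id, "animal_id": post.animal_id, "group": post.group}
        row.update(ratios.to_dict())
        rows.append(row)
    if not rows:
        raise InputError("no paired recordings supplied")
    return pd.DataFrame(rows)
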
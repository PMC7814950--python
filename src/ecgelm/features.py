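"""Hybrid per-beat features: four RR intervals plus final-level DWT coefficients.

Each beat is described by

* four RR-interval features (seconds) capturing the local rhythm:
  ``rr_prev`` (interval to the previous R peak), ``rr_post`` (interval to
  the next), ``rr_short`` (mean of the up-to-``l`` most recent previous
  intervals, default l=10) and ``rr_long`` (mean of the previous intervals
  inside the last ``d`` minutes, default d=5);
* the approximation and detail coefficients at the last level of a
  discrete wavelet transform of the beat segment (Mallat cascade:
  repeated low/high-pass filtering with dyadic downsampling, symmetric
  signal extension).  With the defaults — a 234-sample segment, the Haar
  wavelet ``db1`` and 5 levels — this contributes 8 + 8 = 16 coefficients,
  for a 20-entry feature vector in total.

Features are z-scored with statistics fitted on training data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .ecg_io import BeatAnnotation, EcgRecord
from .preprocess import BaselineFilterConfig, remove_baseline
from .segment import (
    DEFAULT_POST_SECONDS,
    DEFAULT_PRE_SECONDS,
    BeatSegment,
    segment_beats,
)

logger = logging.getLogger(__name__)

#: Representative wavelet of each of the four families compared for this
#: task: Daubechies, biorthogonal, reverse biorthogonal, symlet.
SUPPORTED_WAVELETS = ("db1", "bior1.3", "rbio3.1", "sym2")


@dataclass(frozen=True)
class RrConfig:
    """Parameters of the RR-interval features.

    ``l`` is the short-term averaging depth in beats; ``d_minutes`` the
    long-term averaging window in minutes.
    """

    l: int = 10
    d_minutes: float = 5.0

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError(f"l must be >= 1, got {self.l}")
        if not self.d_minutes > 0:
            raise ValueError(f"d_minutes must be positive, got {self.d_minutes}")


@dataclass(frozen=True)
class WaveletConfig:
    """Wavelet family and decomposition depth for the time-frequency features.

    ``mode`` is the signal-extension convention; the default symmetric
    (half-sample) extension gives per-level coefficient length
    ``floor((n + f - 1) / 2)`` for input length n and filter length f.
    """

    wavelet: str = "db1"
    level: int = 5
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError(f"level must be >= 1, got {self.level}")
        pywt.Wavelet(self.wavelet)  # raises on unknown names


def max_wavelet_level(n_samples: int, wavelet: str) -> int:
    """Deepest useful decomposition level for a segment of ``n_samples``."""
    return pywt.dwt_max_level(n_samples, pywt.Wavelet(wavelet))


def _check_level(n_samples: int, config: WaveletConfig) -> None:
    max_level = max_wavelet_level(n_samples, config.wavelet)
    if config.level > max_level:
        raise ValueError(
            f"level {config.level} too deep for a {n_samples}-sample segment "
            f"with wavelet {config.wavelet}; maximum admissible level is {max_level}"
        )


def wavelet_features(
    segment: BeatSegment | np.ndarray, config: WaveletConfig = WaveletConfig()
) -> np.ndarray:
    """Final-level DWT coefficients of a beat segment, cA then cD.

    Runs the full Mallat cascade to ``config.level`` and returns the
    level-``level`` approximation coefficients concatenated with the
    level-``level`` detail coefficients, each in natural time order.
    """
    x = segment.samples if isinstance(segment, BeatSegment) else np.asarray(segment, float)
    _check_level(len(x), config)
    coeffs = pywt.wavedec(x, config.wavelet, mode=config.mode, level=config.level)
    return np.concatenate([coeffs[0], coeffs[1]])


def coefficient_count(n_samples: int, wavelet: str, level: int) -> int:
    """Total cA+cD count at the final level, by the length recurrence.

    Applies ``n -> floor((n + f - 1) / 2)`` per level (symmetric
    extension, filter length f) and returns twice the final length, since
    approximation and detail branches always share it.
    """
    _check_level(n_samples, WaveletConfig(wavelet=wavelet, level=level))
    f = pywt.Wavelet(wavelet).dec_len
    n = n_samples
    for _ in range(level):
        n = (n + f - 1) // 2
    return 2 * n


def rr_features(
    r_indices: Sequence[int] | np.ndarray,
    i: int,
    fs: float,
    config: RrConfig = RrConfig(),
) -> tuple[float, float, float, float]:
    """The four RR-interval features (seconds) of beat ``i``.

    ``r_indices`` are the R-peak sample positions of the whole record in
    order; beat ``i`` must be interior (both neighbours exist).

    ``rr_short`` averages the up-to-``l`` most recent previous intervals,
    the most recent of which is ``rr_prev`` itself.  ``rr_long`` averages
    the previous intervals whose defining R peaks both lie within
    ``d_minutes`` before the current R peak (again including the interval
    ending at beat ``i``); if no interval fits entirely inside the
    window — only possible very early in a record — it falls back to
    ``rr_short``, logged.
    """
    r = np.asarray(r_indices, dtype=np.int64)
    if r.size < 3:
        raise ValueError("need at least 3 beats to compute RR features")
    if not 0 < i < r.size - 1:
        raise ValueError(f"beat {i} is not interior (0 < i < {r.size - 1} required)")
    rr_prev = (r[i] - r[i - 1]) / fs
    rr_post = (r[i + 1] - r[i]) / fs

    intervals = np.diff(r[: i + 1]) / fs  # previous intervals, oldest first
    rr_short = float(np.mean(intervals[-config.l:]))

    horizon = r[i] - config.d_minutes * 60.0 * fs
    starts = r[:i]  # r_{k-1} of each previous interval
    in_window = starts >= horizon
    if np.any(in_window):
        rr_long = float(np.mean(intervals[in_window]))
    else:
        logger.debug("no complete interval within %g min before beat %d; "
                     "falling back to short-term RR", config.d_minutes, i)
        rr_long = rr_short
    return float(rr_prev), float(rr_post), rr_short, rr_long


def assemble_features(
    segments: Sequence[BeatSegment],
    r_indices: Sequence[int] | np.ndarray,
    fs: float,
    rr_config: RrConfig = RrConfig(),
    wavelet_config: WaveletConfig = WaveletConfig(),
) -> tuple[np.ndarray, list[str]]:
    """Build the beats x features matrix for a list of beat segments.

    Row order follows segment order; columns are ``rr_prev, rr_post,
    rr_short, rr_long`` then the final-level cA and cD coefficients.
    Segments anchored at the first or last beat of the record (where
    ``rr_prev``/``rr_post`` are undefined) are skipped with a logged
    count.
    """
    r = np.asarray(r_indices, dtype=np.int64)
    rows: list[np.ndarray] = []
    labels: list[str] = []
    skipped = 0
    n_cols: int | None = None
    for seg in segments:
        i = int(np.searchsorted(r, seg.annotation.r_index))
        if i >= r.size or r[i] != seg.annotation.r_index:
            raise ValueError(
                f"segment R index {seg.annotation.r_index} not found in r_indices"
            )
        if i == 0 or i == r.size - 1:
            skipped += 1
            continue
        rr = rr_features(r, i, fs, rr_config)
        wav = wavelet_features(seg, wavelet_config)
        rows.append(np.concatenate([rr, wav]))
        labels.append(seg.annotation.label)
        n_cols = rows[-1].size
    if skipped:
        logger.info("skipped %d boundary beats without both RR neighbours", skipped)
    if not rows:
        # preserve the column count so downstream shapes stay meaningful
        if n_cols is None:
            probe = wavelet_features(
                np.zeros(segments[0].pre_samples + segments[0].post_samples)
                if segments else np.zeros(234),
                wavelet_config,
            )
            n_cols = 4 + probe.size
        return np.empty((0, n_cols)), []
    return np.vstack(rows), labels


def extract_beat_features(
    record: EcgRecord,
    annotations: list[BeatAnnotation],
    rr_config: RrConfig = RrConfig(),
    wavelet_config: WaveletConfig = WaveletConfig(),
    pre_seconds: float = DEFAULT_PRE_SECONDS,
    post_seconds: float = DEFAULT_POST_SECONDS,
    baseline_config: BaselineFilterConfig | None = BaselineFilterConfig(),
) -> tuple[np.ndarray, list[str]]:
    """Full per-record pipeline: baseline removal, segmentation, features.

    Pass ``baseline_config=None`` to skip baseline-wander removal.
    """
    if baseline_config is not None:
        record = remove_baseline(record, baseline_config)
    segments = segment_beats(record, annotations, pre_seconds, post_seconds)
    r_indices = [a.r_index for a in annotations]
    return assemble_features(segments, r_indices, record.fs, rr_config, wavelet_config)


# ---------------------------------------------------------------------------
# z-score standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-score state ``x* = (x - mu) / sigma``.

    Fitted on training data only; ``sigma`` uses the population convention
    (divide by N) so the transformed training matrix has unit variance
    exactly.  Zero-variance columns get ``sigma = 1`` (feature passes
    through centred).
    """

    mu: np.ndarray
    sigma: np.ndarray


def fit_standardizer(train_matrix: np.ndarray) -> Standardizer:
    """Fit per-column mean and population standard deviation."""
    X = np.asarray(train_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows to fit")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)  # population (ddof=0)
    degenerate = sigma == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance feature column(s); sigma set to 1", int(degenerate.sum())
        )
        sigma = np.where(degenerate, 1.0, sigma)
    return Standardizer(mu=mu, sigma=sigma)


def apply_standardizer(standardizer: Standardizer, matrix: np.ndarray) -> np.ndarray:
    """Transform a matrix with previously fitted statistics."""
    X = np.asarray(matrix, dtype=float)
    return (X - standardizer.mu) / standardizer.sigma
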
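"""Baseline-wander removal with a two-stage median filter.

Low-frequency drift of the ECG baseline (respiration, electrode motion)
is estimated by cascading two running median filters and subtracted from
the signal.  The first, shorter window (default 0.2 s) flattens the P
wave and QRS complex; the second, longer window (default 0.6 s) flattens
the T wave, leaving only the slow baseline, which is then removed.  The
windows are the conventional choice for the physiological wave durations
(PR interval 0.12-0.22 s, QT interval < ~0.45 s) and are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.ndimage import median_filter

from .ecg_io import EcgRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineFilterConfig:
    """Window lengths (seconds) of the two cascaded median filters."""

    w1_seconds: float = 0.2
    w2_seconds: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.w1_seconds < self.w2_seconds:
            raise ValueError(
                f"need 0 < w1 < w2, got w1={self.w1_seconds}, w2={self.w2_seconds}"
            )


def window_samples(seconds: float, fs: float) -> int:
    """Convert a window duration to an odd sample count at rate ``fs``.

    Medians need a centred (odd) window; an even rounding is bumped up by
    one sample and logged.
    """
    w = int(round(seconds * fs))
    if w < 1:
        w = 1
    if w % 2 == 0:
        logger.debug("window %.4g s -> %d samples (even), rounding up to odd", seconds, w)
        w += 1
    return w


def remove_baseline(
    record: EcgRecord, config: BaselineFilterConfig = BaselineFilterConfig()
) -> EcgRecord:
    """Subtract the two-stage median-filter baseline estimate from a record.

    The baseline is ``median_w2(median_w1(x))`` with edge-replication
    padding so the output has exactly the input length.  Returns a new
    record with identical ``fs``/``lead``/``record_id``.

    Raises
    ------
    ValueError
        If the record is no longer than the second median window.
    """
    w1 = window_samples(config.w1_seconds, record.fs)
    w2 = window_samples(config.w2_seconds, record.fs)
    if len(record) <= w2:
        raise ValueError(
            f"record of {len(record)} samples is too short for a "
            f"{w2}-sample baseline window"
        )
    stage1 = median_filter(record.samples, size=w1, mode="nearest")
    baseline = median_filter(stage1, size=w2, mode="nearest")
    return EcgRecord(
        samples=record.samples - baseline,
        fs=record.fs,
        lead=record.lead,
        record_id=record.record_id,
    )
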
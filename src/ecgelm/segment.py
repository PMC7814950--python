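"""Fixed-duration beat segmentation anchored at annotated R peaks.

Each annotated beat is cut as the half-open sample window
``[r - pre, r + post)`` where ``pre = round(pre_seconds * fs)`` and
``post = round(post_seconds * fs)``.  With the defaults of 0.25 s before
and 0.40 s after the R peak at 360 Hz, every segment is exactly
90 + 144 = 234 samples and 0.65 s long — wide enough to cover the P wave
through the T wave of the current beat without reaching into its
neighbours at normal rates.  Beats whose window would cross a record
boundary are skipped (and counted in a log message), not padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ecg_io import BeatAnnotation, EcgRecord

logger = logging.getLogger(__name__)

DEFAULT_PRE_SECONDS = 0.25
DEFAULT_POST_SECONDS = 0.40


@dataclass(frozen=True)
class BeatSegment:
    """A fixed-length voltage window centred on one annotated R peak.

    ``samples[pre_samples]`` is the R-peak sample itself.
    """

    samples: np.ndarray
    annotation: BeatAnnotation
    pre_samples: int
    post_samples: int

    def __post_init__(self) -> None:
        if len(self.samples) != self.pre_samples + self.post_samples:
            raise ValueError(
                f"segment of {len(self.samples)} samples does not match "
                f"pre+post = {self.pre_samples + self.post_samples}"
            )

    def __len__(self) -> int:
        return len(self.samples)


def segment_beats(
    record: EcgRecord,
    annotations: list[BeatAnnotation],
    pre_seconds: float = DEFAULT_PRE_SECONDS,
    post_seconds: float = DEFAULT_POST_SECONDS,
) -> list[BeatSegment]:
    """Cut one window per annotation, preserving annotation order.

    Annotations whose window ``[r - pre, r + post)`` is not fully inside
    the record are skipped; the skipped count is logged.  An empty
    annotation list yields an empty output.
    """
    if pre_seconds + post_seconds <= 0:
        raise ValueError("pre_seconds + post_seconds must be positive")
    pre = int(round(pre_seconds * record.fs))
    post = int(round(post_seconds * record.fs))
    n = len(record)
    segments: list[BeatSegment] = []
    skipped = 0
    for ann in annotations:
        lo = ann.r_index - pre
        hi = ann.r_index + post
        if lo < 0 or hi > n:
            skipped += 1
            continue
        segments.append(
            BeatSegment(
                samples=record.samples[lo:hi],
                annotation=ann,
                pre_samples=pre,
                post_samples=post,
            )
        )
    if skipped:
        logger.info(
            "skipped %d of %d beats with out-of-bounds windows", skipped, len(annotations)
        )
    return segments
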
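"""Reading and writing ECG records, beat annotations and feature matrices.

All sample indices throughout the package are 0-based.  Two plain-text
dialects are defined here:

* **signal CSV** — two header lines ``fs=<Hz>`` and ``lead=<name>``,
  followed by one voltage sample (mV) per line;
* **annotation CSV** — a ``r_index,label`` header, then one row per
  annotated beat, R-peak sample indices strictly increasing.

Records in WFDB format (MIT-BIH style ``.hea``/``.dat``/``.atr`` triples)
can be read when the optional :mod:`wfdb` package is installed; nothing
else in the package requires it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 16 beat annotation symbols of the MIT-BIH arrhythmia database
#: (normal, bundle-branch blocks, premature/escape beats, paced, fusion,
#: flutter, blocked APC, unclassifiable).  WFDB annotation streams also
#: carry non-beat symbols (rhythm changes, noise markers); readers drop
#: those.
BEAT_SYMBOLS: frozenset[str] = frozenset(
    ["N", "L", "R", "A", "V", "/", "a", "!", "F", "x", "j", "f", "E", "J", "e", "Q"]
)


class FormatError(ValueError):
    """A file does not conform to one of the declared dialects."""


class MissingDependencyError(ImportError):
    """An optional dependency needed for this operation is not installed."""


@dataclass
class EcgRecord:
    """A sampled single-lead ECG voltage series.

    Parameters
    ----------
    samples
        Voltage series in millivolts; finite, length >= 1.
    fs
        Sampling rate in Hz (positive).  MIT-BIH records are digitised
        at 360 Hz.
    lead
        Free-text lead name (e.g. ``"MLII"``).
    record_id
        Free-text identifier.
    """

    samples: np.ndarray
    fs: float
    lead: str = "MLII"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class BeatAnnotation:
    """A fiducial R-peak position with its heartbeat class symbol."""

    r_index: int
    label: str

    def __post_init__(self) -> None:
        if self.r_index < 0:
            raise ValueError(f"r_index must be non-negative, got {self.r_index}")


def validate_annotations(
    annotations: Sequence[BeatAnnotation], record_length: int | None = None
) -> None:
    """Check ordering (strictly increasing r_index) and bounds."""
    prev = -1
    for ann in annotations:
        if ann.r_index <= prev:
            raise FormatError(
                f"annotation r_index {ann.r_index} not strictly increasing "
                f"(previous {prev})"
            )
        if record_length is not None and ann.r_index >= record_length:
            raise FormatError(
                f"annotation r_index {ann.r_index} outside record of length "
                f"{record_length}"
            )
        prev = ann.r_index


# ---------------------------------------------------------------------------
# signal CSV dialect
# ---------------------------------------------------------------------------

def read_record_csv(path: str | Path) -> EcgRecord:
    """Read an ECG record from the two-line-header signal CSV dialect.

    The first two lines must declare ``fs=<Hz>`` and ``lead=<name>``;
    every following line holds one sample value in mV.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2 or not lines[0].startswith("fs=") or not lines[1].startswith("lead="):
        raise FormatError(
            f"{path}: expected header lines 'fs=<Hz>' and 'lead=<name>'"
        )
    try:
        fs = float(lines[0][len("fs="):])
    except ValueError:
        raise FormatError(f"{path}: invalid fs value {lines[0][3:]!r}") from None
    if not fs > 0:
        raise FormatError(f"{path}: fs must be positive, got {fs}")
    lead = lines[1][len("lead="):]
    body = lines[2:]
    if not body:
        raise FormatError(f"{path}: no sample rows after the header")
    samples = np.empty(len(body))
    for i, row in enumerate(body):
        try:
            samples[i] = float(row)
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric sample {row!r} at data row {i}"
            ) from None
    return EcgRecord(samples=samples, fs=fs, lead=lead, record_id=path.stem)


def write_record_csv(path: str | Path, record: EcgRecord) -> None:
    """Write an ECG record in the two-line-header signal CSV dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"fs={record.fs:g}\n")
        fh.write(f"lead={record.lead}\n")
        for value in record.samples:
            fh.write(f"{value:.10g}\n")


# ---------------------------------------------------------------------------
# annotation CSV dialect
# ---------------------------------------------------------------------------

def read_annotations_csv(path: str | Path) -> list[BeatAnnotation]:
    """Read beat annotations (``r_index,label`` rows, sorted by index)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"r_index": int, "label": str})
    if list(df.columns) != ["r_index", "label"]:
        raise FormatError(
            f"{path}: expected columns ['r_index', 'label'], got {list(df.columns)}"
        )
    if (df["r_index"] < 0).any():
        raise FormatError(f"{path}: negative r_index")
    annotations = [
        BeatAnnotation(r_index=int(r), label=str(l))
        for r, l in zip(df["r_index"], df["label"])
    ]
    validate_annotations(annotations)
    return annotations


def write_annotations_csv(path: str | Path, annotations: Sequence[BeatAnnotation]) -> None:
    """Write beat annotations in the ``r_index,label`` CSV dialect."""
    validate_annotations(annotations)
    df = pd.DataFrame(
        {"r_index": [a.r_index for a in annotations],
         "label": [a.label for a in annotations]}
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# WFDB (optional)
# ---------------------------------------------------------------------------

def read_record_wfdb(
    record_path: str | Path, channel: int = 0
) -> tuple[EcgRecord, list[BeatAnnotation]]:
    """Read one channel of a WFDB record plus its beat annotations.

    Requires the optional :mod:`wfdb` package.  Annotation symbols outside
    the 16 MIT-BIH beat classes (rhythm-change and noise markers, etc.) are
    dropped with a logged count.  Sample indices are 0-based.

    Notes
    -----
    MIT-BIH record 114 stores MLII on the *lower* channel, unlike the other
    records; pass ``channel=1`` for it.  No other record-specific fix is
    applied here.
    """
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError:
        raise MissingDependencyError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install ecgelm[wfdb])"
        ) from None
    record_path = Path(record_path)
    if not record_path.with_suffix(".hea").exists():
        raise FileNotFoundError(f"WFDB header {record_path.with_suffix('.hea')} not found")
    rec = wfdb.rdrecord(str(record_path))
    if not 0 <= channel < rec.n_sig:
        raise ValueError(
            f"channel {channel} out of range for {rec.n_sig}-channel record"
        )
    samples = np.asarray(rec.p_signal[:, channel], dtype=float)
    lead = rec.sig_name[channel] if rec.sig_name else f"ch{channel}"
    record = EcgRecord(
        samples=samples, fs=float(rec.fs), lead=lead, record_id=record_path.stem
    )
    ann = wfdb.rdann(str(record_path), "atr")
    annotations: list[BeatAnnotation] = []
    dropped = 0
    for idx, symbol in zip(ann.sample, ann.symbol):
        if symbol in BEAT_SYMBOLS:
            annotations.append(BeatAnnotation(r_index=int(idx), label=symbol))
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d non-beat annotation symbols", dropped)
    validate_annotations(annotations, record_length=len(record))
    return record, annotations


# ---------------------------------------------------------------------------
# feature matrix CSV
# ---------------------------------------------------------------------------

def feature_column_names(n_features: int) -> list[str]:
    """Column names for an assembled feature matrix.

    The first four columns are the RR-interval features; the remainder are
    the final-level wavelet approximation (``wA_*``) then detail (``wD_*``)
    coefficients, which always come in equal halves.
    """
    n_wavelet = n_features - 4
    if n_features < 4 or n_wavelet % 2:
        raise ValueError(
            f"feature count {n_features} is not 4 RR features plus an even "
            "number of wavelet coefficients"
        )
    k = n_wavelet // 2
    return (
        ["rr_prev", "rr_post", "rr_short", "rr_long"]
        + [f"wA_{i}" for i in range(1, k + 1)]
        + [f"wD_{i}" for i in range(1, k + 1)]
    )


def write_feature_matrix(
    path: str | Path, matrix: np.ndarray, labels: Sequence[str]
) -> None:
    """Write a beats x features matrix plus per-beat labels to CSV."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D (beats x features)")
    if matrix.shape[0] != len(labels):
        raise ValueError(
            f"row count {matrix.shape[0]} does not match label count {len(labels)}"
        )
    columns = feature_column_names(matrix.shape[1])
    df = pd.DataFrame(matrix, columns=columns)
    df["label"] = list(labels)
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a feature-matrix CSV back into (matrix, labels)."""
    df = pd.read_csv(path, dtype={"label": str})
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    labels = df.pop("label").astype(str).tolist()
    expected = feature_column_names(df.shape[1])
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: unexpected feature columns {list(df.columns)[:6]}..."
        )
    return df.to_numpy(dtype=float), labels
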
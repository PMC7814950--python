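"""Validation-split grid search over wavelet, level, C and L.

The search follows a two-stage protocol: first the wavelet family and
decomposition depth are chosen on validation accuracy with the ELM
hyperparameters held fixed, then C (regularization) and L (hidden nodes)
are searched on the chosen features.  The split is a stratified random
70/30 train/validation partition — stratified because realistic beat
class frequencies are heavily skewed and an unstratified split can lose
rare classes entirely.  Each (C, L) cell draws its own hidden layer from
a cell-derived seed so the whole result table is reproducible bit for
bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import elm
from .ecg_io import BeatAnnotation, EcgRecord
from .features import (
    RrConfig,
    WaveletConfig,
    apply_standardizer,
    extract_beat_features,
    fit_standardizer,
    max_wavelet_level,
)
from .metrics import confusion, overall_accuracy
from .preprocess import BaselineFilterConfig

logger = logging.getLogger(__name__)

DEFAULT_C_VALUES = tuple(10.0 ** k for k in range(-4, 6))  # 1e-4 .. 1e5 by decades
DEFAULT_L_VALUES = tuple(range(200, 5001, 200))


@dataclass(frozen=True)
class GridSpec:
    """Search space plus split settings for the grid searches."""

    wavelets: tuple[str, ...] = ("db1", "bior1.3", "rbio3.1", "sym2")
    levels: tuple[int, ...] = (2, 3, 4, 5, 6)
    C_values: tuple[float, ...] = DEFAULT_C_VALUES
    L_values: tuple[int, ...] = DEFAULT_L_VALUES
    val_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("wavelets", "levels", "C_values", "L_values"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if not 0 < self.val_fraction < 1:
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")


def _cell_seed(base_seed: int, cell_index: int) -> int:
    """Deterministic per-cell RNG seed below 2**31."""
    return int(np.random.SeedSequence([base_seed, cell_index]).generate_state(1)[0] % 2**31)


def split_indices(
    labels: Sequence[str], val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/validation index split.

    Per class the validation share is ``round(n_class * val_fraction)``
    (so within one sample of the global fraction), capped to keep at
    least one training sample; classes with a single sample go wholly to
    training, logged.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    for lab, idx in by_class.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            logger.warning("class %r has a single sample; kept in training", lab)
            train_idx.extend(idx.tolist())
            continue
        perm = rng.permutation(idx)
        n_val = min(int(round(idx.size * val_fraction)), idx.size - 1)
        val_idx.extend(perm[:n_val].tolist())
        train_idx.extend(perm[n_val:].tolist())
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def split_train_validation(
    matrix: np.ndarray,
    labels: Sequence[str],
    val_fraction: float = 0.30,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, list[str]], tuple[np.ndarray, list[str]]]:
    """Stratified split of (matrix, labels) into train and validation sets."""
    matrix = np.asarray(matrix)
    tr, va = split_indices(labels, val_fraction, seed)
    labels = np.asarray(labels, dtype=object)
    return (
        (matrix[tr], list(labels[tr])),
        (matrix[va], list(labels[va])),
    )


def _validation_accuracy(
    X: np.ndarray,
    labels: Sequence[str],
    C: float,
    L: int,
    val_fraction: float,
    split_seed: int,
    elm_seed: int,
) -> float:
    """Train on the stratified training split, score on validation.

    The standardizer and the ELM see training rows only.
    """
    tr, va = split_indices(labels, val_fraction, split_seed)
    labels = np.asarray(labels, dtype=object)
    scaler = fit_standardizer(X[tr])
    model = elm.train(
        apply_standardizer(scaler, X[tr]), list(labels[tr]), C=C, L=L, seed=elm_seed
    )
    predicted = elm.predict_labels(model, apply_standardizer(scaler, X[va]))
    cm = confusion(list(labels[va]), predicted, model.classes + sorted(set(labels[va]) - set(model.classes)))
    return overall_accuracy(cm)


def grid_search_wavelet(
    records: EcgRecord | Sequence[EcgRecord],
    annotations: Sequence[BeatAnnotation] | Sequence[Sequence[BeatAnnotation]],
    grid: GridSpec,
    C: float = 0.1,
    L: int = 3000,
    rr_config: RrConfig = RrConfig(),
    baseline_config: BaselineFilterConfig | None = BaselineFilterConfig(),
) -> pd.DataFrame:
    """Rank (wavelet, level) cells by validation accuracy at fixed C, L.

    One fixed stratified split (from ``grid.seed``) is shared by all
    cells; depths beyond a wavelet's admissible maximum for the segment
    length are skipped and logged.  Returns a DataFrame sorted best
    first, with the winner flagged in a ``best`` column; ties prefer the
    shallower level, then the wavelet's position in the grid.
    """
    if isinstance(records, EcgRecord):
        records = [records]
        annotations = [annotations]  # type: ignore[list-item]
    rows = []
    cell = 0
    for wavelet in grid.wavelets:
        for level in grid.levels:
            feats = []
            labs: list[str] = []
            try:
                wavelet_config = WaveletConfig(wavelet=wavelet, level=level)
                for rec, anns in zip(records, annotations):
                    X, y = extract_beat_features(
                        rec, list(anns), rr_config, wavelet_config,
                        baseline_config=baseline_config,
                    )
                    feats.append(X)
                    labs.extend(y)
            except ValueError as exc:
                logger.info("skipping (%s, level %d): %s", wavelet, level, exc)
                continue
            X = np.vstack(feats)
            acc = _validation_accuracy(
                X, labs, C=C, L=L,
                val_fraction=grid.val_fraction,
                split_seed=grid.seed,
                elm_seed=_cell_seed(grid.seed, cell),
            )
            rows.append(
                {"wavelet": wavelet, "level": level, "n_features": X.shape[1],
                 "val_accuracy": acc}
            )
            cell += 1
    if not rows:
        raise ValueError("no admissible (wavelet, level) cells in the grid")
    table = pd.DataFrame(rows)
    order = {w: k for k, w in enumerate(grid.wavelets)}
    table["_w"] = table["wavelet"].map(order)
    table = (
        table.sort_values(["val_accuracy", "level", "_w"], ascending=[False, True, True])
        .drop(columns="_w")
        .reset_index(drop=True)
    )
    table["best"] = False
    table.loc[0, "best"] = True
    return table


def grid_search_elm(
    matrix: np.ndarray,
    labels: Sequence[str],
    grid: GridSpec,
) -> pd.DataFrame:
    """Rank (C, L) cells by validation accuracy on a fixed feature matrix.

    The split is fixed across cells; each cell draws its own hidden layer
    from a seed derived from (grid.seed, cell index), so re-running with
    the same grid reproduces every accuracy exactly.  Ties prefer the
    smaller L, then the smaller C (parsimony).
    """
    matrix = np.asarray(matrix, dtype=float)
    rows = []
    cell = 0
    for C in grid.C_values:
        for L in grid.L_values:
            acc = _validation_accuracy(
                matrix, labels, C=C, L=L,
                val_fraction=grid.val_fraction,
                split_seed=grid.seed,
                elm_seed=_cell_seed(grid.seed, cell),
            )
            rows.append({"C": C, "L": L, "val_accuracy": acc})
            cell += 1
    table = (
        pd.DataFrame(rows)
        .sort_values(["val_accuracy", "L", "C"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
    table["best"] = False
    table.loc[0, "best"] = True
    return table


# ---------------------------------------------------------------------------
# one-against-one baseline harness (comparators only)
# ---------------------------------------------------------------------------

def one_against_one_problem_count(m: int) -> int:
    """Number of pairwise binary problems an OAO decomposition needs."""
    if m < 2:
        raise ValueError(f"need at least 2 classes, got {m}")
    return m * (m - 1) // 2


def oao_svm_baseline(
    X_train: np.ndarray, y_train: Sequence[str]
) -> tuple[object, int]:
    """Fit the one-against-one SVM comparator; returns (model, #binary problems).

    Purely a baseline harness — the package's own classifier is the ELM.
    """
    from sklearn.multiclass import OneVsOneClassifier
    from sklearn.svm import SVC

    clf = OneVsOneClassifier(SVC(kernel="rbf"))
    clf.fit(np.asarray(X_train, dtype=float), list(y_train))
    n_problems = len(clf.estimators_)
    assert n_problems == one_against_one_problem_count(len(clf.classes_))
    return clf, n_problems
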
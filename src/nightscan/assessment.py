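"""Validation procedures: Monte-Carlo partition sweep and cross-series
true validation.

Two complementary assessments of the 15-class linear SVM:

* **Partition sweep** — the pooled data set is split at random into
  training and validation fractions (50:50 up to 95:5), 1000 times per
  fraction; the frequency distribution of binary-collapsed validation
  accuracies exposes the bias-variance behaviour of the classifier (narrow
  distributions = low variance; high mean = low bias).  Splits are simple
  random samples without stratification; a split leaving any training class
  empty is redrawn and counted.

* **True validation** — train on one growing series, validate on the other,
  in both directions.  Per-class percentage confusion rows from the two
  directions are averaged cell-wise, and the per-row plant counts averaged,
  reproducing the reporting layout of the published confusion tables.
  Binary detection metrics (false positives/negatives, accuracy) come from
  the combined, un-averaged predictions.

Confusion-table cells are stored at one-decimal precision, the precision at
which such tables are printed, so that metrics recomputed *from a table*
use exactly the printed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier as clf
from .classifier import collapse, decode_class, N_CLASSES
from .synth_scene import PERIODS

SWEEP_FRACTIONS = (0.50, 0.60, 0.70, 0.80, 0.90, 0.95)
DEFAULT_N_ITER = 1000

_PERIOD_SHORT = {"baseline": "Base", "early": "Early", "late": "Late"}
_FERT_SHORT = {"low": "Low", "medium": "Med", "high": "High"}


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Binary-accuracy distributions per training fraction."""

    accuracies: dict[float, np.ndarray]     # fraction -> n_iter accuracies
    seed: int
    n_redraws: dict[float, int] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for frac in sorted(self.accuracies):
            acc = self.accuracies[frac]
            rows.append(
                {
                    "fraction": frac,
                    "n_iter": len(acc),
                    "min": acc.min(),
                    "mean": acc.mean(),
                    "max": acc.max(),
                    "spread": acc.max() - acc.min(),
                    "n_redraws": self.n_redraws.get(frac, 0),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fraction": frac, "iteration": i, "accuracy": a}
            for frac in sorted(self.accuracies)
            for i, a in enumerate(self.accuracies[frac])
        ]
        return pd.DataFrame(rows)


@dataclass
class ConfusionTable:
    """Per-class percentage confusion matrix averaged over both validation
    directions, with average per-row plant counts."""

    crop: str
    matrix: np.ndarray          # 15 x 15 percentages, one-decimal precision
    plants: np.ndarray          # average plants per true-class row
    flagged_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.plants = np.asarray(self.plants, dtype=float)
        if self.matrix.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("confusion matrix must be 15 x 15")
        if len(self.plants) != N_CLASSES:
            raise ValueError("plants column must have 15 entries")

    @property
    def total_profiles(self) -> float:
        """Profiles across both directions: 2 x sum of average row counts."""
        return 2.0 * float(self.plants.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code in range(1, N_CLASSES + 1):
            period, fert, inf = decode_class(code)
            row = {
                "Code": code,
                "Time": _PERIOD_SHORT[period],
                "Fert": _FERT_SHORT[fert],
                "Inf": "Yes" if inf else "No",
            }
            row.update(
                {str(c): self.matrix[code - 1, c - 1] for c in range(1, N_CLASSES + 1)}
            )
            row["Plants"] = self.plants[code - 1]
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, crop: str = "") -> "ConfusionTable":
        frame = frame.sort_values("Code").reset_index(drop=True)
        if list(frame["Code"]) != list(range(1, N_CLASSES + 1)):
            raise ValueError("table must contain codes 1..15 exactly once")
        cols = [str(c) for c in range(1, N_CLASSES + 1)]
        matrix = frame[cols].fillna(0.0).to_numpy(dtype=float)
        plants = frame["Plants"].to_numpy(dtype=float)
        return cls(crop=crop, matrix=matrix, plants=plants)


@dataclass
class BinaryMetrics:
    """Infestation-detection counts after collapsing the 15 classes."""

    total: float
    false_positives: float
    false_negatives: float

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * (self.total - self.false_positives - self.false_negatives) / self.total


# ---------------------------------------------------------------------------
# Partition sweep
# ---------------------------------------------------------------------------

def _binary_accuracy(true_codes: np.ndarray, pred_codes: np.ndarray) -> float:
    return float(np.mean(collapse(true_codes) == collapse(pred_codes)))


def partition_sweep(
    frame: pd.DataFrame,
    codes: np.ndarray | None = None,
    fractions=SWEEP_FRACTIONS,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    max_redraws: int = 1000,
) -> SweepResult:
    """Random train/validation partition sweep of binary detection accuracy.

    For each training fraction, ``n_iter`` unstratified random splits are
    drawn; each trains the 15-class SVM and records the binary-collapsed
    validation accuracy.  Splits that leave a training class empty are
    redrawn (counted in ``n_redraws``).  Fully reproducible given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if codes is None:
        codes = clf.codes_for_frame(frame)
    codes = np.asarray(codes, dtype=int)
    n = len(frame)
    classes = np.unique(codes)
    if n < len(classes) + 1:
        raise ValueError("dataset smaller than the class count; cannot split")
    for frac in fractions:
        if not 0.0 < frac < 1.0:
            raise ValueError("training fractions must lie in (0, 1)")

    features = clf.band_columns(frame)
    X = frame[features]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA55]))
    accuracies: dict[float, np.ndarray] = {}
    redraws: dict[float, int] = {}

    for frac in fractions:
        n_train = int(round(frac * n))
        n_train = min(max(n_train, 1), n - 1)
        acc = np.empty(n_iter)
        n_redraw = 0
        for it in range(n_iter):
            for _attempt in range(max_redraws):
                perm = rng.permutation(n)
                train_idx, val_idx = perm[:n_train], perm[n_train:]
                if len(np.unique(codes[train_idx])) == len(classes):
                    break
                n_redraw += 1
            else:
                raise RuntimeError(
                    f"could not draw a split covering all classes at fraction {frac}"
                )
            model = clf.train(X.iloc[train_idx], codes[train_idx], features=features)
            pred = clf.predict(model, X.iloc[val_idx])
            acc[it] = _binary_accuracy(codes[val_idx], pred)
        accuracies[frac] = acc
        redraws[frac] = n_redraw
    return SweepResult(accuracies=accuracies, seed=seed, n_redraws=redraws)


# ---------------------------------------------------------------------------
# True validation
# ---------------------------------------------------------------------------

def _direction_confusion(
    train_frame: pd.DataFrame, val_frame: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """One directed train→validate run.

    Returns (percentage matrix, per-row counts, true codes, predicted codes,
    flagged row codes missing from training).
    """
    train_codes = clf.codes_for_frame(train_frame)
    val_codes = clf.codes_for_frame(val_frame)
    features = clf.band_columns(train_frame)
    flagged = sorted(set(range(1, N_CLASSES + 1)) - set(np.unique(train_codes)))
    if flagged:
        warnings.warn(
            f"training series lacks class(es) {flagged}; proceeding with the rest"
        )
    model = clf.train(train_frame[features], train_codes, features=features)
    pred = clf.predict(model, val_frame[features])

    matrix = np.zeros((N_CLASSES, N_CLASSES))
    counts = np.zeros(N_CLASSES)
    for code in range(1, N_CLASSES + 1):
        sel = val_codes == code
        counts[code - 1] = sel.sum()
        if counts[code - 1] == 0:
            continue
        for p in range(1, N_CLASSES + 1):
            matrix[code - 1, p - 1] = 100.0 * np.sum(pred[sel] == p) / counts[code - 1]
    return matrix, counts, val_codes, pred, flagged


def true_validation(
    series1: pd.DataFrame, series2: pd.DataFrame, crop: str = ""
) -> tuple[ConfusionTable, BinaryMetrics]:
    """Train on each series, validate on the other; average the two runs.

    The confusion table averages the two directions' percentage matrices
    cell-wise and their per-row counts (half-integer plant counts arise when
    the series differ by one plant).  Binary metrics are computed from the
    pooled predictions of both directions, before any rounding.
    """
    m1, c1, t1, p1, f1 = _direction_confusion(series1, series2)
    m2, c2, t2, p2, f2 = _direction_confusion(series2, series1)
    matrix = np.round((m1 + m2) / 2.0, 1)       # printed precision
    plants = (c1 + c2) / 2.0
    table = ConfusionTable(
        crop=crop, matrix=matrix, plants=plants, flagged_rows=sorted(set(f1) | set(f2))
    )

    true_bits = collapse(np.concatenate([t1, t2]))
    pred_bits = collapse(np.concatenate([p1, p2]))
    fp = float(np.sum(~true_bits & pred_bits))
    fn = float(np.sum(true_bits & ~pred_bits))
    metrics = BinaryMetrics(
        total=float(len(true_bits)), false_positives=fp, false_negatives=fn
    )
    return table, metrics


# ---------------------------------------------------------------------------
# Metrics from a printed table
# ---------------------------------------------------------------------------

def binary_metrics_from_table(
    table: ConfusionTable, rounding: str = "none"
) -> BinaryMetrics:
    """Recover binary detection metrics from a percentage confusion table.

    Each cell contributes ``cell% / 100 x plants x 2`` profiles (the factor
    2 restores both validation directions from the averaged counts).  With
    ``rounding='integer'`` the false-positive and false-negative totals are
    rounded to whole plants before the accuracy is formed, matching how
    counts are reported from printed tables.
    """
    if rounding not in ("none", "integer"):
        raise ValueError("rounding must be 'none' or 'integer'")
    row_sums = table.matrix.sum(axis=1)
    if np.any(np.abs(row_sums - 100.0) > 0.5):
        bad = int(np.argmax(np.abs(row_sums - 100.0))) + 1
        warnings.warn(f"row {bad} sums to {row_sums[bad - 1]:.1f}%, not ~100%")

    infested_bit = collapse(np.arange(1, N_CLASSES + 1))
    weights = table.matrix / 100.0 * table.plants[:, None] * 2.0
    fp = float(weights[np.ix_(~infested_bit, infested_bit)].sum())
    fn = float(weights[np.ix_(infested_bit, ~infested_bit)].sum())
    if rounding == "integer":
        fp, fn = float(round(fp)), float(round(fn))
    return BinaryMetrics(
        total=table.total_profiles, false_positives=fp, false_negatives=fn
    )
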
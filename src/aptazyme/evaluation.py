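"""Model evaluation: R² metrics, splits, structural-segment hold-out, and
flow-cytometry-style normalization / activation ratios.

Two R² variants are always reported: squared Pearson correlation (invariant to
affine rescaling of the predictions; the headline) and the coefficient of
determination 1 - SS_res/SS_tot (which penalizes bias).  Structural-segment
hold-out retrains the model with each structure group (identical stem lengths,
loop lengths and branch flags) entirely excluded, probing robustness to
structures absent from training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (ControlError, DegenerateData, HoldoutError, SelectionError,
                     SplitError)


@dataclass(frozen=True)
class EvaluationReport:
    r2_pearson: float
    r2_cod: float
    n: int
    segment_key: object = None


@dataclass(frozen=True)
class SwitchMeasurement:
    normalized_basal: float      # percent of inactive control, uninduced
    normalized_induced: float    # percent of inactive control, induced
    activation_ratio: float


def r_squared(predicted, measured, segment_key=None) -> EvaluationReport:
    """Both R² variants for predicted vs measured activities."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.ndim != 1 or len(p) < 2:
        raise SplitError("need two equal-length 1-D arrays of length >= 2")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(m))):
        raise DegenerateData("non-finite values")
    ss_tot = np.sum((m - m.mean()) ** 2)
    if ss_tot == 0:
        raise DegenerateData("measured values have zero variance")
    if np.all(p == p[0]):
        r2p = 0.0   # constant predictions carry no correlation
    else:
        r2p = float(np.corrcoef(p, m)[0, 1] ** 2)
    r2cod = float(1.0 - np.sum((m - p) ** 2) / ss_tot)
    return EvaluationReport(r2p, r2cod, len(p), segment_key)


def split_train_test(records, train_frac: float = 0.75, seed: int = 0):
    """Seeded shuffle split; train size rounds half up."""
    if not (0 < train_frac < 1):
        raise SplitError("train_frac must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise SplitError("need at least 2 records to split")
    idx = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(n * train_frac + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    tr, te = idx[:n_train], idx[n_train:]
    if isinstance(records, np.ndarray):
        return records[tr], records[te]
    if hasattr(records, "iloc"):
        return records.iloc[tr].reset_index(drop=True), records.iloc[te].reset_index(drop=True)
    return [records[i] for i in tr], [records[i] for i in te]


def split_indices(n: int, train_frac: float = 0.75, seed: int = 0):
    """Index form of :func:`split_train_test`."""
    if not (0 < train_frac < 1):
        raise SplitError("train_frac must be in (0, 1)")
    if n < 2:
        raise SplitError("need at least 2 records to split")
    idx = np.random.default_rng(seed).permutation(n)
    n_train = min(max(int(np.floor(n * train_frac + 0.5)), 1), n - 1)
    return idx[:n_train], idx[n_train:]


def segment_holdout(X, y, keys, train_fn, predict_fn,
                    min_segment_size: int = 50) -> list[EvaluationReport]:
    """Leave-one-structure-out evaluation.

    Each qualifying segment (>= min_segment_size records sharing a structure
    key) is held out exactly once; the model is retrained on all *other*
    records and evaluated on the held-out segment.

    ``train_fn(X_train, y_train) -> model``; ``predict_fn(model, X_test) -> y_hat``.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    keys = list(keys)
    if len(keys) != len(y):
        raise SplitError("keys and labels differ in length")
    uniq = {}
    for i, k in enumerate(keys):
        uniq.setdefault(k, []).append(i)
    qualifying = {k: idx for k, idx in uniq.items() if len(idx) >= min_segment_size}
    if len(qualifying) < 2:
        raise HoldoutError("need at least 2 segments of min_segment_size")
    reports = []
    for k in sorted(qualifying, key=str):
        test_idx = np.array(qualifying[k])
        train_idx = np.array([i for i, kk in enumerate(keys) if kk != k])
        model = train_fn(X[train_idx], y[train_idx])
        pred = np.asarray(predict_fn(model, X[test_idx]), dtype=float)
        reports.append(r_squared(pred, y[test_idx], segment_key=k))
    return reports


def normalize_and_ratio(uninduced_ratio: float, induced_ratio: float,
                        control_uninduced: float, control_induced: float
                        ) -> SwitchMeasurement:
    """Percent-of-control normalization with condition-matched controls, and
    the activation ratio (normalized induced / normalized basal)."""
    if control_uninduced <= 0 or control_induced <= 0:
        raise ControlError("control GFP/mCherry values must be positive")
    basal = 100.0 * uninduced_ratio / control_uninduced
    induced = 100.0 * induced_ratio / control_induced
    if basal <= 0:
        raise ControlError("normalized basal activity must be positive for a ratio")
    return SwitchMeasurement(basal, induced, induced / basal)


def mean_lowest_predicted(predicted, measured, n: int = 10) -> float:
    """Mean measured activity of the n records with the lowest predictions."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if n > len(p):
        raise SelectionError(f"n={n} exceeds {len(p)} records", scoreable=len(p))
    order = np.lexsort((np.arange(len(p)), p))[:n]
    return float(m[order].mean())
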
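"""Per-residue confusion counting and evaluation metrics.

The positive class is "disordered" (label 1).  Reported metrics are
sensitivity, specificity, balanced accuracy (their mean) and the Matthews
correlation coefficient of the 2x2 confusion table.  Counts are pooled
over all residues of all proteins by default; a per-protein mode is
available in the cross-validation driver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import DataError

__all__ = [
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "kfold_protein_split",
]


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sens: float
    spec: float
    bacc: float
    mcc: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return asdict(self)

    def table_row(self, label: str = "") -> str:
        """One aligned text row in Sens, Spec, BACC, MCC column order."""
        return (
            f"{label:<16s} {self.sens:8.4f} {self.spec:8.4f} "
            f"{self.bacc:8.4f} {self.mcc:8.4f}"
        )

    @staticmethod
    def table_header() -> str:
        return f"{'':<16s} {'Sens':>8s} {'Spec':>8s} {'BACC':>8s} {'MCC':>8s}"


def confusion_counts(calls: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """Standard (TP, FP, TN, FN) with disordered (1) as the positive class."""
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise DataError(f"calls shape {calls.shape} != truth shape {truth.shape}")
    calls = calls.astype(bool)
    truth = truth.astype(bool)
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    tn = int(np.sum(~calls & ~truth))
    fn = int(np.sum(~calls & truth))
    return tp, fp, tn, fn


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Sens, Spec, BACC and MCC from confusion counts.

    Conventions for degenerate tables: an empty marginal in the MCC
    denominator gives MCC = 0; an undefined sensitivity or specificity
    (no positives / no negatives in the truth) is reported as NaN with a
    warning and propagates into BACC.
    """
    if min(tp, fp, tn, fn) < 0:
        raise DataError("confusion counts must be nonnegative")
    if tp + fp + tn + fn == 0:
        raise DataError("empty confusion table")
    if tp + fn == 0:
        warnings.warn("no positive residues in truth; Sens undefined", stacklevel=2)
        sens = math.nan
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative residues in truth; Spec undefined", stacklevel=2)
        spec = math.nan
    else:
        spec = tn / (tn + fp)
    bacc = (sens + spec) / 2.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, sens=sens, spec=spec, bacc=bacc, mcc=mcc)


def kfold_protein_split(ids: list[str], folds: int, seed: int) -> list[list[str]]:
    """Protein-level fold assignment, a deterministic function of (ids, seed).

    Ids are sorted, permuted by a seeded generator, and dealt round-robin,
    so the assignment is independent of input order.
    """
    if folds < 2:
        raise DataError("need at least 2 folds")
    if len(ids) < folds:
        raise DataError(f"{len(ids)} proteins cannot fill {folds} folds")
    if len(set(ids)) != len(ids):
        raise DataError("duplicate protein ids")
    rng = np.random.default_rng(seed)
    order = sorted(ids)
    perm = rng.permutation(len(order))
    out: list[list[str]] = [[] for _ in range(folds)]
    for pos, idx in enumerate(perm):
        out[pos % folds].append(order[idx])
    return out
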
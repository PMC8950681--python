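"""End-to-end drivers: featurization, training runs, cross-validation.

These functions glue the feature modules, the network and the metrics into
the experiments the command line exposes, and define the desk-scale
planted-signal recovery experiment used to validate the whole pipeline on
synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError
from .kmers import KmerTable, build_kmer_table
from .metrics import MetricsReport, compute_metrics, confusion_counts, kfold_protein_split
from .network import DisorderNet, ModelConfig, TrainConfig, build_model, predict_protein, train
from .profiles import assemble_feature_matrix
from .seq_io import ProteinRecord
from .synth import default_planted_config, generate_corpus

__all__ = [
    "featurize_corpus",
    "pooled_training_arrays",
    "Standardizer",
    "train_and_evaluate",
    "planted_recovery_experiment",
    "cross_validate",
]


def featurize_corpus(
    records: Sequence[ProteinRecord],
    pssms: dict[str, np.ndarray] | None,
    table2: KmerTable,
    table3: KmerTable,
    window: int = 33,
    pssm_fallback: bool = False,
) -> dict[str, np.ndarray]:
    """35 x L feature matrix per protein id."""
    out: dict[str, np.ndarray] = {}
    for rec in records:
        pssm = None if pssms is None else pssms.get(rec.id)
        out[rec.id] = assemble_feature_matrix(
            rec, pssm, table2, table3, window=window, pssm_fallback=pssm_fallback
        )
    return out


def pooled_training_arrays(
    records: Sequence[ProteinRecord], features: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Pool all residues of all proteins into (n, 35) features and (n,) labels."""
    xs, ys = [], []
    for rec in records:
        if rec.labels is None:
            raise DataError(f"record {rec.id!r} has no labels")
        xs.append(features[rec.id].T)
        ys.append(rec.labels)
    return np.concatenate(xs), np.concatenate(ys)


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training residues.

    Raw feature rows live on very different scales (integer log-odds vs.
    [0, 1] tracks); standardising them onto a common scale conditions the
    SGD optimisation.  Constant features are left unscaled.
    """

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    std: np.ndarray = field(default_factory=lambda: np.ones(0))

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        self.std = np.where(std > 0, std, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def train_and_evaluate(
    train_records: Sequence[ProteinRecord],
    test_records: Sequence[ProteinRecord],
    features: dict[str, np.ndarray],
    model_config: ModelConfig,
    train_config: TrainConfig,
    model_seed: int = 0,
    standardize: bool = True,
) -> tuple[MetricsReport, DisorderNet, list[float]]:
    """Train on one protein set, evaluate pooled residue metrics on another."""
    X, y = pooled_training_arrays(train_records, features)
    scaler = Standardizer().fit(X) if standardize else None
    if scaler is not None:
        X = scaler.transform(X)
    model = build_model(model_config, seed=model_seed)
    history = train(model, X, y, train_config)

    tp = fp = tn = fn = 0
    for rec in test_records:
        F = features[rec.id]
        if scaler is not None:
            F = scaler.transform(F.T).T
        result = predict_protein(model, F)
        a, b, c, d = confusion_counts(result.calls, rec.labels)
        tp, fp, tn, fn = tp + a, fp + b, tn + c, fn + d
    return compute_metrics(tp, fp, tn, fn), model, history


def planted_recovery_experiment(
    seed: int = 0,
    scale: str = "small",
    window: int = 33,
    heldout_fraction: float = 0.25,
    max_epochs: int = 4,
    learning_rate: float = 0.01,
    convergence_tol: float = 2e-3,
) -> dict:
    """The desk-scale planted-signal experiment.

    Generates the default planted corpus, splits proteins into train /
    held-out sets, builds the k-mer tables on the training split only,
    featurizes everything with the training tables, trains the small-scale
    network and reports pooled held-out metrics.  Deterministic given
    ``seed``.
    """
    cfg = default_planted_config(scale, seed=seed)
    records, pssms = generate_corpus(cfg)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(len(records))
    n_test = max(1, int(round(heldout_fraction * len(records))))
    test_ids = {records[i].id for i in order[:n_test]}
    train_recs = [r for r in records if r.id not in test_ids]
    test_recs = [r for r in records if r.id in test_ids]

    table2 = build_kmer_table(train_recs, 2, corpus_id="planted-train")
    table3 = build_kmer_table(train_recs, 3, corpus_id="planted-train")
    features = featurize_corpus(records, pssms, table2, table3, window=window)

    report, model, history = train_and_evaluate(
        train_recs,
        test_recs,
        features,
        ModelConfig.small(),
        TrainConfig(
            learning_rate=learning_rate,
            max_epochs=max_epochs,
            seed=seed + 2,
            convergence_tol=convergence_tol,
        ),
        model_seed=seed + 3,
    )
    return {
        "report": report,
        "model": model,
        "history": history,
        "n_train_proteins": len(train_recs),
        "n_test_proteins": len(test_recs),
        "n_test_residues": report.total,
    }


def cross_validate(
    records: Sequence[ProteinRecord],
    features: dict[str, np.ndarray],
    folds: int,
    seed: int,
    model_config: ModelConfig,
    train_config: TrainConfig,
    standardize: bool = True,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Protein-level k-fold cross-validation with pooled residue metrics.

    Returns (per-fold reports, pooled report over all held-out residues).
    """
    by_id = {r.id: r for r in records}
    fold_ids = kfold_protein_split([r.id for r in records], folds, seed)
    per_fold: list[MetricsReport] = []
    tot = np.zeros(4, dtype=np.int64)
    for k, held in enumerate(fold_ids):
        held_set = set(held)
        train_recs = [r for r in records if r.id not in held_set]
        test_recs = [by_id[i] for i in held]
        report, _, _ = train_and_evaluate(
            train_recs, test_recs, features, model_config, train_config,
            model_seed=seed + k, standardize=standardize,
        )
        per_fold.append(report)
        tot += np.array([report.tp, report.fp, report.tn, report.fn])
    pooled = compute_metrics(*map(int, tot))
    return per_fold, pooled
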
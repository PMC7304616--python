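"""Evaluation protocols: confusion rates, k-fold CV, k-sweep, SMOTE experiment.

Accuracy is reported as a (true-positive rate, true-negative rate) pair pooled
over all (sample, group) cells: with 96 oils and 5 groups the two bases sum to
480 cells.  The true-positive rate is the percentage of desired-1 cells
predicted 1; the true-negative rate the percentage of desired-0 cells
predicted 0.  Pooling (rather than macro-averaging per group) is used because
the headline numbers quote a single TP/TN pair whose bases add up to the full
cell count; a per-group breakdown is also emitted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .descriptors import (DescriptorTable, cosine_distance_matrix,
                          correlation_distance_matrix, build_group_count_vectors,
                          filter_rare_descriptors, upgma_cut)
from .labels import GroupLabelMatrix, assign_group_labels
from .neuralnet import (NetworkArchitecture, OdorPredictor, TrainingConfig, binarize,
                        encode, train_autoencoder, train_mapping, _derive_seed)
from .smote import SmoteConfig, smote_sample


@dataclass(frozen=True)
class ConfusionRates:
    """TP/TN percentages with the number of cells each is based on.

    A rate whose base is empty (no desired-positive or desired-negative
    cells) is undefined and reported as NaN, never as 0.
    """

    tp_rate: float
    tn_rate: float
    tp_base: int
    tn_base: int


def confusion_rates(pred: np.ndarray, truth: np.ndarray) -> ConfusionRates:
    """Pooled TP/TN rates over all (sample, group) cells, in percent."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction shape {pred.shape} != truth shape {truth.shape}")
    pos = truth == 1
    neg = truth == 0
    tp_base = int(pos.sum())
    tn_base = int(neg.sum())
    tp_rate = 100.0 * float((pred[pos] == 1).sum()) / tp_base if tp_base else float("nan")
    tn_rate = 100.0 * float((pred[neg] == 0).sum()) / tn_base if tn_base else float("nan")
    return ConfusionRates(tp_rate, tn_rate, tp_base, tn_base)


def make_folds(n: int, folds: int, seed: int, labels: np.ndarray | None = None,
               stratify: bool = False) -> list[np.ndarray]:
    """Disjoint fold index blocks covering range(n).

    Default protocol: seeded shuffle, then contiguous blocks (sizes as equal
    as possible — 96 samples in 6 folds gives 16 each).  With ``stratify`` the
    shuffled samples are ordered by label pattern and dealt round-robin, which
    roughly balances label patterns across folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    if stratify:
        if labels is None:
            raise ValueError("stratified folds require labels")
        patterns = ["".join(map(str, row)) for row in np.asarray(labels, dtype=int)[perm]]
        perm = perm[np.argsort(patterns, kind="stable")]
        return [perm[f::folds] for f in range(folds)]
    sizes = np.full(folds, n // folds)
    sizes[: n % folds] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [perm[bounds[f]:bounds[f + 1]] for f in range(folds)]


@dataclass
class CVResult:
    """Cross-validation outcome: pooled rates, per-group rates, bookkeeping."""

    rates: ConfusionRates
    per_group: list[ConfusionRates]
    fold_indices: list[np.ndarray]
    predictions: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "tp_rate": self.rates.tp_rate, "tn_rate": self.rates.tn_rate,
            "tp_base": self.rates.tp_base, "tn_base": self.rates.tn_base,
            "per_group": [dataclasses.asdict(r) for r in self.per_group],
            "seed": self.seed,
        }


def cross_validate(values: np.ndarray, labels: np.ndarray, arch: NetworkArchitecture,
                   config: TrainingConfig, folds: int = 6,
                   eval_labels: np.ndarray | None = None,
                   stratify: bool = False) -> CVResult:
    """k-fold CV of the full predictor (autoencoder retrained per fold).

    Per fold: train the sparse autoencoder on the training block only (test
    spectra are never seen), encode, train the mapping network on the training
    block's labels, then predict the held-out block.  Rates are pooled over
    folds.  ``eval_labels`` lets predictions be scored against a different
    reference matrix (e.g. a generator's ground truth) than the one trained on.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    truth = labels if eval_labels is None else np.asarray(eval_labels, dtype=int)
    if values.shape[0] != labels.shape[0] or truth.shape != labels.shape:
        raise ValueError("spectra, labels and eval_labels must have aligned rows")
    fold_indices = make_folds(values.shape[0], folds, config.seed, labels, stratify)
    predictions = np.zeros_like(labels)
    for f, test_idx in enumerate(fold_indices):
        train_idx = np.setdiff1d(np.arange(values.shape[0]), test_idx)
        fold_config = replace(config, seed=_derive_seed(config.seed, 100 + f))
        ae = train_autoencoder(values[train_idx], arch, fold_config)
        mapper = train_mapping(encode(ae, values[train_idx]), labels[train_idx],
                               arch, fold_config)
        predictor = OdorPredictor(ae, mapper)
        predictions[test_idx] = binarize(predictor.predict_proba(values[test_idx]))
    per_group = [confusion_rates(predictions[:, c], truth[:, c])
                 for c in range(labels.shape[1])]
    return CVResult(confusion_rates(predictions, truth), per_group, fold_indices,
                    predictions, config.seed)


@dataclass
class ExperimentReport:
    """Results of a k-sweep or SMOTE-vs-original experiment."""

    results: dict
    seeds: dict
    config: dict
    fold_indices: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, (CVResult, ExperimentReport)):
                return x.to_dict()
            if isinstance(x, ConfusionRates):
                return dataclasses.asdict(x)
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.integer, np.floating)):
                return x.item()
            return x
        return {"results": conv(self.results), "seeds": conv(self.seeds),
                "config": conv(self.config)}


def group_sweep(values: np.ndarray, table: DescriptorTable, arch: NetworkArchitecture,
                config: TrainingConfig, k_range=range(4, 9), backend: str = "correlation",
                embeddings=None, folds: int = 6, min_occurrence: int = 2,
                eval_labels_for_k=None) -> ExperimentReport:
    """Re-cluster, re-label and cross-validate for each group count k.

    ``backend`` selects the descriptor similarity: "correlation" (7-dim count
    vectors) or "word-similarity" (cosine distance over ``embeddings``).
    """
    filtered = filter_rare_descriptors(table, min_occurrence)
    vocab = filtered.vocabulary()
    if backend == "correlation":
        dist = correlation_distance_matrix(build_group_count_vectors(filtered))
    elif backend == "word-similarity":
        if embeddings is None:
            raise ValueError("word-similarity backend requires an embedding table")
        dist = cosine_distance_matrix(embeddings, vocab)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    k_range = list(k_range)
    if not all(2 <= k <= len(vocab) for k in k_range):
        raise ValueError(f"k range {k_range} outside [2, {len(vocab)}]")
    results = {}
    for k in k_range:
        clustering = upgma_cut(dist, k)
        label_matrix = assign_group_labels(filtered, clustering)
        arch_k = replace(arch, n_groups=k)
        eval_labels = None if eval_labels_for_k is None else eval_labels_for_k(k)
        results[k] = cross_validate(values, label_matrix.values, arch_k, config,
                                    folds=folds, eval_labels=eval_labels)
    return ExperimentReport(results=results, seeds={"global": config.seed},
                            config={"backend": backend, "k_range": k_range,
                                    "folds": folds, **config.__dict__})


def train_test_split_indices(n: int, seed: int, train_frac: float = 0.6):
    """Seeded split into round(train_frac * n) training rows and the rest.

    At n = 96 and the default 60% fraction this is the 58 / 38 protocol split.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _fit_cluster_mapper(Z, y_col, arch, config):
    arch1 = replace(arch, n_groups=1)
    return train_mapping(Z, y_col.reshape(-1, 1), arch1, config)


def smote_experiment(values: np.ndarray, labels: GroupLabelMatrix | np.ndarray,
                     smote_configs, arch: NetworkArchitecture, config: TrainingConfig,
                     train_frac: float = 0.6, selection_folds: int = 5,
                     include_training_cv: bool = True) -> ExperimentReport:
    """SMOTE-vs-original comparison on a shared held-out test set.

    Protocol: a seeded train/test split (60% -> 58/38 at n=96); the sparse
    autoencoder is trained on the training spectra and both arms use its
    bottleneck features.  Per descriptor group, the "smote" arm rebalances the
    *training* rows only (the test set never contains synthetic rows), a
    per-group mapping network is trained on each arm, and a k-fold CV on each
    arm's own training rows is recorded for model assessment.  Final TP/TN
    rates for both arms are computed on the identical original test rows.

    ``smote_configs`` is one :class:`SmoteConfig` for all groups or a mapping
    {group index -> SmoteConfig}.
    """
    y = labels.values if isinstance(labels, GroupLabelMatrix) else np.asarray(labels)
    y = np.atleast_2d(y).astype(int)
    values = np.asarray(values, dtype=float)
    if values.shape[0] != y.shape[0]:
        raise ValueError("spectra and labels must have aligned rows")
    n, k = y.shape
    if isinstance(smote_configs, SmoteConfig):
        smote_configs = {c: smote_configs for c in range(k)}
    missing = [c for c in range(k) if c not in smote_configs]
    if missing:
        raise ValueError(f"no SmoteConfig for group(s) {missing}")

    train_idx, test_idx = train_test_split_indices(n, config.seed, train_frac)
    ae = train_autoencoder(values[train_idx], arch, config)
    Z_train = encode(ae, values[train_idx])
    Z_test = encode(ae, values[test_idx])

    arm_results = {}
    for arm in ("original", "smote"):
        preds = np.zeros((test_idx.size, k), dtype=int)
        per_group_cv = []
        for c in range(k):
            y_col = y[train_idx, c]
            if arm == "smote":
                res = smote_sample(Z_train, y_col, smote_configs[c])
                Z_fit, y_fit = res.X, res.y
            else:
                Z_fit, y_fit = Z_train, y_col
            fit_config = replace(config, seed=_derive_seed(config.seed, 200 + c))
            if include_training_cv:
                per_group_cv.append(_mapper_cv(Z_fit, y_fit, arch, fit_config,
                                               selection_folds))
            mapper = _fit_cluster_mapper(Z_fit, y_fit, arch, fit_config)
            preds[:, c] = binarize(mapper.predict_proba(Z_test))[:, 0]
        arm_results[arm] = {
            "test_rates": confusion_rates(preds, y[test_idx]),
            "per_group_test": [confusion_rates(preds[:, c], y[test_idx, c])
                               for c in range(k)],
            "training_cv": per_group_cv,
            "predictions": preds,
        }
    return ExperimentReport(
        results=arm_results,
        seeds={"global": config.seed},
        config={"train_frac": train_frac, "n_train": int(train_idx.size),
                "n_test": int(test_idx.size), **config.__dict__},
        fold_indices=[train_idx, test_idx])


def _mapper_cv(Z, y_col, arch, config, folds):
    """k-fold CV of a single-group mapping network on (possibly resampled) rows."""
    folds = min(folds, Z.shape[0])
    fold_indices = make_folds(Z.shape[0], folds, config.seed)
    preds = np.zeros(Z.shape[0], dtype=int)
    for f, test_idx in enumerate(fold_indices):
        train_idx = np.setdiff1d(np.arange(Z.shape[0]), test_idx)
        fold_config = replace(config, seed=_derive_seed(config.seed, 300 + f))
        mapper = _fit_cluster_mapper(Z[train_idx], y_col[train_idx], arch, fold_config)
        preds[test_idx] = binarize(mapper.predict_proba(Z[test_idx]))[:, 0]
    return confusion_rates(preds, y_col)
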
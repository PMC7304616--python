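"""Minority oversampling by neighbor interpolation plus majority down-sampling.

The odor-group targets are heavily imbalanced: most oils are negative for any
given descriptor group, so a discriminative model drifts toward predicting 0.
SMOTE rebalances the *training* data only: each minority sample spawns
``floor(perc_over/100)`` synthetic points, each placed uniformly at random on
the segment to one of its k nearest minority neighbors, and the majority class
is down-sampled to ``floor(perc_under/100 * n_synthetic)`` rows.  These count
semantics (and their floor rounding) follow the DMwR convention, under which
e.g. 22 positives / 36 negatives at 600%/100% become 154 / 132.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


class SmoteError(ValueError):
    """Invalid rebalancing request (single class, minority of one, ...)."""


@dataclass(frozen=True)
class SmoteConfig:
    """Oversampling/undersampling percentages and neighborhood size."""

    perc_over: float = 500.0
    perc_under: float = 100.0
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perc_over < 0 or self.perc_under < 0:
            raise ValueError("percentages must be >= 0")
        if 0 < self.perc_over < 100:
            raise SmoteError(
                "perc_over below 100 (fractional minority selection) is not supported")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class ResampledSet:
    """Rebalanced rows with per-row provenance ('original' or 'synthetic')."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.provenance)):
            raise ValueError("X, y and provenance must have equal length")

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.y, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


def smote_counts(n_min: int, n_maj: int, perc_over: float,
                 perc_under: float) -> tuple[int, int]:
    """Post-SMOTE class sizes: (minority_after, majority_after).

    ``n_syn = n_min * floor(perc_over/100)`` synthetic minority points are
    added, and ``floor(perc_under/100 * n_syn)`` majority rows are kept.  Both
    roundings floor — the only convention consistent with printed counts such
    as floor(1.2 * 144) = 172 and floor(1.2 * 48) = 57.
    """
    if n_min < 1:
        raise SmoteError("minority class must have at least one sample")
    if n_maj < 0:
        raise SmoteError("majority count must be >= 0")
    if 0 < perc_over < 100:
        raise SmoteError("perc_over below 100 is not supported")
    n_syn = n_min * int(perc_over // 100)
    minority_after = n_min + n_syn
    majority_after = int(np.floor(perc_under / 100.0 * n_syn))
    return minority_after, majority_after


def _minority_class(y: np.ndarray) -> tuple[int, int]:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise SmoteError(f"need exactly two classes, got {classes.tolist()}")
    if counts[0] == counts[1]:
        # tie: the class labelled 0 (sorted first) is treated as minority
        return int(classes[0]), int(classes[1])
    order = np.argsort(counts)
    return int(classes[order[0]]), int(classes[order[1]])


def smote_sample(X: np.ndarray, y: np.ndarray, config: SmoteConfig) -> ResampledSet:
    """Rebalance a binary-labelled feature matrix per the count contract.

    The output holds the original minority rows, the synthetic minority rows
    (each on a segment between a minority row and one of its ``k_neighbors``
    nearest minority neighbors), and a seeded uniform sample of the majority
    rows — without replacement when enough are available, with replacement
    otherwise.  Deterministic given ``config.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).ravel()
    if X.shape[0] != y.size:
        raise SmoteError(f"X has {X.shape[0]} rows but y has {y.size} labels")
    minority, majority = _minority_class(y)
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    n_min, n_maj = min_idx.size, maj_idx.size
    if n_min < 2:
        raise SmoteError("minority class must have at least 2 samples to interpolate")
    minority_after, majority_after = smote_counts(n_min, n_maj, config.perc_over,
                                                  config.perc_under)
    n_syn = minority_after - n_min
    k = config.k_neighbors
    if k > n_min - 1:
        warnings.warn(f"k_neighbors={k} exceeds minority size - 1 = {n_min - 1}; clamped",
                      stacklevel=2)
        k = n_min - 1

    rng = np.random.default_rng(config.seed)
    Xmin = X[min_idx]
    per_case = n_syn // n_min  # == floor(perc_over/100)
    synthetic = np.empty((n_syn, X.shape[1]))
    if n_syn:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
        neigh = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self
        row = 0
        for i in range(n_min):
            choices = rng.integers(0, k, size=per_case)
            gaps = rng.uniform(0.0, 1.0, size=per_case)
            for c, u in zip(choices, gaps):
                base = Xmin[i]
                synthetic[row] = base + u * (Xmin[neigh[i, c]] - base)
                row += 1

    if majority_after <= n_maj:
        kept = rng.choice(maj_idx, size=majority_after, replace=False)
    else:
        kept = rng.choice(maj_idx, size=majority_after, replace=True)

    X_out = np.vstack([X[min_idx], synthetic, X[kept]])
    y_out = np.concatenate([np.full(minority_after, minority, dtype=int),
                            np.full(majority_after, majority, dtype=int)])
    provenance = np.array(["original"] * n_min + ["synthetic"] * n_syn
                          + ["original"] * majority_after)
    return ResampledSet(X_out, y_out, provenance)
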
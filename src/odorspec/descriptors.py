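"""Odor-descriptor vectors, similarity matrices and hierarchical clustering.

Essential-oil databases annotate each oil with a *set* of odor descriptors
("floral", "balsamic", ...): binary data in which near-synonyms are mutually
exclusive, so their sample correlation vanishes.  Two remedies are provided:

1. **Continuous count vectors** — each descriptor is summarised by how often
   it occurs in each of the seven essential-oil families (Herbal, Citrus,
   Floral, Exotic, Resin, Spicy, Woody), giving a 7-dim integer profile whose
   Pearson correlation recovers similarity between descriptors that never
   co-occur on the same oil.
2. **Word embeddings** — descriptors are compared by cosine distance between
   pre-trained word vectors, importing semantic similarity from text corpora.

Either distance matrix is clustered by UPGMA (unweighted average linkage) and
the dendrogram is cut into k odor-descriptor groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

OIL_GROUPS = ("Herbal", "Citrus", "Floral", "Exotic", "Resin", "Spicy", "Woody")

#: Distances closer than this are considered tied during agglomeration.
MERGE_TIE_TOL = 1e-9


class DescriptorError(ValueError):
    """Invalid descriptor table, embedding file or clustering request."""


class OOVError(DescriptorError):
    """Descriptors missing from the embedding vocabulary; lists all of them."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"descriptors missing from embedding vocabulary: {self.missing}")


def _clean(descriptor: str) -> str:
    return str(descriptor).strip().lower()


@dataclass
class DescriptorTable:
    """Per-oil descriptor sets plus each oil's essential-oil family.

    ``descriptors`` maps oil id -> frozenset of lowercased descriptor strings;
    ``groups`` maps oil id -> one of the seven family names.  Oils may carry an
    empty descriptor set only after rare-descriptor filtering (``allow_empty``).
    """

    descriptors: dict[str, frozenset[str]]
    groups: dict[str, str]
    allow_empty: bool = False

    def __post_init__(self) -> None:
        if set(self.descriptors) != set(self.groups):
            raise DescriptorError("descriptor and group tables list different oils")
        clean = {}
        for oil, descs in self.descriptors.items():
            descs = frozenset(_clean(d) for d in descs if _clean(d))
            if not descs and not self.allow_empty:
                raise DescriptorError(f"oil {oil!r} has no descriptors")
            clean[str(oil)] = descs
        self.descriptors = clean
        for oil, group in self.groups.items():
            if group not in OIL_GROUPS:
                raise DescriptorError(
                    f"oil {oil!r} has unknown group {group!r}; expected one of {OIL_GROUPS}"
                )

    @property
    def oil_ids(self) -> list[str]:
        return sorted(self.descriptors)

    def vocabulary(self) -> list[str]:
        vocab = set()
        for descs in self.descriptors.values():
            vocab |= descs
        return sorted(vocab)

    def occurrence_counts(self) -> dict[str, int]:
        """Number of oils annotated with each descriptor."""
        counts: dict[str, int] = {}
        for descs in self.descriptors.values():
            for d in descs:
                counts[d] = counts.get(d, 0) + 1
        return counts


def read_descriptor_table(path) -> DescriptorTable:
    """Read a delimited table: oil_id, group, semicolon-separated descriptors."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise DescriptorError(f"{path}: expected columns oil_id, group, descriptors")
    descriptors, groups = {}, {}
    for _, row in df.iterrows():
        oil = str(row.iloc[0])
        if oil in descriptors:
            raise DescriptorError(f"{path}: duplicate oil id {oil!r}")
        groups[oil] = str(row.iloc[1]).strip()
        raw = "" if pd.isna(row.iloc[2]) else str(row.iloc[2])
        descriptors[oil] = frozenset(d for d in (s.strip() for s in raw.split(";")) if d)
    return DescriptorTable(descriptors, groups, allow_empty=True)


def write_descriptor_table(table: DescriptorTable, path) -> None:
    rows = [(oil, table.groups[oil], ";".join(sorted(table.descriptors[oil])))
            for oil in table.oil_ids]
    pd.DataFrame(rows, columns=["oil_id", "group", "descriptors"]).to_csv(path, index=False)


def filter_rare_descriptors(table: DescriptorTable, min_occurrence: int = 2) -> DescriptorTable:
    """Drop descriptors annotated on fewer than ``min_occurrence`` oils.

    Descriptors appearing only once carry no correlation information.  Oils
    whose descriptor sets become empty are retained (with a warning) so the
    sample set stays aligned with the spectra.
    """
    counts = table.occurrence_counts()
    keep = {d for d, c in counts.items() if c >= min_occurrence}
    filtered = {oil: frozenset(d for d in descs if d in keep)
                for oil, descs in table.descriptors.items()}
    emptied = sorted(oil for oil, descs in filtered.items() if not descs)
    if emptied:
        warnings.warn(f"oils left with no descriptors after filtering: {emptied}",
                      stacklevel=2)
    return DescriptorTable(filtered, dict(table.groups), allow_empty=True)


def build_group_count_vectors(table: DescriptorTable) -> pd.DataFrame:
    """Descriptor x oil-family occurrence counts (the 7-dim continuous vectors).

    Entry (d, g) counts the oils of family g annotated with descriptor d, so
    each row sums to the descriptor's total number of annotated oils.
    """
    vocab = table.vocabulary()
    counts = pd.DataFrame(0, index=pd.Index(vocab, name="descriptor"),
                          columns=list(OIL_GROUPS), dtype=int)
    for oil, descs in table.descriptors.items():
        group = table.groups[oil]
        for d in descs:
            counts.loc[d, group] += 1
    return counts


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities over labelled descriptors."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DescriptorError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DescriptorError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise DescriptorError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise DescriptorError("distance matrix has negative entries")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)


def correlation_distance_matrix(vectors: pd.DataFrame) -> DistanceMatrix:
    """One minus the Pearson correlation between descriptor count vectors.

    Entries lie in [0, 2].  A zero-variance (constant) count vector has
    undefined correlation; it is treated as uninformative and given distance 1
    to every other descriptor, with a warning.
    """
    X = np.asarray(vectors, dtype=float)
    if X.shape[0] < 2:
        raise DescriptorError("need at least 2 descriptor vectors")
    labels = [str(i) for i in vectors.index]
    std = X.std(axis=1)
    constant = std == 0
    if np.any(constant):
        warnings.warn(
            "constant count vectors (correlation undefined), assigned distance 1: "
            f"{[labels[i] for i in np.flatnonzero(constant)]}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    d = 1.0 - r
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, np.clip((d + d.T) / 2.0, 0.0, 2.0))


@dataclass
class EmbeddingTable:
    """Word -> fixed-dimension real vector (word2vec text format)."""

    vectors: dict[str, np.ndarray]
    dim: int

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def resolve(self, descriptor: str) -> np.ndarray:
        """Vector for a descriptor: verbatim lookup, else per-token average.

        Multi-word descriptors absent verbatim are averaged over their tokens;
        a missing token raises :class:`OOVError` rather than guessing.
        """
        key = _clean(descriptor)
        if key in self.vectors:
            return self.vectors[key]
        tokens = key.split()
        if len(tokens) > 1 and all(t in self.vectors for t in tokens):
            return np.mean([self.vectors[t] for t in tokens], axis=0)
        raise OOVError([key])


def load_embeddings(path, vocabulary=None) -> EmbeddingTable:
    """Load word vectors from the standard text format ('n d' header).

    With ``vocabulary`` given, only the requested words (and the tokens of
    multi-word entries) are retained, and every requested descriptor must be
    resolvable or an :class:`OOVError` listing all missing words is raised.
    """
    wanted = None
    if vocabulary is not None:
        wanted = set()
        for desc in vocabulary:
            key = _clean(desc)
            wanted.add(key)
            wanted.update(key.split())
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise DescriptorError(f"{path}: line 1: expected 'count dimension' header")
        try:
            n_declared, dim = int(header[0]), int(header[1])
        except ValueError:
            raise DescriptorError(f"{path}: line 1: non-integer header {header}") from None
        n_seen = 0
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) <= 1:
                continue
            n_seen += 1
            word = parts[0]
            if wanted is not None and word not in wanted:
                continue
            if len(parts) - 1 != dim:
                raise DescriptorError(
                    f"{path}: line {lineno}: expected {dim} values for {word!r}, "
                    f"got {len(parts) - 1}")
            try:
                vectors[word] = np.array(parts[1:], dtype=float)
            except ValueError:
                raise DescriptorError(f"{path}: line {lineno}: non-numeric value") from None
    if n_seen != n_declared:
        raise DescriptorError(f"{path}: header declares {n_declared} words, found {n_seen}")
    table = EmbeddingTable(vectors, dim)
    if vocabulary is not None:
        missing = []
        for desc in vocabulary:
            try:
                table.resolve(desc)
            except OOVError as exc:
                missing.extend(exc.missing)
        if missing:
            raise OOVError(missing)
    return table


def cosine_distance_matrix(emb: EmbeddingTable, descriptors) -> DistanceMatrix:
    """One minus cosine similarity between descriptor word vectors ([0, 2])."""
    labels = [_clean(d) for d in descriptors]
    missing, rows = [], []
    for d in labels:
        try:
            rows.append(emb.resolve(d))
        except OOVError as exc:
            missing.extend(exc.missing)
    if missing:
        raise OOVError(missing)
    V = np.vstack(rows)
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        bad = [labels[i] for i in np.flatnonzero(norms == 0)]
        raise DescriptorError(f"zero-norm embedding vectors for: {bad}")
    sim = (V / norms[:, None]) @ (V / norms[:, None]).T
    d = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, np.clip((d + d.T) / 2.0, 0.0, 2.0))


@dataclass
class DescriptorClustering:
    """A k-group partition of descriptors cut from a UPGMA dendrogram.

    ``merge_history`` records every agglomeration of the *full* tree as
    (members_left, members_right, height) with non-decreasing heights, so the
    dendrogram can be re-cut or exported without re-clustering.
    """

    k: int
    assignment: dict[str, int]
    merge_history: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for label, c in self.assignment.items():
            out.setdefault(c, []).append(label)
        return {c: sorted(members) for c, members in sorted(out.items())}

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))


def _canonical_cluster_indices(partition: list[tuple[str, ...]]) -> dict[str, int]:
    # Clusters numbered 1..k by order of each cluster's lexicographically
    # smallest member — stable downstream labelling.
    ordered = sorted(partition, key=lambda members: min(members))
    assignment = {}
    for idx, members in enumerate(ordered, start=1):
        for label in members:
            assignment[label] = idx
    return assignment


def upgma_cut(dist: DistanceMatrix, k: int) -> DescriptorClustering:
    """Agglomerate by unweighted average linkage and cut to exactly k clusters.

    Inter-cluster distance is the mean of all cross-pair leaf distances
    (UPGMA).  Ties within ``MERGE_TIE_TOL`` are broken by merging the pair
    whose sorted pair of smallest member labels is lexicographically smallest,
    making the dendrogram reproducible.
    """
    n = len(dist.labels)
    if not 1 <= k <= n:
        raise DescriptorError(f"k={k} out of range for {n} descriptors")
    D0 = dist.values
    idx = {lab: i for i, lab in enumerate(dist.labels)}
    clusters: list[tuple[str, ...]] = [(lab,) for lab in sorted(dist.labels)]
    merge_history: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    assignment: dict[str, int] | None = None
    last_height = 0.0

    def avg_dist(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        rows = [idx[x] for x in a]
        cols = [idx[x] for x in b]
        return float(D0[np.ix_(rows, cols)].mean())

    if len(clusters) == k:
        assignment = _canonical_cluster_indices(clusters)
    while len(clusters) > 1:
        best, best_d, best_key = None, np.inf, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = avg_dist(clusters[i], clusters[j])
                key = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                if d < best_d - MERGE_TIE_TOL or (
                        abs(d - best_d) <= MERGE_TIE_TOL and key < best_key):
                    best, best_d, best_key = (i, j), d, key
        i, j = best
        a, b = clusters[i], clusters[j]
        height = max(best_d, last_height)  # UPGMA is monotone; guard fp jitter
        merge_history.append((a, b, height))
        last_height = height
        merged = tuple(sorted(a + b))
        clusters = [c for pos, c in enumerate(clusters) if pos not in (i, j)]
        clusters.append(merged)
        if len(clusters) == k:
            assignment = _canonical_cluster_indices(clusters)
    return DescriptorClustering(k=k, assignment=assignment, merge_history=merge_history)


def to_newick(clustering: DescriptorClustering) -> str:
    """Export the full dendrogram as Newick, branch lengths from merge heights.

    A node's height is the average-linkage distance at which it was formed
    (leaves at 0); each branch length is parent height minus child height.
    """
    height: dict[tuple[str, ...], float] = {}
    newick: dict[tuple[str, ...], str] = {}
    for label in clustering.assignment:
        height[(label,)] = 0.0
        newick[(label,)] = label.replace(" ", "_")
    node = None
    for a, b, h in clustering.merge_history:
        parts = []
        for child in (a, b):
            bl = max(h - height[child], 0.0)
            parts.append(f"{newick[child]}:{bl:.10g}")
        node = tuple(sorted(a + b))
        newick[node] = "(" + ",".join(parts) + ")"
        height[node] = h
    if node is None:  # single descriptor, no merges
        (only,) = clustering.assignment
        return f"{only.replace(' ', '_')};"
    return newick[node] + ";"
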
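"""Synthetic essential-oil datasets with planted, recoverable structure.

The generator emulates the structure of the study data so the whole pipeline
is testable without any downloads: seven oil families, each with its own
template of Gaussian-shaped fragment peaks at family-specific integer m/z in
50-250 (multiplicative lognormal intensity noise plus a small additive
baseline, then per-spectrum max-normalisation); descriptor annotations drawn
from family-affine vocabularies (each oil samples 2-5 descriptors, each from
its family's vocabulary with probability 0.8, otherwise from another family's,
which creates the cross-family leakage the clustering must tolerate); and toy
word embeddings whose cosine geometry mirrors the planted descriptor families.

What this does *not* emulate: real electron-ionisation fragmentation (peaks
are placed at random m/z, not chemically), chromatographic artifacts, and the
vocabulary of a real odor lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import OIL_GROUPS, DescriptorTable
from .labels import GroupLabelMatrix
from .spectra import DEFAULT_MZ_HI, DEFAULT_MZ_LO, SpectraMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and noise of a generated dataset (defaults = study conditions)."""

    n_oils: int = 96
    n_oil_families: int = 7
    peaks_per_family: int = 8
    descriptor_families: int = 5
    words_per_family: int = 8
    descriptors_per_oil: tuple[int, int] = (2, 5)
    family_affinity: float = 0.8   # P(descriptor drawn from the oil's own family)
    noise_sd: float = 0.1          # lognormal sigma on peak intensities
    baseline: float = 0.01         # additive uniform(0, baseline) floor
    label_noise: float = 0.0       # ground-truth cell flip probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oils < self.n_oil_families:
            raise ValueError("need at least one oil per family")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.family_affinity <= 1:
            raise ValueError("family_affinity must lie in (0, 1]")
        if self.descriptor_families > self.n_oil_families:
            raise ValueError("descriptor families cannot outnumber oil families")


def _family_vocabularies(spec: SyntheticSpec) -> list[list[str]]:
    # Word names sort by family index, so the canonical cluster numbering of a
    # recovered partition coincides with the planted family order.
    return [[f"odor{j}{chr(97 + i)}" for i in range(spec.words_per_family)]
            for j in range(spec.descriptor_families)]


def generate_dataset(spec: SyntheticSpec = SyntheticSpec()):
    """Generate (SpectraMatrix, DescriptorTable, ground-truth GroupLabelMatrix).

    Oil i belongs to family ``i mod 7``; family f's primary descriptor family
    is ``f mod descriptor_families``.  The ground-truth matrix marks each oil
    positive exactly for its primary descriptor family (then applies
    ``label_noise`` flips), which is what a perfect spectra-based predictor
    could recover; the descriptor table adds the sampling noise on top.
    """
    rng = np.random.default_rng(spec.seed)
    channels = np.arange(DEFAULT_MZ_LO, DEFAULT_MZ_HI + 1)
    n_channels = channels.size

    # family peak templates: globally distinct integer peak positions
    interior = np.arange(DEFAULT_MZ_LO + 5, DEFAULT_MZ_HI - 4)
    positions = rng.choice(interior, size=spec.n_oil_families * spec.peaks_per_family,
                           replace=False).reshape(spec.n_oil_families, -1)
    amplitudes = rng.uniform(0.2, 1.0, size=positions.shape)
    peak_sd = 1.5  # channels; unit-resolution peaks with slight shoulders
    grid = channels[None, :]

    templates = []
    for f in range(spec.n_oil_families):
        shapes = np.exp(-0.5 * ((grid - positions[f][:, None]) / peak_sd) ** 2)
        templates.append(amplitudes[f][:, None] * shapes)
    vocabs = _family_vocabularies(spec)

    sample_ids, rows = [], []
    descriptors, groups = {}, {}
    family_of = np.arange(spec.n_oils) % spec.n_oil_families
    primary = family_of % spec.descriptor_families
    lo_m, hi_m = spec.descriptors_per_oil
    for i in range(spec.n_oils):
        f = family_of[i]
        peak_scale = np.exp(rng.normal(0.0, spec.noise_sd, size=spec.peaks_per_family))
        signal = (peak_scale[:, None] * templates[f]).sum(axis=0)
        signal = signal + rng.uniform(0.0, spec.baseline, size=n_channels)
        rows.append(signal / signal.max())
        oil = f"oil{i:03d}"
        sample_ids.append(oil)
        groups[oil] = OIL_GROUPS[f]
        # m independent affinity draws; duplicate picks collapse (set semantics),
        # keeping the per-draw off-family probability at exactly 1 - affinity
        m = int(rng.integers(lo_m, hi_m + 1))
        others = [w for j, vocab in enumerate(vocabs) if j != primary[i] for w in vocab]
        picked: set[str] = set()
        for _ in range(m):
            if rng.random() < spec.family_affinity:
                picked.add(vocabs[primary[i]][int(rng.integers(0, spec.words_per_family))])
            else:
                picked.add(others[int(rng.integers(0, len(others)))])
        descriptors[oil] = frozenset(picked)

    truth = np.zeros((spec.n_oils, spec.descriptor_families), dtype=int)
    truth[np.arange(spec.n_oils), primary] = 1
    if spec.label_noise > 0:
        flips = rng.random(truth.shape) < spec.label_noise
        truth = np.where(flips, 1 - truth, truth)

    matrix = SpectraMatrix(sample_ids, channels, np.vstack(rows))
    table = DescriptorTable(descriptors, groups)
    ground_truth = GroupLabelMatrix(sample_ids,
                                    list(range(1, spec.descriptor_families + 1)), truth)
    return matrix, table, ground_truth


def planted_partition(spec: SyntheticSpec = SyntheticSpec()) -> dict[str, int]:
    """Descriptor -> planted family cluster index (1-based, canonical order)."""
    return {w: j + 1 for j, vocab in enumerate(_family_vocabularies(spec))
            for w in vocab}


def write_toy_embeddings(families, dim: int = 64, separation: float = 2.0,
                         seed: int = 0, path=None) -> None:
    """Write a word2vec-text embedding file with planted family geometry.

    ``families`` is a list of word lists.  Each family gets an orthonormal
    center direction; each word vector is ``separation * center`` plus unit
    isotropic noise, so within-family cosine distances shrink as
    ``separation`` grows (clean partition recovery from separation ~ 2-3).
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    families = [list(f) for f in families]
    n_fam = len(families)
    if dim < n_fam:
        raise ValueError(f"dim={dim} cannot host {n_fam} orthogonal family centers")
    rng = np.random.default_rng(seed)
    centers, _ = np.linalg.qr(rng.normal(size=(dim, n_fam)))
    centers = centers.T
    words, vectors = [], []
    for j, family in enumerate(families):
        for word in family:
            noise = rng.normal(0.0, 1.0 / np.sqrt(dim), size=dim)
            words.append(word)
            vectors.append(separation * centers[j] + noise)
    with open(path, "w") as fh:
        fh.write(f"{len(words)} {dim}\n")
        for word, vec in zip(words, vectors):
            fh.write(word + " " + " ".join(f"{v:.6f}" for v in vec) + "\n")
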
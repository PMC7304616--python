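"""Binary odor-descriptor-group targets for the predictive model.

Once descriptors are partitioned into k groups, each oil's prediction target
is a k-long binary vector: an oil is positive for a group when at least one
of the oil's descriptors belongs to that group (e.g. a cluster {orange,
citrus, lemon} marks every oil annotated "orange" as carrying that odor
character).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DescriptorClustering, DescriptorError, DescriptorTable


@dataclass
class GroupLabelMatrix:
    """Oils x odor-descriptor-groups binary target matrix."""

    oil_ids: list[str]
    cluster_ids: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.oil_ids = [str(o) for o in self.oil_ids]
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.oil_ids), len(self.cluster_ids)):
            raise ValueError(
                f"label matrix shape {self.values.shape} does not match "
                f"{len(self.oil_ids)} oils x {len(self.cluster_ids)} clusters")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("label matrix entries must be 0 or 1")

    @property
    def k(self) -> int:
        return len(self.cluster_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.oil_ids, name="oil_id"),
                            columns=self.cluster_ids)


def assign_group_labels(table: DescriptorTable,
                        clustering: DescriptorClustering) -> GroupLabelMatrix:
    """Label each oil 1 for every cluster its descriptor set intersects.

    Every descriptor still on an oil must be assigned in ``clustering`` (i.e.
    the table has been rare-filtered with the same threshold used before
    clustering).  Oils with no surviving descriptors get an all-zero row and
    a warning — they carry no target information but keep the rows aligned
    with the spectra matrix.
    """
    clusters = clustering.clusters()
    member_of = clustering.assignment
    oil_ids = table.oil_ids
    cluster_ids = sorted(clusters)
    values = np.zeros((len(oil_ids), len(cluster_ids)), dtype=int)
    empty = []
    for i, oil in enumerate(oil_ids):
        descs = table.descriptors[oil]
        if not descs:
            empty.append(oil)
            continue
        for d in descs:
            if d not in member_of:
                raise DescriptorError(
                    f"descriptor {d!r} (oil {oil!r}) is not assigned in the clustering")
            values[i, cluster_ids.index(member_of[d])] = 1
    if empty:
        warnings.warn(f"oils with no descriptors labelled all-zero: {empty}", stacklevel=2)
    return GroupLabelMatrix(oil_ids, cluster_ids, values)


def read_group_labels(path) -> GroupLabelMatrix:
    df = pd.read_csv(path, index_col=0)
    return GroupLabelMatrix(list(df.index), [int(c) for c in df.columns],
                            df.to_numpy(dtype=int))


def write_group_labels(labels: GroupLabelMatrix, path) -> None:
    labels.to_frame().to_csv(path)
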
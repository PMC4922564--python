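"""External validation of a clustering against a ground-truth classification.

All measures derive from the class-by-cluster contingency table: the
pairwise measures (precision, recall, F1, Rand, Jaccard) from pair counts,
the variation of information from natural-log partition entropies, and the
clustering edit distance from the count of co-occupied cells,
Edit = 2 * (number of nonzero cells) - #classes - #clusters.

The published crotonase and enolase superfamily validation tables ship as
packaged fixtures (see `load_packaged_contingency`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import comb

from .spectral import ClusterAssignment


class ValidationError(ValueError):
    pass


@dataclass
class ContingencyTable:
    """Classes x clusters non-negative integer count matrix."""

    counts: np.ndarray
    class_names: list[str]
    cluster_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValidationError("contingency counts must be 2-D")
        if (self.counts < 0).any():
            raise ValidationError("negative contingency counts")
        if self.counts.shape != (len(self.class_names), len(self.cluster_names)):
            raise ValidationError("contingency shape does not match names")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContingencyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df.to_numpy(dtype=np.int64),
                   class_names=[str(i) for i in df.index],
                   cluster_names=[str(c) for c in df.columns])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=self.class_names,
                          columns=self.cluster_names)
        df.index.name = "class"
        df.to_csv(path, sep="\t")


def load_packaged_contingency(which: str) -> ContingencyTable:
    """Packaged SFLD validation tables: 'crotonase' or 'enolase'."""
    if which not in ("crotonase", "enolase"):
        raise ValidationError("which must be 'crotonase' or 'enolase'")
    ref = resources.files("isofam.data") / f"{which}_contingency.tsv"
    with resources.as_file(ref) as path:
        return ContingencyTable.from_tsv(path)


def contingency_from_labels(truth: Mapping[str, str],
                            clusters: ClusterAssignment) -> ContingencyTable:
    if set(truth) != set(clusters.labels):
        raise ValidationError("truth and clustering cover different id sets")
    class_names = sorted(set(truth.values()))
    cluster_names = [str(c) for c in range(1, clusters.k + 1)]
    counts = np.zeros((len(class_names), clusters.k), dtype=np.int64)
    class_index = {name: i for i, name in enumerate(class_names)}
    for pid, label in truth.items():
        counts[class_index[label], clusters.labels[pid] - 1] += 1
    return ContingencyTable(counts=counts, class_names=class_names,
                            cluster_names=cluster_names)


@dataclass
class PairwiseCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def pairwise_counts(t: ContingencyTable) -> PairwiseCounts:
    """Pair counts over all C(N,2) object pairs.

    TP: same class and same cluster; FP: same cluster, different class;
    FN: same class, different cluster; TN: different both.
    """
    n = t.n
    if n < 2:
        raise ValidationError("pair counts need at least 2 objects")
    c2 = lambda x: comb(x, 2, exact=True)
    tp = int(sum(c2(v) for v in t.counts.ravel()))
    same_cluster = int(sum(c2(v) for v in t.counts.sum(axis=0)))
    same_class = int(sum(c2(v) for v in t.counts.sum(axis=1)))
    fp = same_cluster - tp
    fn = same_class - tp
    tn = c2(n) - tp - fp - fn
    return PairwiseCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class MeasureSuite:
    precision: float
    recall: float
    f1: float
    rand: float
    jaccard: float
    vi: float
    edit: int

    def as_dict(self) -> dict[str, float | int]:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, "rand": self.rand, "jaccard": self.jaccard,
                "vi": self.vi, "edit": self.edit}


def pairwise_measures(c: PairwiseCounts) -> tuple[float, float, float, float, float]:
    """(precision, recall, F1, Rand, Jaccard) from the pair counts."""
    if c.tp + c.fp == 0:
        raise ValidationError("precision undefined: no same-cluster pairs")
    if c.tp + c.fn == 0:
        raise ValidationError("recall undefined: no same-class pairs")
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        raise ValidationError("F1 undefined: precision + recall = 0")
    f1 = 2 * precision * recall / (precision + recall)
    rand = (c.tp + c.tn) / c.total
    if c.tp + c.fp + c.fn == 0:
        raise ValidationError("Jaccard undefined")
    jaccard = c.tp / (c.tp + c.fp + c.fn)
    return precision, recall, f1, rand, jaccard


def _entropy(fractions: np.ndarray) -> float:
    f = fractions[fractions > 0]
    return float(-(f * np.log(f)).sum())


def variation_of_information(t: ContingencyTable) -> float:
    """VI = H(S) + H(S') - 2 I(S, S') in nats (0 iff partitions coincide)."""
    n = t.n
    if n < 1:
        raise ValidationError("empty contingency table")
    p_joint = t.counts / n
    h_rows = _entropy(t.counts.sum(axis=1) / n)
    h_cols = _entropy(t.counts.sum(axis=0) / n)
    h_joint = _entropy(p_joint.ravel())
    mutual = h_rows + h_cols - h_joint
    return h_rows + h_cols - 2 * mutual


def edit_distance(t: ContingencyTable) -> int:
    """Minimum split/merge operations between the two partitions."""
    nonzero = int((t.counts > 0).sum())
    return 2 * nonzero - len(t.class_names) - len(t.cluster_names)


def measure_suite(t: ContingencyTable) -> MeasureSuite:
    precision, recall, f1, rand, jaccard = pairwise_measures(pairwise_counts(t))
    return MeasureSuite(precision=precision, recall=recall, f1=f1, rand=rand,
                        jaccard=jaccard, vi=variation_of_information(t),
                        edit=edit_distance(t))


__all__ = [
    "ValidationError", "ContingencyTable", "PairwiseCounts", "MeasureSuite",
    "load_packaged_contingency", "contingency_from_labels", "pairwise_counts",
    "pairwise_measures", "variation_of_information", "edit_distance",
    "measure_suite",
]
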
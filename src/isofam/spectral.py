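"""Spectral clustering with the random-walk normalized Laplacian.

The integrated similarity matrix defines a fully connected weighted graph.
We form L_rw = I - D^-1 W, take the eigenvectors of its K smallest
eigenvalues as an N x K embedding, and run seeded K-means on the rows. The
eigenproblem is solved in its equivalent symmetric generalized form
(D - W) v = lambda D v for numerical stability; the contract is on the
result, not the routine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans


class SpectralError(ValueError):
    pass


@dataclass
class ClusterAssignment:
    """Surjective labeling of proteins into K non-empty clusters (1..K)."""

    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        used = set(self.labels.values())
        if not used <= set(range(1, self.k + 1)):
            raise SpectralError(f"labels outside 1..{self.k}: {sorted(used)}")
        if used != set(range(1, self.k + 1)):
            raise SpectralError("every cluster must be non-empty")

    @property
    def ids(self) -> list[str]:
        return list(self.labels)

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.labels.items() if c == cluster]

    def as_array(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids], dtype=int)


_ZERO_ROW_FLOOR = 1e-12


def build_affinity(values: np.ndarray) -> np.ndarray:
    """Non-negative affinity from a combined similarity matrix.

    Shifts by -min if negatives exist, zeroes the diagonal (no self-loops),
    and floors all-zero rows so the fully-connected degree contract holds.
    """
    w = np.asarray(values, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise SpectralError("affinity input must be square")
    if not np.allclose(w, w.T):
        raise SpectralError("affinity input must be symmetric")
    if not np.isfinite(w).all():
        raise SpectralError("affinity input must be finite")
    w = w.copy()
    lo = w.min()
    if lo < 0:
        w = w - lo
    np.fill_diagonal(w, 0.0)
    zero_rows = w.sum(axis=1) == 0
    if zero_rows.any():
        w[zero_rows, :] += _ZERO_ROW_FLOOR
        w[:, zero_rows] += _ZERO_ROW_FLOOR
        np.fill_diagonal(w, 0.0)
    return w


def random_walk_embedding(w: np.ndarray, k: int) -> np.ndarray:
    """Eigenvectors for the K smallest eigenvalues of L_rw = I - D^-1 W."""
    n = len(w)
    if not 1 <= k <= n:
        raise SpectralError(f"K={k} must be in 1..{n}")
    d = w.sum(axis=1)
    if (d <= 0).any():
        raise SpectralError("degree matrix not positive; affinity has zero rows")
    laplacian = np.diag(d) - w
    # (D - W) v = lambda D v  <=>  L_rw v = lambda v
    eigvals, eigvecs = scipy.linalg.eigh(laplacian, np.diag(d))
    order = np.argsort(eigvals)
    return eigvecs[:, order[:k]]


def spectral_cluster(w: np.ndarray, ids: Sequence[str], k: int, seed: int,
                     n_init: int = 10, empty_retries: int = 5) -> ClusterAssignment:
    """Cluster rows of the Laplacian embedding with seeded K-means."""
    ids = list(ids)
    if len(ids) != len(w):
        raise SpectralError("ids and affinity size mismatch")
    if k > len(ids):
        raise SpectralError(f"K={k} exceeds N={len(ids)}")
    embedding = random_walk_embedding(np.asarray(w, dtype=float), k)
    rng_seed = int(seed) % (2**31)
    for attempt in range(empty_retries + 1):
        km = KMeans(n_clusters=k, n_init=n_init,
                    random_state=(rng_seed + attempt) % (2**31))
        raw = km.fit_predict(embedding)
        if len(set(raw)) == k:
            return ClusterAssignment(
                labels={pid: int(c) + 1 for pid, c in zip(ids, raw)}, k=k)
    raise SpectralError(
        f"K-means produced an empty cluster in {empty_retries + 1} attempts; "
        "fewer than K separable embedding rows")


def write_assignment(assignment: ClusterAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcluster\n")
        for pid, c in assignment.labels.items():
            fh.write(f"{pid}\t{c}\n")


def read_assignment(path) -> ClusterAssignment:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "cluster": int})
    labels = dict(zip(df["id"], df["cluster"].astype(int)))
    return ClusterAssignment(labels=labels, k=max(labels.values()))


__all__ = [
    "SpectralError", "ClusterAssignment", "build_affinity",
    "random_walk_embedding", "spectral_cluster",
    "write_assignment", "read_assignment",
]
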
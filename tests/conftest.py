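import numpy as np
import pytest

from isofam.pockets import ActiveSiteAlignment
from isofam.spectral import ClusterAssignment


@pytest.fixture
def four_protein_msa():
    """Width-1 alignment over four proteins: column A,A,C,C."""
    return ActiveSiteAlignment(rows={"p1": "A", "p2": "A", "p3": "C", "p4": "C"})


@pytest.fixture
def two_cluster_labels():
    return ClusterAssignment(labels={"p1": 1, "p2": 1, "p3": 2, "p4": 2}, k=2)


# ---------------------------------------------------------------------------
# independent oracles (quadratic-space DP; brute-force probability tables)

def gotoh_global(a: str, b: str, sub, gap_open: float = 10.0,
                 gap_extend: float = 4.0) -> float:
    """Affine-gap global alignment score; a gap of length L costs
    gap_open + L * gap_extend. Independent of the package implementation."""
    neg = -1e18
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Iy = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - gap_open - gap_extend,
                           Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open - gap_extend,
                           Iy[i, j - 1] - gap_extend)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def smith_waterman_local(a: str, b: str, sub, gap_open: float = 10.0,
                         gap_extend: float = 4.0) -> float:
    """Affine-gap local alignment score (floor 0), same gap convention."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e18)
    F = np.full((n + 1, m + 1), -1e18)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend,
                          E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend,
                          F[i - 1, j] - gap_extend)
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]],
                          E[i, j], F[i, j])
            best = max(best, H[i, j])
    return float(best)


def brute_force_partial_mi(msa: ActiveSiteAlignment, labels: ClusterAssignment,
                           position: int, cluster: int, residue: str) -> float:
    """Partial MI computed straight from tabulated probabilities.

    Over the non-gap rows at the position: PMI terms use joint p(c, r) and
    marginals p(c), p(r); weights are residue frequencies within the cluster
    and within its complement; result is 0 unless the cluster-side PMI is
    positive, and never negative.
    """
    import math

    rows = [(labels.labels[pid], row[position]) for pid, row in msa.rows.items()
            if pid in labels.labels and row[position] != "-"]
    n = len(rows)
    if n == 0:
        return 0.0
    in_cluster = [r for c, r in rows if c == cluster]
    out_cluster = [r for c, r in rows if c != cluster]
    if not in_cluster:
        return 0.0
    p_joint_in = sum(1 for c, r in rows if c == cluster and r == residue) / n
    p_joint_out = sum(1 for c, r in rows if c != cluster and r == residue) / n
    p_c = len(in_cluster) / n
    p_cbar = len(out_cluster) / n
    p_r = sum(1 for _, r in rows if r == residue) / n
    if p_joint_in == 0 or p_r == 0:
        return 0.0
    pmi_in = math.log(p_joint_in / (p_c * p_r))
    if pmi_in <= 0:
        return 0.0
    w_in = in_cluster.count(residue) / len(in_cluster)
    total = w_in * pmi_in
    if p_cbar > 0 and p_joint_out > 0:
        pmi_out = math.log(p_joint_out / (p_cbar * p_r))
        w_out = out_cluster.count(residue) / len(out_cluster)
        total += w_out * pmi_out
    return max(0.0, total)


def brute_force_pair_counts(truth: list, clusters: list):
    """O(N^2) enumeration of all object pairs."""
    n = len(truth)
    tp = fp = fn = tn = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_class = truth[i] == truth[j]
            same_cluster = clusters[i] == clusters[j]
            if same_class and same_cluster:
                tp += 1
            elif same_class:
                fn += 1
            elif same_cluster:
                fp += 1
            else:
                tn += 1
    return tp, fp, fn, tn
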
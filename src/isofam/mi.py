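"""Active-site mutual-information cluster scoring and SDP ranking.

A clustering is good when each cluster shows (almost) exclusive residues at
specific active-site positions. For position p, cluster c and residue r the
partial score is

    MI_p(c, r) = p_p(c, r) * PMI_p(c, r) + p_p(c-bar, r) * PMI_p(c-bar, r)

where PMI(x, y) = ln p(x,y) / (p(x) p(y)), the joint and marginal
probabilities are taken over the non-gap rows at p, and the weights
p_p(c, r) / p_p(c-bar, r) are residue r's frequencies within the cluster and
within its complement. A residue must be over-represented in the cluster
(PMI_p(c, r) > 0) to count; occurrence elsewhere pulls the score down
through the negative complement term, and the result is floored at 0.
Position scores aggregate residues weighted by within-cluster frequency
(gaps excluded), and the overall quality averages over all P positions and
C clusters:

    MI = (1/P) (1/C) sum_p sum_c MI_p(c)

which is the fitness the evolutionary search maximizes. The same partial
terms, ranked per cluster, point at the residues/positions that
differentiate each cluster (candidate specificity determining positions).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._tables import AMINO_ACIDS, GAP
from .pockets import ActiveSiteAlignment
from .spectral import ClusterAssignment


class MIError(ValueError):
    pass


def pmi(p_joint: float, p_x: float, p_y: float) -> float:
    """Pointwise mutual information ln(p(x,y) / (p(x) p(y))), natural log.

    Returns -inf when p_joint is 0 (callers weight it by 0 or floor it).
    """
    for p in (p_joint, p_x, p_y):
        if not 0.0 <= p <= 1.0:
            raise MIError(f"probability {p} outside [0,1]")
    if p_x == 0 or p_y == 0:
        raise MIError("marginal probabilities must be positive")
    if p_joint == 0:
        return -math.inf
    return math.log(p_joint / (p_x * p_y))


@dataclass
class MIReport:
    """Overall MI plus per-(position, cluster) and per-residue partial terms."""

    overall: float
    unnormalized_sum: float
    per_position_cluster: dict[tuple[int, int], float]
    per_residue: dict[tuple[int, int, str], tuple[float, float]]  # -> (MI, f_k)
    positions: int
    clusters: int

    def to_json(self, path) -> None:
        payload = {
            "overall": self.overall,
            "unnormalized_sum": self.unnormalized_sum,
            "positions": self.positions,
            "clusters": self.clusters,
            "per_position_cluster": [
                {"position": p, "cluster": c, "mi": v}
                for (p, c), v in sorted(self.per_position_cluster.items())],
            "per_residue": [
                {"position": p, "cluster": c, "residue": r, "mi": v, "freq": f}
                for (p, c, r), (v, f) in sorted(self.per_residue.items())],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _position_counts(msa: ActiveSiteAlignment, labels: ClusterAssignment,
                     position: int):
    """Non-gap rows at a position: per-(cluster, residue) and marginal counts."""
    joint: dict[tuple[int, str], int] = {}
    cluster_n: dict[int, int] = {}
    residue_n: dict[str, int] = {}
    total = 0
    for pid, row in msa.rows.items():
        if pid not in labels.labels:
            continue
        res = row[position]
        if res == GAP:
            continue
        c = labels.labels[pid]
        joint[(c, res)] = joint.get((c, res), 0) + 1
        cluster_n[c] = cluster_n.get(c, 0) + 1
        residue_n[res] = residue_n.get(res, 0) + 1
        total += 1
    return joint, cluster_n, residue_n, total


def residue_cluster_mi(msa: ActiveSiteAlignment, labels: ClusterAssignment,
                       position: int, cluster: int, residue: str) -> float:
    """Partial MI of one residue for one cluster at one position (>= 0)."""
    joint, cluster_n, residue_n, total = _position_counts(msa, labels, position)
    return _partial_mi(joint, cluster_n, residue_n, total, cluster, residue)


def _partial_mi(joint, cluster_n, residue_n, total, cluster, residue) -> float:
    if total == 0:
        return 0.0
    n_c = cluster_n.get(cluster, 0)
    if n_c == 0:
        return 0.0  # cluster entirely gapped at this position
    n_r = residue_n.get(residue, 0)
    c_in = joint.get((cluster, residue), 0)
    if c_in == 0 or n_r == 0:
        return 0.0
    pmi_in = math.log((c_in / total) / ((n_c / total) * (n_r / total)))
    if pmi_in <= 0:
        return 0.0
    term = (c_in / n_c) * pmi_in
    n_cbar = total - n_c
    c_out = n_r - c_in
    if n_cbar > 0 and c_out > 0:
        pmi_out = math.log((c_out / total) / ((n_cbar / total) * (n_r / total)))
        term += (c_out / n_cbar) * pmi_out
    return max(0.0, term)


def position_cluster_mi(msa: ActiveSiteAlignment, labels: ClusterAssignment,
                        position: int, cluster: int,
                        weight_by_frequency: bool = True) -> float:
    """MI_p(c) = sum_k f_k MI_p(c, r_k) over residues present in the cluster."""
    joint, cluster_n, residue_n, total = _position_counts(msa, labels, position)
    n_c = cluster_n.get(cluster, 0)
    if n_c == 0:
        return 0.0
    out = 0.0
    for (c, res), count in joint.items():
        if c != cluster:
            continue
        f_k = count / n_c
        term = _partial_mi(joint, cluster_n, residue_n, total, cluster, res)
        out += (f_k * term) if weight_by_frequency else term
    return out


def overall_mi(msa: ActiveSiteAlignment, labels: ClusterAssignment,
               weight_by_frequency: bool = True) -> MIReport:
    """Score a clustering over all positions and clusters (the GP fitness)."""
    missing = [pid for pid in labels.labels if pid not in msa.rows]
    if missing:
        raise MIError(f"alignment lacks rows for labeled proteins: {missing[:5]}")
    p_total = msa.width
    if p_total == 0:
        raise MIError("alignment has zero positions")
    c_total = labels.k
    per_pc: dict[tuple[int, int], float] = {}
    per_residue: dict[tuple[int, int, str], tuple[float, float]] = {}
    total_sum = 0.0
    for p in range(p_total):
        joint, cluster_n, residue_n, total = _position_counts(msa, labels, p)
        for c in range(1, c_total + 1):
            n_c = cluster_n.get(c, 0)
            acc = 0.0
            if n_c > 0:
                for (cc, res), count in joint.items():
                    if cc != c:
                        continue
                    f_k = count / n_c
                    term = _partial_mi(joint, cluster_n, residue_n, total, c, res)
                    if term > 0:
                        per_residue[(p, c, res)] = (term, f_k)
                    acc += (f_k * term) if weight_by_frequency else term
            per_pc[(p, c)] = acc
            total_sum += acc
    return MIReport(
        overall=total_sum / (p_total * c_total),
        unnormalized_sum=total_sum,
        per_position_cluster=per_pc,
        per_residue=per_residue,
        positions=p_total,
        clusters=c_total,
    )


def rank_discriminative_residues(report: MIReport, cluster: int,
                                 top: int | None = None,
                                 position_labels: Mapping[int, int] | None = None
                                 ) -> list[tuple[str, float]]:
    """Residues with positive partial MI for a cluster, best first.

    Rendered as residue + 1-based position (+ reference-structure residue
    number when position labels are available), e.g. "K11_523". Ties break
    by (position, residue) for determinism.
    """
    entries = [
        (mi_value, p, r)
        for (p, c, r), (mi_value, _f) in report.per_residue.items()
        if c == cluster and mi_value > 0
    ]
    entries.sort(key=lambda t: (-t[0], t[1], t[2]))
    if top is not None:
        entries = entries[:top]
    out = []
    for mi_value, p, r in entries:
        label = f"{r}{p + 1}"
        if position_labels and p in position_labels:
            label += f"_{position_labels[p]}"
        out.append((label, mi_value))
    return out


PROFILE_ALPHABET = AMINO_ACIDS + GAP


def cluster_profile_matrix(msa: ActiveSiteAlignment, labels: ClusterAssignment
                           ) -> dict[int, np.ndarray]:
    """Per-cluster P x 21 residue/gap frequency matrices (logo-ready)."""
    profiles: dict[int, np.ndarray] = {}
    index = {ch: k for k, ch in enumerate(PROFILE_ALPHABET)}
    for c in range(1, labels.k + 1):
        members = labels.members(c)
        mat = np.zeros((msa.width, len(PROFILE_ALPHABET)))
        for pid in members:
            for p, res in enumerate(msa.rows[pid]):
                mat[p, index[res]] += 1
        mat /= max(1, len(members))
        profiles[c] = mat
    return profiles


def write_profiles(profiles: Mapping[int, np.ndarray], directory) -> None:
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for c, mat in profiles.items():
        df = pd.DataFrame(mat, columns=list(PROFILE_ALPHABET))
        df.index.name = "position"
        df.to_csv(directory / f"cluster_{c}_profile.tsv", sep="\t")


__all__ = [
    "MIError", "MIReport", "pmi", "residue_cluster_mi", "position_cluster_mi",
    "overall_mi", "rank_discriminative_residues", "cluster_profile_matrix",
    "write_profiles", "PROFILE_ALPHABET",
]
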
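"""Planted-subfamily benchmark generator.

Emulates the statistical structure of every input the pipeline consumes —
domain sequences, a putative-active-site alignment with planted
specificity-determining positions (SDPs), evidence matrices with block
structure, scalar property tables and candidate pockets — with known ground
truth, so every downstream module can be exercised without any external
data. SDP positions carry one dominant residue per subfamily (distinct
across subfamilies, mirroring the two-residue swaps that switch real enzyme
specificities), conserved positions carry one family-wide residue, random
positions are uniform. Informative matrices are two-level block matrices
(within/between means plus Gaussian noise); redundant matrices are
correlated copies; noise matrices are pure symmetric Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._tables import AMINO_ACIDS, GAP
from .evidence import EvidenceMatrix
from .family import PropertyTable, ProteinFamily
from .pockets import ActiveSiteAlignment, PocketSet


class SyntheticError(ValueError):
    pass


@dataclass
class MatrixPlan:
    """Role of one generated evidence matrix."""

    name: str
    role: str = "informative"    # informative | redundant | noise
    rho: float = 0.9             # correlation to the informative matrix (redundant)
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("informative", "redundant", "noise"):
            raise SyntheticError(f"unknown matrix role {self.role!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise SyntheticError("rho must lie in [-1, 1]")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise SyntheticError("missing fraction must lie in [0, 1)")


@dataclass
class SyntheticFamilySpec:
    """Study conditions for a planted-subfamily benchmark.

    Defaults: 60 proteins in 3 equal subfamilies, a 10-position active site
    with 3 SDP positions (residue flip noise 5%), 4 family-conserved and 3
    uniform positions, 2% gaps, one informative evidence matrix (within-block
    mean 0.9, between 0.1, noise SD 0.1) plus two pure-noise matrices.
    """

    n: int = 60
    sizes: tuple[int, ...] = (20, 20, 20)
    sdp_positions: int = 3
    conserved_positions: int = 4
    random_positions: int = 3
    sdp_noise: float = 0.05
    gap_rate: float = 0.02
    within_mean: float = 0.9
    between_mean: float = 0.1
    noise_sd: float = 0.1
    sequence_length: int = 80
    matrices: tuple[MatrixPlan, ...] = (
        MatrixPlan("informative_0", "informative"),
        MatrixPlan("noise_0", "noise"),
        MatrixPlan("noise_1", "noise"),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.sizes) != self.n:
            raise SyntheticError("subfamily sizes must sum to N")
        if any(s < 1 for s in self.sizes):
            raise SyntheticError("subfamily sizes must be positive")
        for rate in (self.sdp_noise, self.gap_rate):
            if not 0.0 <= rate <= 1.0:
                raise SyntheticError("rates must lie in [0, 1]")
        if len(self.sizes) > len(AMINO_ACIDS):
            raise SyntheticError("more subfamilies than distinct dominant residues")

    @property
    def k_true(self) -> int:
        return len(self.sizes)

    @property
    def positions(self) -> int:
        return self.sdp_positions + self.conserved_positions + self.random_positions


def _planted_block_matrix(rng: np.random.Generator, membership: np.ndarray,
                          spec: SyntheticFamilySpec) -> np.ndarray:
    same = membership[:, None] == membership[None, :]
    base = np.where(same, spec.within_mean, spec.between_mean).astype(float)
    noise = rng.normal(0.0, spec.noise_sd, size=base.shape)
    noise = (noise + noise.T) / 2.0
    values = base + (noise if spec.noise_sd > 0 else 0.0)
    np.fill_diagonal(values, spec.within_mean)
    return values


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float = 1.0) -> np.ndarray:
    noise = rng.normal(0.0, sd, size=(n, n))
    noise = (noise + noise.T) / 2.0
    np.fill_diagonal(noise, 0.0)
    return noise


def generate_family(spec: SyntheticFamilySpec
                    ) -> tuple[ProteinFamily, ActiveSiteAlignment,
                               dict[str, EvidenceMatrix], PropertyTable]:
    """Generate a labeled family, active-site MSA, evidence set and properties."""
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    ids = [f"P{idx:04d}" for idx in range(spec.n)]
    membership = np.repeat(np.arange(spec.k_true), spec.sizes)
    labels = {pid: f"subfamily_{membership[i] + 1}" for i, pid in enumerate(ids)}

    aa = np.array(list(AMINO_ACIDS))

    # active-site alignment with planted structure
    columns: list[np.ndarray] = []
    for _ in range(spec.sdp_positions):
        dominant = rng.choice(len(aa), size=spec.k_true, replace=False)
        col = aa[dominant[membership]].copy()
        flip = rng.random(spec.n) < spec.sdp_noise
        col[flip] = aa[rng.integers(0, len(aa), size=int(flip.sum()))]
        columns.append(col)
    for _ in range(spec.conserved_positions):
        columns.append(np.full(spec.n, rng.choice(aa)))
    for _ in range(spec.random_positions):
        columns.append(aa[rng.integers(0, len(aa), size=spec.n)])
    site = np.stack(columns, axis=1)
    gaps = rng.random(site.shape) < spec.gap_rate
    site[gaps] = GAP
    msa = ActiveSiteAlignment(
        rows={pid: "".join(site[i]) for i, pid in enumerate(ids)})

    # domain sequences: subfamily consensus with per-protein substitutions
    consensus = {k: aa[rng.integers(0, len(aa), size=spec.sequence_length)]
                 for k in range(spec.k_true)}
    sequences = {}
    for i, pid in enumerate(ids):
        seq = consensus[membership[i]].copy()
        mutate = rng.random(spec.sequence_length) < 0.1
        seq[mutate] = aa[rng.integers(0, len(aa), size=int(mutate.sum()))]
        sequences[pid] = "".join(seq)

    # evidence matrices per plan
    matrices: dict[str, EvidenceMatrix] = {}
    informative_values: np.ndarray | None = None
    for plan in spec.matrices:
        if plan.role == "informative":
            values = _planted_block_matrix(rng, membership, spec)
            if informative_values is None:
                informative_values = values
        elif plan.role == "redundant":
            if informative_values is None:
                raise SyntheticError("redundant matrix requires a preceding "
                                     "informative matrix in the plan")
            jitter = _symmetric_noise(rng, spec.n, sd=informative_values.std())
            values = (plan.rho * informative_values
                      + np.sqrt(max(0.0, 1 - plan.rho**2)) * jitter)
        else:
            values = _symmetric_noise(rng, spec.n)
        missing = np.zeros((spec.n, spec.n), dtype=bool)
        if plan.missing_fraction > 0:
            iu = np.triu_indices(spec.n, k=1)
            drop = rng.random(len(iu[0])) < plan.missing_fraction
            missing[iu[0][drop], iu[1][drop]] = True
            missing |= missing.T
        matrices[plan.name] = EvidenceMatrix(
            name=plan.name, ids=ids, values=values, missing=missing)

    # per-subfamily scalar properties with overlap
    centers = rng.normal(0.0, 1.0, size=spec.k_true)
    props = PropertyTable(scalars=pd.DataFrame({
        "molWeight": 20000 + 2000 * centers[membership]
        + rng.normal(0, 500, spec.n),
        "isoPoint": 7.0 + 0.5 * centers[membership] + rng.normal(0, 0.3, spec.n),
    }, index=pd.Index(ids, name="id")))

    family = ProteinFamily(ids=ids, sequences=sequences, labels=labels)
    return family, msa, matrices, props


def truth_assignment(family: ProteinFamily) -> "ClusterAssignment":
    """The planted partition as a cluster assignment (labels sorted to 1..K)."""
    from .spectral import ClusterAssignment

    if not family.labels:
        raise SyntheticError("family carries no truth labels")
    names = sorted(set(family.labels.values()))
    index = {name: k + 1 for k, name in enumerate(names)}
    return ClusterAssignment(
        labels={pid: index[family.labels[pid]] for pid in family.ids},
        k=len(names))


def generate_pockets(spec: SyntheticFamilySpec, n_pockets: int = 3,
                     which_is_site: int = 0) -> PocketSet:
    """Candidate pockets where only the designated one passes the
    conservation rule (>= 3 positions conserved at >= 50%) and carries the
    top pocket score."""
    if not 0 <= which_is_site < n_pockets:
        raise SyntheticError("which_is_site out of range")
    rng = np.random.default_rng(spec.seed + 1)
    ids = [f"P{idx:04d}" for idx in range(spec.n)]
    aa = np.array(list(AMINO_ACIDS))
    pockets = {}
    for p in range(n_pockets):
        width = 6
        if p == which_is_site:
            cols = [np.full(spec.n, rng.choice(aa)) for _ in range(4)]
            cols += [aa[rng.integers(0, len(aa), size=spec.n)] for _ in range(width - 4)]
            score = 50.0
        else:
            # fully random columns: with 20 residues and N >= 8 rows no column
            # reaches 50% conservation except with negligible probability
            cols = [aa[rng.integers(0, len(aa), size=spec.n)] for _ in range(width)]
            score = 60.0 + p  # higher score, but fails the conservation rule
        site = np.stack(cols, axis=1)
        pockets[f"pocket_{p}"] = (
            ActiveSiteAlignment(rows={pid: "".join(site[i])
                                      for i, pid in enumerate(ids)}),
            score)
    return PocketSet(pockets=pockets)


def write_dataset(spec: SyntheticFamilySpec, directory) -> None:
    """Write a generated dataset in the same formats the loaders read."""
    from pathlib import Path

    from .evidence import write_matrix
    from .family import write_fasta
    from .pockets import write_active_site_fasta

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    family, msa, matrices, props = generate_family(spec)
    write_fasta(family, directory / "family.fasta")
    write_active_site_fasta(msa, directory / "active_site.fasta")
    with open(directory / "labels.tsv", "w") as fh:
        fh.write("id\tlabel\n")
        for pid in family.ids:
            fh.write(f"{pid}\t{family.labels[pid]}\n")
    props_df = props.scalars.copy()
    props_df.to_csv(directory / "properties.tsv", sep="\t")
    mat_dir = directory / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for name, m in matrices.items():
        write_matrix(m, mat_dir / f"{name}.tsv")


__all__ = [
    "SyntheticError", "MatrixPlan", "SyntheticFamilySpec",
    "generate_family", "generate_pockets", "truth_assignment", "write_dataset",
]
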
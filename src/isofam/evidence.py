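"""Pairwise functional-similarity evidence matrices.

Each evidence source yields one symmetric N x N matrix over the family.
Sources computable from sequences and properties are built here (alignment
scores, active-site comparisons, property differences, composition
distances, shared-annotation counts); sources produced upstream by external
tools (structural alignments, structural signatures, genomic context) enter
as pair-score tables. Before integration every matrix is min-max normalized
into a common similarity orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from ._tables import (AA_CLASSES, AMINO_ACIDS, CLASS_PROPERTY_TO_EVIDENCE,
                      DAYHOFF_FREQ_PERCENT, EVIDENCE_ORIENTATION, GAP)
from .family import PairScoreTable, PropertyTable, ProteinFamily

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class EvidenceError(ValueError):
    pass


@dataclass
class EvidenceMatrix:
    """Named symmetric pairwise evidence with orientation and missing mask."""

    name: str
    ids: list[str]
    values: np.ndarray
    orientation: str = "similarity"          # or "distance"
    missing: np.ndarray | None = None        # symmetric boolean mask
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise EvidenceError(f"{self.name}: values must be {n}x{n}")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise EvidenceError(f"{self.name}: matrix not symmetric")
        if self.orientation not in ("similarity", "distance"):
            raise EvidenceError(f"{self.name}: bad orientation {self.orientation!r}")
        if self.missing is None:
            self.missing = np.zeros((n, n), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if not (self.missing == self.missing.T).all():
                raise EvidenceError(f"{self.name}: missing mask not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_pair_table(cls, table: PairScoreTable, ids: Sequence[str],
                        orientation: str | None = None) -> "EvidenceMatrix":
        """Build a matrix from sparse pair rows; absent pairs become missing."""
        ids = list(ids)
        index = {pid: k for k, pid in enumerate(ids)}
        n = len(ids)
        values = np.zeros((n, n))
        missing = np.ones((n, n), dtype=bool)
        np.fill_diagonal(missing, False)
        for key, value in table.entries.items():
            a, b = key
            i, j = index[a], index[b]
            values[i, j] = values[j, i] = value
            missing[i, j] = missing[j, i] = False
        if orientation is None:
            orientation = ("distance" if EVIDENCE_ORIENTATION.get(table.name)
                           == "distance" else "similarity")
        return cls(name=table.name, ids=ids, values=values,
                   orientation=orientation, missing=missing)


# ---------------------------------------------------------------------------
# pairwise sequence alignment scores

def _make_aligner(mode: str, matrix_name: str, gap_open: float,
                  gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_sequence(seq: str, on_unknown: str) -> str:
    if not seq:
        raise EvidenceError("empty sequence")
    unknown = set(seq) - set(AMINO_ACIDS)
    if unknown:
        if on_unknown == "error":
            raise EvidenceError(f"unknown residue letters: {sorted(unknown)}")
        return "".join(c if c in AMINO_ACIDS else "X" for c in seq)
    return seq


def _alignment_score(mode: str, seq_a: str, seq_b: str, matrix: str,
                     gap_open: float, gap_extend: float, on_unknown: str) -> float:
    seq_a = _check_sequence(seq_a, on_unknown)
    seq_b = _check_sequence(seq_b, on_unknown)
    aligner = _make_aligner(mode, matrix, gap_open, gap_extend)
    if "X" in seq_a or "X" in seq_b:
        # treat-as-X convention: X scores 0 against everything
        mat = aligner.substitution_matrix.copy()
        alpha = mat.alphabet
        xi = alpha.index("X")
        for k in range(len(alpha)):
            mat[xi, k] = mat[k, xi] = 0.0
        aligner.substitution_matrix = mat
    return float(aligner.score(seq_a, seq_b))


def global_alignment_score(seq_a: str, seq_b: str, *, matrix: str = "BLOSUM62",
                           gap_open: float = 10.0, gap_extend: float = 4.0,
                           on_unknown: str = "error") -> float:
    """Needleman-Wunsch global score (affine gaps, cost open + L*extend)."""
    return _alignment_score("global", seq_a, seq_b, matrix, gap_open,
                            gap_extend, on_unknown)


def local_alignment_score(seq_a: str, seq_b: str, *, matrix: str = "BLOSUM62",
                          gap_open: float = 10.0, gap_extend: float = 4.0,
                          on_unknown: str = "error") -> float:
    """Smith-Waterman local score, floored at 0."""
    return max(0.0, _alignment_score("local", seq_a, seq_b, matrix, gap_open,
                                     gap_extend, on_unknown))


def alignment_score_matrix(family: ProteinFamily, mode: str = "global",
                           **kwargs) -> EvidenceMatrix:
    name = {"global": "seqAliG", "local": "seqAliL"}[mode]
    score = global_alignment_score if mode == "global" else local_alignment_score
    n = len(family.ids)
    values = np.zeros((n, n))
    for i in range(n):
        si = family.sequences[family.ids[i]]
        values[i, i] = score(si, si, **kwargs)
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = score(si, family.sequences[family.ids[j]],
                                                **kwargs)
    return EvidenceMatrix(name=name, ids=list(family.ids), values=values)


# ---------------------------------------------------------------------------
# active-site comparisons

def _comparable_columns(site_a: str, site_b: str) -> list[int]:
    if len(site_a) != len(site_b):
        raise EvidenceError("active-site strings have different widths")
    return [k for k in range(len(site_a))
            if site_a[k] != GAP and site_b[k] != GAP]


def active_site_identity(site_a: str, site_b: str) -> float:
    """Percent identity over gap-free columns; 0 (with warning) if none."""
    cols = _comparable_columns(site_a, site_b)
    if not cols:
        warnings.warn("no comparable (gap-free) columns; identity set to 0")
        return 0.0
    matches = sum(site_a[k] == site_b[k] for k in cols)
    return 100.0 * matches / len(cols)


def active_site_blosum62(site_a: str, site_b: str) -> float:
    """Summed BLOSUM62 score over gap-free columns; 0 (with warning) if none."""
    cols = _comparable_columns(site_a, site_b)
    if not cols:
        warnings.warn("no comparable (gap-free) columns; score set to 0")
        return 0.0
    return float(sum(_BLOSUM62[site_a[k], site_b[k]] for k in cols))


def active_site_matrices(msa: "Mapping[str, str] | object", ids: Sequence[str] | None = None
                         ) -> tuple[EvidenceMatrix, EvidenceMatrix]:
    """ASid / ASscr matrices from an active-site alignment (id -> gapped row)."""
    rows = msa.rows if hasattr(msa, "rows") else dict(msa)
    ids = list(ids) if ids is not None else list(rows)
    n = len(ids)
    ident = np.zeros((n, n))
    score = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            ident[i, i] = active_site_identity(rows[ids[i]], rows[ids[i]])
            score[i, i] = active_site_blosum62(rows[ids[i]], rows[ids[i]])
            for j in range(i + 1, n):
                ident[i, j] = ident[j, i] = active_site_identity(rows[ids[i]], rows[ids[j]])
                score[i, j] = score[j, i] = active_site_blosum62(rows[ids[i]], rows[ids[j]])
    return (EvidenceMatrix(name="ASid", ids=ids, values=ident),
            EvidenceMatrix(name="ASscr", ids=ids, values=score))


# ---------------------------------------------------------------------------
# property-derived matrices

def scalar_difference_matrix(column: Mapping[str, float], ids: Sequence[str],
                             name: str) -> EvidenceMatrix:
    """|v_i - v_j| distance-like matrix; pairs with an absent value are missing."""
    ids = list(ids)
    n = len(ids)
    v = np.array([float(column.get(i, np.nan)) for i in ids])
    if np.isinf(v).any():
        raise EvidenceError(f"{name}: non-finite property value")
    present = ~np.isnan(v)
    values = np.abs(np.subtract.outer(np.nan_to_num(v), np.nan_to_num(v)))
    missing = ~(np.outer(present, present))
    np.fill_diagonal(missing, False)
    values[missing] = 0.0
    return EvidenceMatrix(name=name, ids=ids, values=values,
                          orientation="distance", missing=missing)


def vector_distance_matrix(vectors: Mapping[str, Sequence[float]],
                           ids: Sequence[str], name: str,
                           metric: str = "euclidean") -> EvidenceMatrix:
    """Pairwise Euclidean or squared-Euclidean distances between arrays."""
    ids = list(ids)
    arrays = [np.asarray(vectors[i], dtype=float) for i in ids]
    widths = {a.shape for a in arrays}
    if len(widths) > 1:
        raise EvidenceError(f"{name}: arrays of differing lengths")
    x = np.vstack(arrays)
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    if metric == "euclidean":
        values = np.sqrt(sq)
    elif metric == "squared-euclidean":
        values = sq
    else:
        raise EvidenceError(f"unknown metric {metric!r}")
    return EvidenceMatrix(name=name, ids=ids, values=values, orientation="distance")


def shared_annotation_matrix(sets: Mapping[str, set], ids: Sequence[str],
                             name: str) -> EvidenceMatrix:
    """values[i][j] = number of annotation identifiers shared by i and j."""
    ids = list(ids)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        si = sets.get(ids[i], set())
        values[i, i] = len(si)
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = len(si & sets.get(ids[j], set()))
    return EvidenceMatrix(name=name, ids=ids, values=values)


def sequence_derived_properties(seq: str) -> dict[str, float | np.ndarray]:
    """Sequence-computable properties: average molecular weight (Da), molar
    percentage per amino-acid class, GRAVY, and the Dayhoff-normalized
    composition array (molar fraction over reference frequency, 20 entries).

    Isoelectric point and instability index are input-only scalars, not
    computed here.
    """
    from Bio.SeqUtils.ProtParam import ProteinAnalysis

    if not seq:
        raise EvidenceError("empty sequence")
    unknown = set(seq) - set(AMINO_ACIDS)
    if unknown:
        raise EvidenceError(f"unknown residue letters: {sorted(unknown)}")
    analysis = ProteinAnalysis(seq)
    counts = {aa: seq.count(aa) for aa in AMINO_ACIDS}
    n = len(seq)
    record: dict[str, float | np.ndarray] = {
        "molWeight": float(analysis.molecular_weight()),
        "gravy": float(analysis.gravy()),
    }
    for cls_name, members in AA_CLASSES.items():
        record[cls_name] = 100.0 * sum(counts[a] for a in members) / n
    record["composition"] = np.array(
        [(100.0 * counts[a] / n) / DAYHOFF_FREQ_PERCENT[a] for a in AMINO_ACIDS])
    return record


def property_matrices(family: ProteinFamily, props: PropertyTable
                      ) -> list[EvidenceMatrix]:
    """All evidence matrices derivable from a property table."""
    out: list[EvidenceMatrix] = []
    scalar_to_name = {"molWeight": "difMolWeight", "isoPoint": "difIsoPoint",
                      "instability": "difInstab", "gravy": "difGRAVY",
                      **CLASS_PROPERTY_TO_EVIDENCE}
    for col, name in scalar_to_name.items():
        if col in props.scalars.columns:
            out.append(scalar_difference_matrix(
                props.scalars[col].dropna().to_dict(), family.ids, name))
    for col, name in (("interpro", "interpro"), ("go", "go")):
        if col in props.sets:
            out.append(shared_annotation_matrix(props.sets[col], family.ids, name))
    return out


def sequence_property_matrices(family: ProteinFamily) -> list[EvidenceMatrix]:
    """Property-difference and composition-distance matrices computed from
    the domain subsequences themselves."""
    records = {pid: sequence_derived_properties(family.sequences[pid])
               for pid in family.ids}
    out = []
    for col, name in (("molWeight", "difMolWeight"), ("gravy", "difGRAVY"),
                      *CLASS_PROPERTY_TO_EVIDENCE.items()):
        out.append(scalar_difference_matrix(
            {pid: r[col] for pid, r in records.items()}, family.ids, name))
    out.append(vector_distance_matrix(
        {pid: r["composition"] for pid, r in records.items()},
        family.ids, "aaCompDist", metric="squared-euclidean"))
    return out


# ---------------------------------------------------------------------------
# normalization and correlation

def normalize_matrix(m: EvidenceMatrix) -> EvidenceMatrix:
    """Min-max normalize into common similarity orientation.

    Present off-diagonal values are affinely mapped to [0,1], or to [-1,1]
    when negatives exist; distance-like matrices are then interval-reversed
    so larger always means more similar. Missing entries are imputed as the
    minimum-similarity value of the target interval, and the diagonal is set
    to maximum similarity. A constant matrix maps to all zeros with a warning.
    """
    if m.normalized:
        return m
    n = m.n
    off = ~np.eye(n, dtype=bool)
    present = off & ~m.missing
    values = m.values.astype(float).copy()
    if present.sum() == 0:
        raise EvidenceError(f"{m.name}: no present off-diagonal values")
    raw = values[present]
    lo, hi = raw.min(), raw.max()
    negative = lo < 0
    floor, ceil = (-1.0, 1.0) if negative else (0.0, 1.0)
    out = np.empty_like(values)
    if hi == lo:
        warnings.warn(f"{m.name}: constant matrix; normalized to all zeros")
        out[:] = 0.0
        reversed_floor = 0.0
        out[m.missing & off] = 0.0
        np.fill_diagonal(out, 0.0)
        return replace(m, values=out, orientation="similarity",
                       missing=np.zeros((n, n), dtype=bool), normalized=True)
    scaled = floor + (ceil - floor) * (values - lo) / (hi - lo)
    if m.orientation == "distance":
        # reverse within the target interval so larger = more similar
        scaled = (1.0 - scaled) if not negative else -scaled
    out = scaled
    out[m.missing & off] = floor
    np.fill_diagonal(out, ceil)
    out = (out + out.T) / 2.0
    return replace(m, values=out, orientation="similarity",
                   missing=np.zeros((n, n), dtype=bool), normalized=True)


def matrix_correlation(a: EvidenceMatrix, b: EvidenceMatrix) -> float:
    """Pearson correlation over upper-triangle pairs present in both."""
    if a.ids != b.ids:
        raise EvidenceError("matrices cover different protein sets")
    iu = np.triu_indices(a.n, k=1)
    present = ~(a.missing[iu] | b.missing[iu])
    x, y = a.values[iu][present], b.values[iu][present]
    if len(x) < 2:
        raise EvidenceError("fewer than 2 common pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EvidenceError("zero variance; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# serialization

def write_matrix(m: EvidenceMatrix, tsv_path, sidecar_path=None) -> None:
    import json
    from pathlib import Path

    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as fh:
        fh.write("id_a\tid_b\tvalue\n")
        for i in range(m.n):
            for j in range(i + 1, m.n):
                if not m.missing[i, j]:
                    fh.write(f"{m.ids[i]}\t{m.ids[j]}\t{m.values[i, j]:.10g}\n")
    sidecar = Path(sidecar_path) if sidecar_path else tsv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "name": m.name, "orientation": m.orientation,
        "normalized": m.normalized, "ids": m.ids}, indent=1))


def read_matrix(tsv_path, sidecar_path=None) -> EvidenceMatrix:
    import json
    from pathlib import Path

    from .family import read_pair_table

    tsv_path = Path(tsv_path)
    sidecar = Path(sidecar_path) if sidecar_path else tsv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    table = read_pair_table(tsv_path, name=meta["name"], known_ids=meta["ids"])
    m = EvidenceMatrix.from_pair_table(table, meta["ids"],
                                       orientation=meta["orientation"])
    m.normalized = bool(meta.get("normalized", False))
    return m


__all__ = [
    "EvidenceError", "EvidenceMatrix",
    "global_alignment_score", "local_alignment_score", "alignment_score_matrix",
    "active_site_identity", "active_site_blosum62", "active_site_matrices",
    "scalar_difference_matrix", "vector_distance_matrix",
    "shared_annotation_matrix", "sequence_derived_properties",
    "property_matrices", "sequence_property_matrices",
    "normalize_matrix", "matrix_correlation", "write_matrix", "read_matrix",
]
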
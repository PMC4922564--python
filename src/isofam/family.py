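"""Protein-family containers, loaders and family-definition filters.

A family is the set of proteins carrying a shared domain; the sequences held
here are the domain subsequences, and both filters below operate on them:
a length filter (keep proteins within one standard deviation of the mean
domain length) and a reference-identity filter (keep proteins with at least a
threshold percent identity to at least one reference structure, the minimum
required for homology modeling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO


class FamilyError(ValueError):
    """Raised for malformed or inconsistent family inputs."""


@dataclass
class ProteinFamily:
    """Ordered set of protein ids with optional sequences and truth labels."""

    ids: list[str]
    sequences: dict[str, str] = field(default_factory=dict)
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.ids:
            raise FamilyError("family must contain at least one protein id")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FamilyError(f"duplicate protein ids: {dupes}")
        known = set(self.ids)
        for keyed, what in ((self.sequences, "sequence"), (self.labels or {}, "label")):
            unknown = set(keyed) - known
            if unknown:
                raise FamilyError(f"{what} entries for unknown ids: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, keep: Iterable[str]) -> "ProteinFamily":
        keep = set(keep)
        return ProteinFamily(
            ids=[i for i in self.ids if i in keep],
            sequences={i: s for i, s in self.sequences.items() if i in keep},
            labels=None if self.labels is None
            else {i: l for i, l in self.labels.items() if i in keep},
        )


@dataclass
class PairScoreTable:
    """Symmetric per-pair evidence values keyed by unordered id pairs."""

    name: str
    entries: dict[frozenset, float]

    @classmethod
    def from_rows(cls, name: str, rows: Iterable[tuple[str, str, float]],
                  known_ids: Iterable[str] | None = None) -> "PairScoreTable":
        known = set(known_ids) if known_ids is not None else None
        entries: dict[frozenset, float] = {}
        for id_a, id_b, value in rows:
            if id_a == id_b:
                raise FamilyError(f"{name}: self-pair ({id_a},{id_b})")
            if known is not None:
                for i in (id_a, id_b):
                    if i not in known:
                        raise FamilyError(f"{name}: pair references unknown id {i!r}")
            key = frozenset((id_a, id_b))
            if key in entries:
                raise FamilyError(f"{name}: duplicate pair ({id_a},{id_b})")
            value = float(value)
            if not math.isfinite(value):
                raise FamilyError(f"{name}: non-finite value for pair ({id_a},{id_b})")
            entries[key] = value
        return cls(name=name, entries=entries)

    def __len__(self) -> int:
        return len(self.entries)


# Scalar columns a property table may carry. Isoelectric point and
# instability index are accepted as inputs only (computed upstream).
SCALAR_COLUMNS = (
    "molWeight", "isoPoint", "instability", "gravy",
    "aliphatic", "aromatic", "nonpolar", "polar", "charged", "basic", "acidic",
)
SET_COLUMNS = ("interpro", "go")


@dataclass
class PropertyTable:
    """Per-protein scalar properties plus set-valued annotation columns."""

    scalars: pd.DataFrame                      # index = protein id
    sets: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.scalars.columns) - set(SCALAR_COLUMNS)
        if unknown:
            raise FamilyError(f"unknown scalar property columns: {sorted(unknown)}")
        unknown = set(self.sets) - set(SET_COLUMNS)
        if unknown:
            raise FamilyError(f"unknown annotation-set columns: {sorted(unknown)}")
        bad = self.scalars.columns[~self.scalars.apply(
            lambda c: pd.to_numeric(c, errors="coerce").notna() | c.isna()).all()]
        if len(bad):
            raise FamilyError(f"non-numeric values in scalar columns: {list(bad)}")

    @classmethod
    def empty(cls) -> "PropertyTable":
        return cls(scalars=pd.DataFrame(), sets={})


# ---------------------------------------------------------------------------
# loaders

def read_fasta_family(path: str | Path, labels: Mapping[str, str] | None = None
                      ) -> ProteinFamily:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FamilyError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = {r.id: str(r.seq).upper() for r in records}
    if len(set(ids)) != len(ids):
        raise FamilyError(f"duplicate ids in {path}")
    fam = ProteinFamily(ids=ids, sequences=seqs)
    if labels is not None:
        fam.labels = {i: labels[i] for i in ids if i in labels}
    return fam


def read_pair_table(path: str | Path, name: str | None = None,
                    known_ids: Iterable[str] | None = None) -> PairScoreTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    required = {"id_a", "id_b", "value"}
    if not required.issubset(df.columns):
        raise FamilyError(f"{path}: pair table needs columns id_a, id_b, value")
    if df["value"].isna().any():
        raise FamilyError(f"{path}: malformed value column")
    return PairScoreTable.from_rows(
        name or path.stem,
        df[["id_a", "id_b", "value"]].itertuples(index=False, name=None),
        known_ids=known_ids,
    )


def read_property_table(path: str | Path, known_ids: Iterable[str] | None = None
                        ) -> PropertyTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}).set_index("id")
    if known_ids is not None:
        unknown = set(df.index) - set(known_ids)
        if unknown:
            raise FamilyError(f"property rows for unknown ids: {sorted(unknown)}")
    sets: dict[str, dict[str, set[str]]] = {}
    for col in SET_COLUMNS:
        if col in df.columns:
            sets[col] = {
                pid: set(str(v).split(";")) - {"", "nan"}
                for pid, v in df[col].items()
            }
            df = df.drop(columns=[col])
    return PropertyTable(scalars=df.astype(float), sets=sets)


def read_label_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "label"}.issubset(df.columns):
        raise FamilyError(f"{path}: label table needs columns id, label")
    return dict(zip(df["id"], df["label"]))


def load_family_inputs(fasta: str | Path,
                       pair_tables: Iterable[str | Path] = (),
                       properties: str | Path | None = None,
                       labels: str | Path | None = None,
                       ) -> tuple[ProteinFamily, list[PairScoreTable], PropertyTable]:
    """Load and cross-validate all family inputs.

    Missing per-pair entries are simply absent from the returned tables; they
    become a missing mask on the evidence matrices, never fabricated values.
    """
    label_map = read_label_table(labels) if labels else None
    fam = read_fasta_family(fasta, labels=label_map)
    tables = [read_pair_table(p, known_ids=fam.ids) for p in pair_tables]
    props = (read_property_table(properties, known_ids=fam.ids)
             if properties else PropertyTable.empty())
    return fam, tables, props


# ---------------------------------------------------------------------------
# family-definition filters

def filter_by_length(family: ProteinFamily) -> ProteinFamily:
    """Keep proteins whose domain length is within one SD of the mean.

    Statistics (mean and sample SD, n-1 denominator) are computed over the
    lengths of this call's input; re-applying the filter recomputes them on
    the already-filtered set.
    """
    missing = [i for i in family.ids if i not in family.sequences]
    if missing:
        raise FamilyError(f"length filter requires sequences for all ids: {missing}")
    lengths = [len(family.sequences[i]) for i in family.ids]
    if len(lengths) < 2:
        raise FamilyError("length filter needs at least 2 sequences (SD undefined)")
    mean = sum(lengths) / len(lengths)
    sd = math.sqrt(sum((l - mean) ** 2 for l in lengths) / (len(lengths) - 1))
    keep = [i for i, l in zip(family.ids, lengths) if abs(l - mean) <= sd]
    return family.subset(keep)


def filter_by_reference_identity(
    family: ProteinFamily,
    identities: Mapping[str, Mapping[str, float]],
    threshold: float = 30.0,
    on_missing: str = "error",
) -> ProteinFamily:
    """Keep proteins with >= threshold %identity to at least one reference."""
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    keep = []
    for pid in family.ids:
        per_ref = identities.get(pid)
        if not per_ref:
            if on_missing == "error":
                raise FamilyError(f"no reference identities for {pid}")
            continue
        values = list(per_ref.values())
        if any(not (0.0 <= v <= 100.0) for v in values):
            raise FamilyError(f"identity out of [0,100] for {pid}")
        if max(values) >= threshold:
            keep.append(pid)
    return family.subset(keep)


def write_fasta(family: ProteinFamily, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in family.ids:
            if pid in family.sequences:
                fh.write(f">{pid}\n{family.sequences[pid]}\n")


def write_pair_table(table: PairScoreTable, path: str | Path) -> None:
    rows = []
    for key, value in table.entries.items():
        id_a, id_b = sorted(key)
        rows.append((id_a, id_b, value))
    rows.sort()
    pd.DataFrame(rows, columns=["id_a", "id_b", "value"]).to_csv(
        path, sep="\t", index=False)


__all__ = [
    "FamilyError", "ProteinFamily", "PairScoreTable", "PropertyTable",
    "SCALAR_COLUMNS", "SET_COLUMNS",
    "read_fasta_family", "read_pair_table", "read_property_table",
    "read_label_table", "load_family_inputs",
    "filter_by_length", "filter_by_reference_identity",
    "write_fasta", "write_pair_table",
]
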
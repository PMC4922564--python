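"""Putative active-site selection among candidate surface pockets.

Each candidate pocket of the reference structure comes with a fixed-width
gapped alignment (one row per family protein: the residues that superpose
onto the pocket positions) and a pocket-detection score. The pocket chosen
as the putative active site is the highest-scoring one among those with at
least `min_conserved` positions conserved in at least `min_fraction` of the
family, reflecting that functional sites are conserved (enzymes average
about 3.5 catalytic residues, motivating the default minimum of 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from ._tables import AMINO_ACIDS, GAP


class PocketError(ValueError):
    pass


@dataclass
class ActiveSiteAlignment:
    """Fixed-width gapped active-site rows, one per protein."""

    rows: dict[str, str]
    position_labels: dict[int, int] | None = None  # position -> structure residue no.

    def __post_init__(self) -> None:
        if not self.rows:
            raise PocketError("active-site alignment has no rows")
        widths = {len(r) for r in self.rows.values()}
        if len(widths) != 1:
            raise PocketError(f"rows of differing widths: {sorted(widths)}")
        alphabet = set(AMINO_ACIDS) | {GAP}
        for pid, row in self.rows.items():
            bad = set(row) - alphabet
            if bad:
                raise PocketError(f"row {pid!r} has invalid symbols {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def column(self, position: int) -> list[str]:
        if not 0 <= position < self.width:
            raise PocketError(f"position {position} out of range 0..{self.width - 1}")
        return [row[position] for row in self.rows.values()]


@dataclass
class PocketSet:
    """Candidate pockets: id -> (alignment, pocket score)."""

    pockets: dict[str, tuple[ActiveSiteAlignment, float]]

    def __post_init__(self) -> None:
        if not self.pockets:
            raise PocketError("empty pocket set")
        id_sets = {frozenset(msa.ids) for msa, _ in self.pockets.values()}
        if len(id_sets) != 1:
            raise PocketError("pockets cover different protein sets")


def position_conservation(msa: ActiveSiteAlignment, position: int,
                          count_gaps_in_denominator: bool = True
                          ) -> tuple[str | None, float]:
    """Modal non-gap residue at a position and its conservation fraction.

    By default the denominator is all rows (a residue must be present AND
    identical in the required fraction of the family); an all-gap column
    yields (None, 0.0).
    """
    col = msa.column(position)
    residues = [c for c in col if c != GAP]
    if not residues:
        return None, 0.0
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    best = min(sorted(counts), key=lambda r: -counts[r])
    denom = len(col) if count_gaps_in_denominator else len(residues)
    return best, counts[best] / denom


def conserved_position_count(msa: ActiveSiteAlignment, min_fraction: float = 0.5,
                             count_gaps_in_denominator: bool = True) -> int:
    return sum(
        position_conservation(msa, p, count_gaps_in_denominator)[1] >= min_fraction
        for p in range(msa.width))


def select_putative_active_site(pockets: PocketSet, min_conserved: int = 3,
                                min_fraction: float = 0.5,
                                count_gaps_in_denominator: bool = True) -> str:
    """Highest-scoring pocket among those passing the conservation rule.

    Ties on score break lexicographically by pocket id for reproducibility.
    """
    qualifying: list[tuple[float, str]] = []
    counts: dict[str, int] = {}
    for pocket_id, (msa, score) in pockets.pockets.items():
        counts[pocket_id] = conserved_position_count(
            msa, min_fraction, count_gaps_in_denominator)
        if counts[pocket_id] >= min_conserved:
            qualifying.append((score, pocket_id))
    if not qualifying:
        detail = ", ".join(f"{pid}={c}" for pid, c in sorted(counts.items()))
        raise PocketError(
            f"no qualifying pocket (need >= {min_conserved} positions conserved "
            f"at >= {min_fraction:.0%}); conserved counts: {detail}")
    qualifying.sort(key=lambda t: (-t[0], t[1]))
    return qualifying[0][1]


# ---------------------------------------------------------------------------
# I/O: aligned FASTA per pocket + TSV of scores

def read_active_site_fasta(path: str | Path) -> ActiveSiteAlignment:
    from Bio import SeqIO

    rows = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    return ActiveSiteAlignment(rows=rows)


def write_active_site_fasta(msa: ActiveSiteAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, row in msa.rows.items():
            fh.write(f">{pid}\n{row}\n")


def read_pocket_dir(directory: str | Path, scores_tsv: str | Path | None = None
                    ) -> PocketSet:
    """Read a directory of aligned FASTA pockets plus a (pocket_id, score) TSV."""
    import pandas as pd

    directory = Path(directory)
    scores_tsv = Path(scores_tsv) if scores_tsv else directory / "scores.tsv"
    scores = pd.read_csv(scores_tsv, sep="\t", dtype={"pocket_id": str})
    score_map = dict(zip(scores["pocket_id"], scores["score"].astype(float)))
    pockets = {}
    for pocket_id, score in score_map.items():
        fasta = directory / f"{pocket_id}.fasta"
        if not fasta.exists():
            raise PocketError(f"missing pocket alignment {fasta}")
        pockets[pocket_id] = (read_active_site_fasta(fasta), score)
    return PocketSet(pockets=pockets)


__all__ = [
    "PocketError", "ActiveSiteAlignment", "PocketSet",
    "position_conservation", "conserved_position_count",
    "select_putative_active_site",
    "read_active_site_fasta", "write_active_site_fasta", "read_pocket_dir",
]
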
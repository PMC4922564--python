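"""Reference constants: evidence-matrix vocabulary and amino-acid tables.

BLOSUM62, Kyte-Doolittle hydropathy and average residue masses come from
Biopython; the Dayhoff reference composition and the amino-acid class sets
(EMBOSS pepstats convention) are packaged here as documented constants.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical evidence-matrix vocabulary, with the natural orientation of the
#: raw data: distance-like sources (differences, distances) must be
#: interval-reversed on normalization so larger always means more similar.
EVIDENCE_ORIENTATION: dict[str, str] = {
    "seqAliG": "similarity",       # global sequence alignment score
    "seqAliL": "similarity",       # local sequence alignment score
    "strAliSize": "similarity",    # structural alignment size
    "strAliId": "similarity",      # structural alignment identity %
    "strAliScr": "similarity",     # structural alignment TM-score
    "csmDist": "distance",         # structural-signature array distance
    "neighborhood": "similarity",  # conserved gene neighborhood score
    "fusion": "similarity",        # gene fusion score
    "cooccurrence": "similarity",  # co-occurrence score
    "coexpression": "similarity",  # co-expression score
    "difMolWeight": "distance",
    "difIsoPoint": "distance",
    "difAliphRes": "distance",
    "difAromRes": "distance",
    "difPolarRes": "distance",
    "difChargedRes": "distance",
    "difBasicRes": "distance",
    "difAcidicRes": "distance",
    "aaCompDist": "distance",      # composition-array squared Euclidean distance
    "difInstab": "distance",
    "difGRAVY": "distance",
    "interpro": "similarity",      # shared InterPro annotations
    "go": "similarity",            # shared GO terms
    "ASid": "similarity",          # active-site identity %
    "ASscr": "similarity",         # active-site BLOSUM62 score
}

EVIDENCE_NAMES: tuple[str, ...] = tuple(EVIDENCE_ORIENTATION)

#: Amino-acid class membership, EMBOSS pepstats convention.
AA_CLASSES: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("AILV"),
    "aromatic": frozenset("FHWY"),
    "nonpolar": frozenset("ACFGILMPVWY"),
    "polar": frozenset("DEHKNQRST"),
    "charged": frozenset("DEHKR"),
    "basic": frozenset("HKR"),
    "acidic": frozenset("DE"),
}

#: Class-percentage property-column names, mapped to evidence-matrix names.
CLASS_PROPERTY_TO_EVIDENCE: dict[str, str] = {
    "aliphatic": "difAliphRes",
    "aromatic": "difAromRes",
    "polar": "difPolarRes",
    "charged": "difChargedRes",
    "basic": "difBasicRes",
    "acidic": "difAcidicRes",
}

#: Dayhoff reference amino-acid composition (percent), the normalizer used by
#: pepstats' "DayhoffStat" (observed mole% divided by this reference).
DAYHOFF_FREQ_PERCENT: dict[str, float] = {
    "A": 8.6, "C": 2.9, "D": 5.5, "E": 6.0, "F": 3.6,
    "G": 8.4, "H": 2.0, "I": 4.5, "K": 6.6, "L": 7.4,
    "M": 1.7, "N": 4.3, "P": 5.2, "Q": 3.9, "R": 4.9,
    "S": 7.0, "T": 6.1, "V": 6.6, "W": 1.3, "Y": 3.4,
}

GAP = "-"
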
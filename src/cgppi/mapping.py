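"""MARTINI residue -> bead mapping tables and bead-type vocabularies.

Two force-field versions are supported: the classical MARTINI 2.2 protein
model and MARTINI 3.  They differ in how many side-chain beads a residue
receives (e.g. alanine carries no side-chain bead in 2.2 but one in 3;
tryptophan carries four vs. five) and in the bead-type vocabulary used for
non-bonded typing.

The vocabularies below are the fixed ordered token lists used for one-hot
encoding throughout the package: 17 tokens for MARTINI 2.2 and 23 for
MARTINI 3, which together with the 8 sine/cosine angular components yield
node feature vectors of length 25 and 31 respectively.
"""

from __future__ import annotations

from enum import Enum


class MartiniVersion(str, Enum):
    """Supported MARTINI force-field flavours."""

    MARTINI22 = "martini22"
    MARTINI3 = "martini3"


STANDARD_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Per-residue side-chain bead types, in S1..Sk order.  Backbone bead types
# are secondary-structure dependent and listed separately below.
_SIDECHAIN_M22: dict[str, tuple[str, ...]] = {
    "ALA": (),
    "GLY": (),
    "VAL": ("C2",),
    "LEU": ("C1",),
    "ILE": ("C1",),
    "PRO": ("C3",),
    "MET": ("C5",),
    "CYS": ("C5",),
    "SER": ("P1",),
    "THR": ("P1",),
    "ASN": ("P5",),
    "GLN": ("P4",),
    "ASP": ("Qa",),
    "GLU": ("Qa",),
    "ARG": ("N0", "Qd"),
    "LYS": ("C3", "Qd"),
    "HIS": ("SC4", "SP1", "SP1"),
    "PHE": ("SC5", "SC5", "SC5"),
    "TYR": ("SC4", "SC4", "SP1"),
    "TRP": ("SC4", "SP1", "SC5", "SC5"),
}

_SIDECHAIN_M3: dict[str, tuple[str, ...]] = {
    "GLY": (),
    "ALA": ("TC3",),
    "VAL": ("SC3",),
    "LEU": ("SC2",),
    "ILE": ("SC2",),
    "PRO": ("SC3",),
    "MET": ("C6",),
    "CYS": ("TC6",),
    "SER": ("TP1",),
    "THR": ("SP1",),
    "ASN": ("SP5",),
    "GLN": ("P5",),
    "ASP": ("SQ5n",),
    "GLU": ("Q5n",),
    "LYS": ("SC3", "SQ4p"),
    "ARG": ("SC3", "SQ3p"),
    "HIS": ("TC4", "TN6d", "TN5a"),
    "PHE": ("SC4", "TC5", "TC5"),
    "TYR": ("TC4", "TC5", "TC5", "TN6"),
    "TRP": ("TC4", "TN6d", "TC5", "TC5", "TC5"),
}

# Backbone bead type by secondary-structure code (H helix, E strand,
# C coil/turn/bend).  In MARTINI 2.2 the backbone type tracks the secondary
# structure; in MARTINI 3 the backbone type is residue-dependent only.
_BACKBONE_M22: dict[str, str] = {"H": "N0", "E": "Nda", "C": "P5"}
_BACKBONE_M3_DEFAULT = "P2"
_BACKBONE_M3_SPECIAL: dict[str, str] = {"GLY": "SP1", "ALA": "SP2", "PRO": "SP2a"}

# Fixed ordered one-hot vocabularies.  17 tokens (MARTINI22) and 23 tokens
# (MARTINI3); vocabulary size + 8 angular components = node feature length.
_VOCAB_M22: tuple[str, ...] = (
    "P5", "P4", "P3", "P1",
    "Nda", "Nd", "Na", "N0",
    "C5", "C3", "C2", "C1",
    "Qa", "Qd",
    "SC4", "SC5", "SP1",
)

_VOCAB_M3: tuple[str, ...] = (
    "P2", "P5", "P6",
    "SP1", "SP2", "SP2a", "SP5",
    "TP1",
    "C6", "SC2", "SC3", "SC4",
    "TC3", "TC4", "TC5", "TC6",
    "TN5a", "TN6", "TN6d",
    "Q5n", "SQ3p", "SQ4p", "SQ5n",
)


def _version(version: MartiniVersion | str) -> MartiniVersion:
    return MartiniVersion(version)


def sidechain_bead_types(residue_name: str, version: MartiniVersion | str) -> tuple[str, ...]:
    """Bead types of a residue's side-chain beads, in S1..Sk order."""
    table = _SIDECHAIN_M22 if _version(version) is MartiniVersion.MARTINI22 else _SIDECHAIN_M3
    try:
        return table[residue_name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown residue {residue_name!r}: convert non-natural residues to "
            "their standard counterparts upstream (e.g. with pdbfixer) before "
            "coarse-graining"
        ) from None


def sidechain_bead_count(residue_name: str, version: MartiniVersion | str) -> int:
    """Number of side-chain beads (0-5) a residue receives in this version."""
    return len(sidechain_bead_types(residue_name, version))


def backbone_bead_type(residue_name: str, ss_code: str, version: MartiniVersion | str) -> str:
    """Backbone bead type for a residue given its secondary structure."""
    if ss_code not in ("H", "E", "C"):
        raise ValueError(f"secondary-structure code must be H, E or C, got {ss_code!r}")
    if _version(version) is MartiniVersion.MARTINI22:
        return _BACKBONE_M22[ss_code]
    return _BACKBONE_M3_SPECIAL.get(residue_name.upper(), _BACKBONE_M3_DEFAULT)


def bead_type_vocabulary(version: MartiniVersion | str) -> tuple[str, ...]:
    """Fixed ordered bead-type vocabulary for one-hot encoding.

    Sizes are 17 (MARTINI22) and 23 (MARTINI3), making the concatenated node
    feature come out at 25 and 31 components respectively.
    """
    if _version(version) is MartiniVersion.MARTINI22:
        return _VOCAB_M22
    return _VOCAB_M3


def bead_type_index(version: MartiniVersion | str) -> dict[str, int]:
    """Token -> position lookup for the version's vocabulary."""
    return {tok: i for i, tok in enumerate(bead_type_vocabulary(version))}
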
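"""Reading, writing and generating MARTINI coarse-grained protein topologies.

A coarse-grained (CG) protein complex is represented by:

* :class:`CGBead` -- one MARTINI interaction site with a 3D coordinate,
  residue membership and a bead type token;
* :class:`BondedTerm` -- a bond, angle or dihedral over an ordered bead
  tuple, carrying the category labels used for edge typing downstream;
* :class:`CGTopology` -- the beads, bonded terms, per-residue secondary
  structure (H/E/C) and MARTINI version of one complex.

Structures are read from and written to the CG-PDB dialect produced by the
martinize tools (one ATOM record per bead, atom names ``BB``/``SC1``..),
topologies from the ITP dialect of martinize v2.4 / martinize2.  A
simplified built-in mapper (:func:`simple_martinize`) coarse-grains an
atomistic structure directly so that tests and examples need no external
run; it places beads at unweighted heavy-atom centroids and is an
approximation of martinize, not a bit-exact replacement.

All lengths are Angstrom throughout the package; ITP files store nm and are
converted at parse time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .mapping import (
    MartiniVersion,
    backbone_bead_type,
    bead_type_vocabulary,
    sidechain_bead_count,
    sidechain_bead_types,
)

logger = logging.getLogger(__name__)

NM_TO_ANGSTROM = 10.0

BOND_CATEGORIES = ("d_BB_CTS", "d_BB_H", "d_BB3_E", "d_BB4_E", "d_S")
ANGLE_CATEGORIES = ("theta_BBB", "theta_BBS", "theta_BSS")
DIHEDRAL_CATEGORIES = ("psi_BBBB",)

_ROLE_ORDER = {f"S{k}": k for k in range(1, 6)}
_ROLE_ORDER["B"] = 0


class CGParseError(ValueError):
    """Malformed structure or topology file."""


class CGValidationError(ValueError):
    """Chemically inconsistent CG content (e.g. duplicate backbone bead)."""


@dataclass(frozen=True)
class CGBead:
    """A single MARTINI bead.

    ``bead_index`` is the position in the whole-complex bead sequence,
    ``residue_index`` is the per-chain sequential residue number and
    ``bead_role`` is ``"B"`` for the backbone bead or ``"S1"``..``"S5"``
    for side-chain beads.
    """

    bead_index: int
    chain_id: str
    residue_index: int
    residue_name: str
    bead_role: str
    bead_type: str
    coord: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.bead_role not in _ROLE_ORDER:
            raise CGValidationError(f"invalid bead role {self.bead_role!r}")
        if not np.all(np.isfinite(self.coord)):
            raise CGValidationError(
                f"non-finite coordinate for bead {self.bead_index} "
                f"({self.chain_id}/{self.residue_index} {self.bead_role})"
            )


@dataclass(frozen=True)
class BondedTerm:
    """A bond, angle or dihedral over an ordered tuple of bead indices."""

    kind: str  # "bond" | "angle" | "dihedral"
    category: str
    member_beads: tuple[int, ...]
    ref_value: float  # length (A) or angle (degrees) as listed in the topology

    _EXPECTED = {"bond": 2, "angle": 3, "dihedral": 4}
    _CATEGORIES = {
        "bond": BOND_CATEGORIES,
        "angle": ANGLE_CATEGORIES,
        "dihedral": DIHEDRAL_CATEGORIES,
    }

    def __post_init__(self) -> None:
        if self.kind not in self._EXPECTED:
            raise CGValidationError(f"invalid bonded-term kind {self.kind!r}")
        if len(self.member_beads) != self._EXPECTED[self.kind]:
            raise CGValidationError(
                f"{self.kind} needs {self._EXPECTED[self.kind]} members, "
                f"got {len(self.member_beads)}"
            )
        if self.category not in self._CATEGORIES[self.kind]:
            raise CGValidationError(
                f"invalid {self.kind} category {self.category!r}"
            )


@dataclass
class CGTopology:
    """Beads + bonded terms + secondary structure of one CG complex."""

    beads: list[CGBead]
    bonded_terms: list[BondedTerm]
    ss_codes: str  # one H/E/C code per residue, residue order of `beads`
    version: MartiniVersion

    def __post_init__(self) -> None:
        self.version = MartiniVersion(self.version)
        validate_topology(self)

    # -- residue bookkeeping ------------------------------------------------

    def residues(self) -> list[tuple[str, int]]:
        """(chain_id, residue_index) pairs in bead order, one per residue."""
        seen: dict[tuple[str, int], None] = {}
        for b in self.beads:
            seen.setdefault((b.chain_id, b.residue_index), None)
        return list(seen)

    def residue_ss(self) -> dict[tuple[str, int], str]:
        return dict(zip(self.residues(), self.ss_codes))

    def coords(self) -> np.ndarray:
        return np.asarray([b.coord for b in self.beads], dtype=np.float64)

    def bonds(self) -> list[BondedTerm]:
        return [t for t in self.bonded_terms if t.kind == "bond"]

    def angles(self) -> list[BondedTerm]:
        return [t for t in self.bonded_terms if t.kind == "angle"]

    def dihedrals(self) -> list[BondedTerm]:
        return [t for t in self.bonded_terms if t.kind == "dihedral"]

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version.value,
                "ss_codes": self.ss_codes,
                "beads": [
                    {
                        "bead_index": b.bead_index,
                        "chain_id": b.chain_id,
                        "residue_index": b.residue_index,
                        "residue_name": b.residue_name,
                        "bead_role": b.bead_role,
                        "bead_type": b.bead_type,
                        "coord": list(b.coord),
                    }
                    for b in self.beads
                ],
                "bonded_terms": [
                    {
                        "kind": t.kind,
                        "category": t.category,
                        "member_beads": list(t.member_beads),
                        "ref_value": t.ref_value,
                    }
                    for t in self.bonded_terms
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CGTopology":
        d = json.loads(text)
        beads = [
            CGBead(
                bead_index=b["bead_index"],
                chain_id=b["chain_id"],
                residue_index=b["residue_index"],
                residue_name=b["residue_name"],
                bead_role=b["bead_role"],
                bead_type=b["bead_type"],
                coord=tuple(b["coord"]),
            )
            for b in d["beads"]
        ]
        terms = [
            BondedTerm(
                kind=t["kind"],
                category=t["category"],
                member_beads=tuple(t["member_beads"]),
                ref_value=t["ref_value"],
            )
            for t in d["bonded_terms"]
        ]
        return cls(beads=beads, bonded_terms=terms,
                   ss_codes=d["ss_codes"], version=d["version"])


def validate_topology(topo: CGTopology) -> None:
    """Check structural invariants; raise :class:`CGValidationError`."""
    n = len(topo.beads)
    if n == 0:
        raise CGValidationError("topology contains no beads")
    per_residue: dict[tuple[str, int], list[CGBead]] = {}
    for b in topo.beads:
        per_residue.setdefault((b.chain_id, b.residue_index), []).append(b)
    for key, beads in per_residue.items():
        n_backbone = sum(1 for b in beads if b.bead_role == "B")
        if n_backbone != 1:
            raise CGValidationError(
                f"residue {key} has {n_backbone} backbone beads (need exactly 1)"
            )
        expected = sidechain_bead_count(beads[0].residue_name, topo.version)
        n_side = len(beads) - 1
        if n_side != expected:
            raise CGValidationError(
                f"residue {key} ({beads[0].residue_name}) has {n_side} "
                f"side-chain beads, expected {expected} for "
                f"{topo.version.value}"
            )
    if len(topo.ss_codes) != len(per_residue):
        raise CGValidationError(
            f"ss_codes length {len(topo.ss_codes)} != residue count "
            f"{len(per_residue)}"
        )
    if any(c not in "HEC" for c in topo.ss_codes):
        raise CGValidationError("ss_codes must use the H/E/C alphabet")
    for t in topo.bonded_terms:
        for m in t.member_beads:
            if not (0 <= m < n):
                raise CGValidationError(
                    f"{t.kind} {t.category} references unknown bead {m}"
                )


# ---------------------------------------------------------------------------
# bond / angle categorisation
# ---------------------------------------------------------------------------

def categorize_bond(b1: CGBead, b2: CGBead, residue_ss: dict[tuple[str, int], str]) -> str:
    """Assign a MARTINI bond category from member roles, offsets and SS.

    * any side-chain endpoint -> ``d_S``
    * adjacent backbone beads, both residues helical -> ``d_BB_H``
      (the MARTINI constraint bond), otherwise ``d_BB_CTS``
    * backbone beads at residue offset 3 / 4 (extended strands) ->
      ``d_BB3_E`` / ``d_BB4_E``
    """
    if b1.bead_role != "B" or b2.bead_role != "B":
        return "d_S"
    if b1.chain_id != b2.chain_id:
        raise CGValidationError(
            f"backbone bond across chains {b1.chain_id}/{b2.chain_id}"
        )
    offset = abs(b1.residue_index - b2.residue_index)
    ss1 = residue_ss[(b1.chain_id, b1.residue_index)]
    ss2 = residue_ss[(b2.chain_id, b2.residue_index)]
    if offset == 1:
        return "d_BB_H" if (ss1 == "H" and ss2 == "H") else "d_BB_CTS"
    if offset == 3:
        if not (ss1 == "E" and ss2 == "E"):
            logger.warning("i,i+3 backbone bond outside an E segment")
        return "d_BB3_E"
    if offset == 4:
        if not (ss1 == "E" and ss2 == "E"):
            logger.warning("i,i+4 backbone bond outside an E segment")
        return "d_BB4_E"
    raise CGValidationError(
        f"unsupported backbone bond residue offset {offset}"
    )


def categorize_angle(members: tuple[CGBead, CGBead, CGBead]) -> str:
    roles = tuple(b.bead_role for b in members)
    n_backbone = sum(1 for r in roles if r == "B")
    if n_backbone == 3:
        return "theta_BBB"
    if n_backbone == 2:
        return "theta_BBS"
    if n_backbone == 1:
        return "theta_BSS"
    raise CGValidationError(f"angle over roles {roles} is not a MARTINI protein angle")


# ---------------------------------------------------------------------------
# CG-PDB structure IO
# ---------------------------------------------------------------------------

def _role_from_atom_name(name: str) -> str:
    name = name.strip()
    if name == "BB":
        return "B"
    if name.startswith("SC") and name[2:].isdigit():
        return f"S{int(name[2:])}"
    raise CGParseError(f"unrecognised CG bead atom name {name!r}")


def _atom_name_from_role(role: str) -> str:
    return "BB" if role == "B" else f"SC{role[1:]}"


def _prevalidate_pdb_lines(path) -> None:
    """Cheap line-level scan so malformed records report a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise CGParseError(f"{path}:{lineno}: truncated ATOM record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise CGParseError(
                    f"{path}:{lineno}: unparsable coordinates in ATOM record"
                ) from None


def parse_cg_structure(path, version: MartiniVersion | str = MartiniVersion.MARTINI22) -> list[CGBead]:
    """Read a CG-PDB file (one ATOM record per bead) into ordered beads.

    Beads are ordered by (chain appearance order, residue_index, role with B
    before S1..Sk).  Bead types are filled from the version's mapping tables
    with a coil backbone default; the authoritative per-residue types come
    from the accompanying ITP topology when one is parsed.
    """
    version = MartiniVersion(version)
    _prevalidate_pdb_lines(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises various subclasses
        raise CGParseError(f"{path}: cannot parse PDB content: {exc}") from exc
    if atoms.array_length() == 0:
        raise CGValidationError(f"{path}: no ATOM records found")

    chain_order: dict[str, int] = {}
    records = []
    for i in range(atoms.array_length()):
        chain = str(atoms.chain_id[i])
        chain_order.setdefault(chain, len(chain_order))
        role = _role_from_atom_name(str(atoms.atom_name[i]))
        records.append(
            (
                chain_order[chain],
                int(atoms.res_id[i]),
                _ROLE_ORDER[role],
                chain,
                str(atoms.res_name[i]),
                role,
                tuple(float(x) for x in atoms.coord[i]),
            )
        )
    records.sort(key=lambda r: r[:3])

    seen_roles: set[tuple[str, int, str]] = set()
    beads: list[CGBead] = []
    for idx, (_, res_id, _, chain, res_name, role, coord) in enumerate(records):
        key = (chain, res_id, role)
        if key in seen_roles:
            raise CGValidationError(
                f"{path}: duplicate {role} bead in residue {chain}/{res_id}"
            )
        seen_roles.add(key)
        if role == "B":
            btype = backbone_bead_type(res_name, "C", version)
        else:
            side = sidechain_bead_types(res_name, version)
            k = int(role[1:])
            if k > len(side):
                raise CGValidationError(
                    f"{path}: residue {chain}/{res_id} ({res_name}) has no "
                    f"bead {role} in {version.value}"
                )
            btype = side[k - 1]
        beads.append(
            CGBead(
                bead_index=idx,
                chain_id=chain,
                residue_index=res_id,
                residue_name=res_name,
                bead_role=role,
                bead_type=btype,
                coord=coord,
            )
        )
    return beads


def write_cg_structure(beads: list[CGBead], path) -> None:
    """Write beads to a CG-PDB file (3-decimal coordinate precision)."""
    n = len(beads)
    if n == 0:
        raise CGValidationError("cannot write an empty bead list")
    arr = bst.AtomArray(n)
    arr.coord = np.asarray([b.coord for b in beads], dtype=np.float32)
    arr.chain_id = np.asarray([b.chain_id for b in beads])
    arr.res_id = np.asarray([b.residue_index for b in beads])
    arr.res_name = np.asarray([b.residue_name for b in beads])
    arr.atom_name = np.asarray([_atom_name_from_role(b.bead_role) for b in beads])
    arr.element = np.asarray(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# ITP topology parsing
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {
    "moleculetype", "atoms", "bonds", "constraints", "angles", "dihedrals",
}


def _strip_itp(line: str) -> str:
    return line.split(";", 1)[0].strip()


def parse_topology(
    path,
    ss_codes: str,
    version: MartiniVersion | str = MartiniVersion.MARTINI22,
    beads: list[CGBead] | None = None,
    chain_id: str = "A",
) -> CGTopology:
    """Parse an ITP-dialect topology (martinize v2.4 / martinize2 output).

    ``ss_codes`` supplies the per-residue H/E/C string that a martinize
    workflow obtains from its internal DSSP call (coil/turn/bend collapse
    to C).  When ``beads`` from :func:`parse_cg_structure` are given, their
    coordinates are merged positionally; otherwise beads carry zero
    coordinates and only the topology is meaningful.

    Bond lengths are converted from nm to Angstrom; bond categories are
    re-derived from member roles, residue offsets and ``ss_codes`` rather
    than trusted from the file layout.
    """
    version = MartiniVersion(version)
    section = None
    atom_rows: list[tuple[int, str, int, str, str]] = []
    bond_rows: list[tuple[int, int, float, int]] = []
    angle_rows: list[tuple[int, int, int, float, int]] = []
    dihedral_rows: list[tuple[int, int, int, int, float, int]] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = _strip_itp(raw)
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip().lower()
                if section not in _KNOWN_SECTIONS:
                    logger.warning("%s:%d: skipping unrecognised section [%s]",
                                   path, lineno, section)
                    section = "_skip"
                continue
            fields = line.split()
            try:
                if section == "atoms":
                    # id type resnr resname atomname cgnr [charge]
                    atom_rows.append(
                        (int(fields[0]), fields[1], int(fields[2]),
                         fields[3], fields[4])
                    )
                elif section == "bonds":
                    bond_rows.append(
                        (int(fields[0]), int(fields[1]), float(fields[3]), lineno)
                    )
                elif section == "constraints":
                    bond_rows.append(
                        (int(fields[0]), int(fields[1]), float(fields[3]), lineno)
                    )
                elif section == "angles":
                    angle_rows.append(
                        (int(fields[0]), int(fields[1]), int(fields[2]),
                         float(fields[4]), lineno)
                    )
                elif section == "dihedrals":
                    dihedral_rows.append(
                        (int(fields[0]), int(fields[1]), int(fields[2]),
                         int(fields[3]), float(fields[5]), lineno)
                    )
            except (IndexError, ValueError):
                raise CGParseError(
                    f"{path}:{lineno}: malformed [{section}] record: {raw.rstrip()}"
                ) from None

    if not atom_rows:
        raise CGParseError(f"{path}: no [atoms] section found")

    if beads is None:
        built: list[CGBead] = []
        for idx, (_, btype, resnr, resname, atomname) in enumerate(atom_rows):
            built.append(
                CGBead(
                    bead_index=idx,
                    chain_id=chain_id,
                    residue_index=resnr,
                    residue_name=resname,
                    bead_role=_role_from_atom_name(atomname),
                    bead_type=btype,
                    coord=(0.0, 0.0, 0.0),
                )
            )
        beads = built
    else:
        if len(beads) != len(atom_rows):
            raise CGValidationError(
                f"{path}: topology lists {len(atom_rows)} beads but structure "
                f"has {len(beads)}"
            )
        beads = [
            replace(b, bead_type=row[1], bead_index=i)
            for i, (b, row) in enumerate(zip(beads, atom_rows))
        ]

    n = len(beads)

    def _check(idx1: int, lineno: int) -> int:
        if not (1 <= idx1 <= n):
            raise CGValidationError(
                f"{path}:{lineno}: bonded term references unknown bead {idx1}"
            )
        return idx1 - 1

    residue_ss = dict(zip(
        list(dict.fromkeys((b.chain_id, b.residue_index) for b in beads)),
        ss_codes,
    ))

    terms: list[BondedTerm] = []
    for i1, j1, length_nm, lineno in bond_rows:
        i, j = _check(i1, lineno), _check(j1, lineno)
        terms.append(
            BondedTerm(
                kind="bond",
                category=categorize_bond(beads[i], beads[j], residue_ss),
                member_beads=(i, j),
                ref_value=length_nm * NM_TO_ANGSTROM,
            )
        )
    for i1, j1, k1, angle_deg, lineno in angle_rows:
        members = tuple(_check(x, lineno) for x in (i1, j1, k1))
        terms.append(
            BondedTerm(
                kind="angle",
                category=categorize_angle(tuple(beads[m] for m in members)),
                member_beads=members,
                ref_value=angle_deg,
            )
        )
    for i1, j1, k1, l1, angle_deg, lineno in dihedral_rows:
        members = tuple(_check(x, lineno) for x in (i1, j1, k1, l1))
        roles = [beads[m].bead_role for m in members]
        if any(r != "B" for r in roles):
            raise CGValidationError(
                f"{path}:{lineno}: dihedral over non-backbone beads"
            )
        terms.append(
            BondedTerm(kind="dihedral", category="psi_BBBB",
                       member_beads=members, ref_value=angle_deg)
        )

    return CGTopology(beads=beads, bonded_terms=terms,
                      ss_codes=ss_codes, version=version)


# ---------------------------------------------------------------------------
# bonded-term generation (shared by the built-in mapper and synthetic data)
# ---------------------------------------------------------------------------

def generate_bonded_terms(beads: list[CGBead], ss_codes: str) -> list[BondedTerm]:
    """Generate MARTINI-style bonded terms for a bead list.

    Backbone bonds join consecutive residues of a chain (constraint d_BB_H
    inside helices); i,i+3 and i,i+4 long harmonic bonds are added whenever
    all residues of the span are extended (E); side-chain beads are bonded
    as a linear chain B-S1-S2-...; angles cover consecutive backbone triples
    (theta_BBB), the backbone/side-chain junction (theta_BBS over
    B_{i+1}, B_i, S_{i,1}) and the first two side-chain beads (theta_BSS);
    one backbone dihedral psi_BBBB is imposed per all-helical quadruple.
    Reference values are computed from the actual coordinates.
    """
    residues = list(dict.fromkeys((b.chain_id, b.residue_index) for b in beads))
    residue_ss = dict(zip(residues, ss_codes))
    by_residue: dict[tuple[str, int], dict[str, CGBead]] = {}
    for b in beads:
        by_residue.setdefault((b.chain_id, b.residue_index), {})[b.bead_role] = b

    chains: dict[str, list[tuple[str, int]]] = {}
    for key in residues:
        chains.setdefault(key[0], []).append(key)

    coords = np.asarray([b.coord for b in beads])

    def _dist(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[i] - coords[j]))

    def _angle(i: int, j: int, k: int) -> float:
        from .geometry import interior_angle
        return interior_angle(coords[i], coords[j], coords[k])

    def _dihedral(i: int, j: int, k: int, l: int) -> float:
        from .geometry import torsion_angle
        return torsion_angle(coords[i], coords[j], coords[k], coords[l])

    terms: list[BondedTerm] = []
    for chain, keys in chains.items():
        bb = [by_residue[k]["B"].bead_index for k in keys]
        ss = [residue_ss[k] for k in keys]
        for a in range(len(keys) - 1):
            cat = "d_BB_H" if ss[a] == "H" and ss[a + 1] == "H" else "d_BB_CTS"
            terms.append(BondedTerm("bond", cat, (bb[a], bb[a + 1]),
                                    _dist(bb[a], bb[a + 1])))
        for span, cat in ((3, "d_BB3_E"), (4, "d_BB4_E")):
            for a in range(len(keys) - span):
                if all(c == "E" for c in ss[a:a + span + 1]):
                    terms.append(BondedTerm("bond", cat, (bb[a], bb[a + span]),
                                            _dist(bb[a], bb[a + span])))
        for a in range(len(keys) - 2):
            members = (bb[a], bb[a + 1], bb[a + 2])
            terms.append(BondedTerm("angle", "theta_BBB", members,
                                    _angle(*members)))
        for a in range(len(keys) - 3):
            if all(c == "H" for c in ss[a:a + 4]):
                members = (bb[a], bb[a + 1], bb[a + 2], bb[a + 3])
                terms.append(BondedTerm("dihedral", "psi_BBBB", members,
                                        _dihedral(*members)))
        for a, key in enumerate(keys):
            side = [by_residue[key][f"S{k}"].bead_index
                    for k in range(1, 6) if f"S{k}" in by_residue[key]]
            prev = by_residue[key]["B"].bead_index
            for s in side:
                terms.append(BondedTerm("bond", "d_S", (prev, s), _dist(prev, s)))
                prev = s
            if side and a + 1 < len(keys):
                members = (bb[a + 1], bb[a], side[0])
                terms.append(BondedTerm("angle", "theta_BBS", members,
                                        _angle(*members)))
            if len(side) >= 2:
                members = (bb[a], side[0], side[1])
                terms.append(BondedTerm("angle", "theta_BSS", members,
                                        _angle(*members)))
    return terms


def simple_martinize(
    atoms: bst.AtomArray,
    ss_codes: str,
    version: MartiniVersion | str = MartiniVersion.MARTINI22,
) -> CGTopology:
    """Coarse-grain an atomistic structure with the built-in mapper.

    The backbone bead sits at the unweighted centroid of N/CA/C/O; side-chain
    heavy atoms are split, in file order, into as many contiguous groups as
    the version's mapping assigns side-chain beads, each bead at its group
    centroid.  Bonded terms follow :func:`generate_bonded_terms`.  This is an
    approximation of the external martinize mapping intended for fixtures
    and examples, not a bit-identical replacement.
    """
    version = MartiniVersion(version)
    heavy = atoms[atoms.element != "H"]
    chain_order: dict[str, int] = {}
    residue_atoms: dict[tuple[str, int], dict[str, list[int]]] = {}
    res_names: dict[tuple[str, int], str] = {}
    for i in range(heavy.array_length()):
        chain = str(heavy.chain_id[i])
        chain_order.setdefault(chain, len(chain_order))
        key = (chain, int(heavy.res_id[i]))
        group = "bb" if str(heavy.atom_name[i]) in ("N", "CA", "C", "O", "OXT") else "sc"
        residue_atoms.setdefault(key, {"bb": [], "sc": []})[group].append(i)
        res_names[key] = str(heavy.res_name[i])

    ordered = sorted(residue_atoms, key=lambda k: (chain_order[k[0]], k[1]))
    if len(ss_codes) != len(ordered):
        raise CGValidationError(
            f"ss_codes length {len(ss_codes)} != residue count {len(ordered)}"
        )

    beads: list[CGBead] = []
    for key, ss in zip(ordered, ss_codes):
        chain, res_id = key
        res_name = res_names[key]
        bb_idx = residue_atoms[key]["bb"]
        if not bb_idx:
            raise CGValidationError(
                f"residue {chain}/{res_id} ({res_name}): missing backbone atoms "
                "for bead B"
            )
        beads.append(
            CGBead(
                bead_index=len(beads),
                chain_id=chain,
                residue_index=res_id,
                residue_name=res_name,
                bead_role="B",
                bead_type=backbone_bead_type(res_name, ss, version),
                coord=tuple(np.mean(heavy.coord[bb_idx], axis=0)),
            )
        )
        side_types = sidechain_bead_types(res_name, version)
        sc_idx = residue_atoms[key]["sc"]
        if side_types:
            if len(sc_idx) < len(side_types):
                raise CGValidationError(
                    f"residue {chain}/{res_id} ({res_name}): {len(sc_idx)} "
                    f"side-chain heavy atoms cannot fill {len(side_types)} beads"
                )
            groups = np.array_split(np.asarray(sc_idx), len(side_types))
            for k, (btype, grp) in enumerate(zip(side_types, groups), start=1):
                beads.append(
                    CGBead(
                        bead_index=len(beads),
                        chain_id=chain,
                        residue_index=res_id,
                        residue_name=res_name,
                        bead_role=f"S{k}",
                        bead_type=btype,
                        coord=tuple(np.mean(heavy.coord[grp], axis=0)),
                    )
                )

    terms = generate_bonded_terms(beads, ss_codes)
    return CGTopology(beads=beads, bonded_terms=terms,
                      ss_codes=ss_codes, version=version)


__all__ = [
    "CGBead", "BondedTerm", "CGTopology",
    "CGParseError", "CGValidationError",
    "MartiniVersion", "bead_type_vocabulary", "sidechain_bead_count",
    "parse_cg_structure", "write_cg_structure", "parse_topology",
    "simple_martinize", "generate_bonded_terms",
    "categorize_bond", "categorize_angle", "validate_topology",
    "BOND_CATEGORIES", "ANGLE_CATEGORIES", "DIHEDRAL_CATEGORIES",
]
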
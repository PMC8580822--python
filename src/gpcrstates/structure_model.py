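"""Structure loading and the generic-residue-number data model.

Receptor structures are reduced to an ordered table of residues carrying
heavy atoms, an optional generic position (the class-independent
``<segment>x<offset>`` label, with 50 assigned to the reference residue of
each helix), and a segment label derived from it.  The generic numbering is
the only cross-structure key used by every downstream stage; author residue
numbering is preserved as found in the file.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "GenericPosition",
    "ResidueRecord",
    "LigandGroup",
    "AnnotatedStructure",
    "load_structure",
    "apply_generic_numbers",
    "segment_span",
    "read_mapping_table",
    "write_mapping_table",
]

#: segment label for each generic segment code.  Helices 1-7 and helix 8
#: carry single-digit codes; loops are coded by the flanking helices
#: (45 = ECL2, between TM4 and TM5).  Code 78 (the TM7-H8 elbow) has no
#: named segment in the TM/loop scheme and maps to "other".
SEGMENT_BY_CODE = {
    1: "TM1", 2: "TM2", 3: "TM3", 4: "TM4", 5: "TM5", 6: "TM6", 7: "TM7",
    8: "H8",
    12: "ICL1", 23: "ECL1", 34: "ICL2", 45: "ECL2", 56: "ICL3", 67: "ECL3",
    78: "other",
}

TM_SEGMENTS = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7")

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@functools.total_ordering
@dataclass(frozen=True)
class GenericPosition:
    """Generic residue number ``<segment_code>x<offset>`` (e.g. 3x50)."""

    segment_code: int
    offset: int

    def __post_init__(self):
        if self.segment_code not in SEGMENT_BY_CODE:
            raise ValueError(f"unknown generic segment code {self.segment_code}")

    @property
    def segment(self) -> str:
        return SEGMENT_BY_CODE[self.segment_code]

    @classmethod
    def parse(cls, text: str) -> "GenericPosition":
        for sep in ("×", "x", "."):
            if sep in text:
                seg, off = text.split(sep, 1)
                return cls(int(seg), int(off))
        raise ValueError(f"cannot parse generic position {text!r}")

    def __str__(self) -> str:
        return f"{self.segment_code}x{self.offset}"

    def __lt__(self, other: "GenericPosition") -> bool:
        return (self.segment_code, self.offset) < (other.segment_code, other.offset)


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    xyz: tuple
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_ATOMS


@dataclass
class ResidueRecord:
    chain: str
    seqnum: int
    aa: str
    atoms: list
    generic: GenericPosition | None = None
    segment: str = "other"
    name3: str = ""

    def __post_init__(self):
        if self.aa not in _ONE_TO_THREE and self.aa != "X":
            raise ValueError(f"invalid amino-acid letter {self.aa!r}")
        if self.generic is not None and self.segment != self.generic.segment:
            raise ValueError(
                f"segment {self.segment} inconsistent with generic {self.generic}"
            )
        if not self.name3:
            self.name3 = _ONE_TO_THREE.get(self.aa, "UNK")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> np.ndarray | None:
        a = self.atom("CA")
        return None if a is None else a.pos

    def coords(self, sidechain_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if not sidechain_only or a.is_sidechain]
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.pos for a in atoms])


@dataclass
class LigandGroup:
    """Non-polymer hetero group (or flagged peptide chain) kept aside for
    interface mapping; never part of the receptor residue table."""

    name: str
    chain: str
    seqnum: int
    atoms: list

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.stack([a.pos for a in self.atoms])


@dataclass
class AnnotatedStructure:
    structure_id: str
    residues: list
    receptor: str = ""
    gpcr_class: str = ""
    state: str = "unknown"
    ligands: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        seen_key, seen_gen = set(), set()
        for r in self.residues:
            key = (r.chain, r.seqnum)
            if key in seen_key:
                raise ValueError(f"duplicate residue {key} in {self.structure_id}")
            seen_key.add(key)
            if r.generic is not None:
                if r.generic in seen_gen:
                    raise ValueError(
                        f"generic position {r.generic} assigned twice in "
                        f"{self.structure_id}"
                    )
                seen_gen.add(r.generic)

    def by_generic(self) -> dict:
        return {r.generic: r for r in self.residues if r.generic is not None}

    def generic_positions(self) -> set:
        return {r.generic for r in self.residues if r.generic is not None}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnnotatedStructure":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)

        def move(atoms):
            return [replace(a, xyz=tuple(R @ a.pos + t)) for a in atoms]

        residues = [replace(r, atoms=move(r.atoms)) for r in self.residues]
        ligands = [replace(l, atoms=move(l.atoms)) for l in self.ligands]
        return replace(self, residues=residues, ligands=ligands,
                       metadata=dict(self.metadata))


def _resolve_altlocs(residue: gemmi.Residue) -> list:
    """One atom per name: highest occupancy, ties broken by altloc tag."""
    groups: dict = {}
    for atom in residue:
        if atom.element.is_hydrogen:
            continue
        groups.setdefault(atom.name, []).append(atom)
    out = []
    for name, atoms in groups.items():
        best = min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))
        out.append(AtomRecord(
            name=name,
            element=best.element.name,
            xyz=(best.pos.x, best.pos.y, best.pos.z),
            altloc=best.altloc or "",
            occupancy=min(max(best.occ, 0.0), 1.0),
        ))
    return out


def load_structure(path, chain: str, model: int = 0,
                   structure_id: str | None = None,
                   min_ligand_atoms: int = 6) -> AnnotatedStructure:
    """Read one receptor chain from an mmCIF or PDB file.

    Hydrogens are dropped, alternate locations resolved by occupancy (ties
    by tag), waters discarded, and non-polymer hetero groups with more than
    ``min_ligand_atoms`` heavy atoms kept in a side table for interface
    mapping.  Generic numbers are attached separately with
    :func:`apply_generic_numbers`.
    """
    path = str(path)
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if model >= len(st):
        raise IndexError(f"model {model} not present in {path} "
                         f"({len(st)} model(s))")
    mdl = st[model]
    names = [ch.name for ch in mdl]
    if chain not in names:
        raise KeyError(f"chain {chain!r} not found in {path}; "
                       f"available chains: {sorted(set(names))}")

    residues, ligands = [], []
    for ch in mdl:
        for res in ch:
            if res.is_water():
                continue
            atoms = _resolve_altlocs(res)
            if not atoms:
                continue
            one = _THREE_TO_ONE.get(res.name)
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = one is not None or (
                info is not None and info.found() and info.is_amino_acid())
            if ch.name == chain and is_aa:
                residues.append(ResidueRecord(
                    chain=ch.name, seqnum=res.seqid.num,
                    aa=one or "X", atoms=atoms, name3=res.name))
            elif not is_aa and len(atoms) >= min_ligand_atoms:
                ligands.append(LigandGroup(
                    name=res.name, chain=ch.name,
                    seqnum=res.seqid.num, atoms=atoms))
    return AnnotatedStructure(
        structure_id=structure_id or st.name or path,
        residues=residues, ligands=ligands)


def apply_generic_numbers(s: AnnotatedStructure, mapping: dict):
    """Attach generic positions from a ``(chain, seqnum) -> GenericPosition``
    mapping; segment labels follow from the generic code.  Returns the
    annotated structure and the number of residues mapped."""
    targets: dict = {}
    for key, pos in mapping.items():
        if isinstance(pos, str):
            pos = GenericPosition.parse(pos)
        if pos in targets:
            raise ValueError(
                f"generic position {pos} mapped from both {targets[pos]} "
                f"and {key}")
        targets[pos] = key
    by_target = {key: pos for pos, key in targets.items()}

    new_residues, n_mapped = [], 0
    for r in s.residues:
        pos = by_target.get((r.chain, r.seqnum))
        if pos is not None:
            new_residues.append(replace(r, generic=pos, segment=pos.segment))
            n_mapped += 1
        else:
            new_residues.append(replace(r, generic=None, segment="other"))
    out = replace(s, residues=new_residues)
    return out, n_mapped


def segment_span(s: AnnotatedStructure, segment: str) -> list:
    """Residues of one segment, ordered by generic offset."""
    span = [r for r in s.residues
            if r.segment == segment and r.generic is not None]
    return sorted(span, key=lambda r: r.generic.offset)


def read_mapping_table(path) -> dict:
    """Read a generic-number mapping TSV with columns
    structure_id, chain, seqnum, generic.  Returns
    ``{structure_id: {(chain, seqnum): GenericPosition}}``."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"structure_id": str, "chain": str})
    required = {"structure_id", "chain", "seqnum", "generic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mapping table missing column(s): {sorted(missing)}")
    out: dict = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.structure_id, {})[(row.chain, int(row.seqnum))] = \
            GenericPosition.parse(str(row.generic))
    return out


def write_mapping_table(path, structure_id: str, mapping: dict) -> None:
    rows = [{"structure_id": structure_id, "chain": c, "seqnum": n,
             "generic": str(p)} for (c, n), p in sorted(mapping.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def one_to_three(aa: str) -> str:
    return _ONE_TO_THREE.get(aa, "UNK")


def three_to_one(name: str) -> str:
    return _THREE_TO_ONE.get(name, "X")
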
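"""Typed residue-residue contact detection keyed by generic positions.

A residue pair is a contact when any of five geometric criteria holds
between their heavy atoms: van der Waals overlap (summed radii plus a
tolerance), carbon-carbon hydrophobic proximity, donor-acceptor hydrogen
bonding, charged-group ionic pairing, or aromatic ring-centroid proximity.
Each contact records every satisfied type.  The indexed detector
(:func:`detect_contacts`, cell-listed via a k-d tree) and the exhaustive
all-pairs scanner (:func:`detect_contacts_bruteforce`) implement the same
contract; the brute-force version is the correctness oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure_model import AnnotatedStructure, GenericPosition

__all__ = [
    "ContactParams",
    "Contact",
    "ContactSet",
    "detect_contacts",
    "detect_contacts_bruteforce",
    "write_contact_table",
    "read_contact_table",
]

#: heavy-atom van der Waals radii (Angstrom)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98}
DEFAULT_RADIUS = 1.70

# hydrogen-bond capable heavy atoms, by residue one-letter code; "*"
# applies to every residue (backbone).  Hydroxyls and His ring nitrogens
# act as both donor and acceptor.
HBOND_DONORS = {
    "*": {"N"},
    "R": {"NE", "NH1", "NH2"}, "K": {"NZ"}, "N": {"ND2"}, "Q": {"NE2"},
    "H": {"ND1", "NE2"}, "S": {"OG"}, "T": {"OG1"}, "Y": {"OH"},
    "W": {"NE1"}, "C": {"SG"},
}
HBOND_ACCEPTORS = {
    "*": {"O", "OXT"},
    "D": {"OD1", "OD2"}, "E": {"OE1", "OE2"}, "N": {"OD1"}, "Q": {"OE1"},
    "H": {"ND1", "NE2"}, "S": {"OG"}, "T": {"OG1"}, "Y": {"OH"},
    "M": {"SD"},
}
# Proline backbone nitrogen cannot donate
_PRO_EXCLUDED_DONOR = {"N"}

CATION_ATOMS = {"R": {"NE", "NH1", "NH2"}, "K": {"NZ"}}
HIS_CATION_ATOMS = {"ND1", "NE2"}
ANION_ATOMS = {"D": {"OD1", "OD2"}, "E": {"OE1", "OE2"}}

AROMATIC_RING = {
    "F": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Y": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "W": ("CG", "CD1", "NE1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "H": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass(frozen=True)
class ContactParams:
    """Distance criteria (Angstrom) for typed contacts."""

    vdw_tolerance: float = 0.6
    hbond_max: float = 3.5
    ionic_max: float = 4.5
    hydrophobic_max: float = 4.5
    aromatic_centroid_max: float = 5.5
    min_seq_separation: int = 1
    #: for |dseqnum| <= 2 require at least one side-chain atom in the
    #: atom pair, so peptide-bond neighbours only count via side chains
    adjacent_sidechain_rule: bool = True
    #: treat His ring nitrogens as cationic
    his_as_cation: bool = True

    def __post_init__(self):
        for name in ("vdw_tolerance", "hbond_max", "ionic_max",
                     "hydrophobic_max", "aromatic_centroid_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def atom_pair_cutoff(self) -> float:
        """Largest distance at which any atom-pair criterion can fire."""
        return max(self.hbond_max, self.ionic_max, self.hydrophobic_max,
                   2 * max(VDW_RADII.values()) + self.vdw_tolerance)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class Contact:
    pos_a: GenericPosition
    pos_b: GenericPosition
    types: frozenset
    min_distance: float
    atom_pair: tuple = ("", "")
    aa_a: str = "X"
    aa_b: str = "X"

    def __post_init__(self):
        if not self.pos_a < self.pos_b:
            raise ValueError("contact endpoints must be in canonical order")
        if not self.types:
            raise ValueError("contact must have at least one type")

    @property
    def pair(self):
        return (self.pos_a, self.pos_b)

    @property
    def aa_pair(self):
        return (self.aa_a, self.aa_b)


@dataclass
class ContactSet:
    structure_id: str
    contacts: list
    positions_resolved: set = field(default_factory=set)
    params: ContactParams | None = None

    def __post_init__(self):
        pairs = [c.pair for c in self.contacts]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate contact pairs")
        endpoints = {p for c in self.contacts for p in c.pair}
        if not endpoints <= self.positions_resolved:
            raise ValueError("contact endpoint missing from positions_resolved")

    def pair_dict(self) -> dict:
        return {c.pair: c for c in self.contacts}

    def __len__(self):
        return len(self.contacts)


def _donor_names(aa: str) -> set:
    names = set(HBOND_DONORS["*"]) | HBOND_DONORS.get(aa, set())
    if aa == "P":
        names -= _PRO_EXCLUDED_DONOR
    return names


def _acceptor_names(aa: str) -> set:
    return set(HBOND_ACCEPTORS["*"]) | HBOND_ACCEPTORS.get(aa, set())


def _cation_names(aa: str, params: ContactParams) -> set:
    names = set(CATION_ATOMS.get(aa, set()))
    if params.his_as_cation and aa == "H":
        names |= HIS_CATION_ATOMS
    return names


def _anion_names(aa: str) -> set:
    return set(ANION_ATOMS.get(aa, set())) | {"OXT"}


def _ring_centroid(res) -> np.ndarray | None:
    names = AROMATIC_RING.get(res.aa)
    if names is None:
        return None
    pts = [res.atom(n).pos for n in names if res.atom(n) is not None]
    if len(pts) < 3:
        return None
    return np.mean(pts, axis=0)


def _classify_pair(res_a, res_b, params: ContactParams):
    """Evaluate all atom-pair criteria between two residues.

    Returns (types, min_distance, closest atom-name pair) with types empty
    when no criterion holds.  This is the single semantic definition both
    detectors share at the residue level; the detectors differ only in how
    candidate residue pairs are found.
    """
    same_chain = res_a.chain == res_b.chain
    dnum = abs(res_a.seqnum - res_b.seqnum)
    if same_chain and dnum < params.min_seq_separation:
        return frozenset(), np.inf, ("", "")
    require_sidechain = (params.adjacent_sidechain_rule and same_chain
                         and dnum <= 2)

    atoms_a = res_a.atoms
    atoms_b = res_b.atoms
    if require_sidechain:
        # keep atom pairs with >= 1 side-chain member: drop pairs where both
        # are backbone, i.e. evaluate on the full matrix but mask later
        pass
    if not atoms_a or not atoms_b:
        return frozenset(), np.inf, ("", "")

    xa = np.stack([a.pos for a in atoms_a])
    xb = np.stack([a.pos for a in atoms_b])
    dmat = cdist(xa, xb)
    if require_sidechain:
        bb_a = np.array([not a.is_sidechain for a in atoms_a])
        bb_b = np.array([not a.is_sidechain for a in atoms_b])
        mask = np.outer(bb_a, bb_b)          # both backbone -> excluded
        dmat = np.where(mask, np.inf, dmat)

    if not np.isfinite(dmat).any():
        return frozenset(), np.inf, ("", "")
    i, j = np.unravel_index(np.argmin(dmat), dmat.shape)
    min_d = float(dmat[i, j])
    atom_pair = (atoms_a[i].name, atoms_b[j].name)

    types = set()
    ra = np.array([VDW_RADII.get(a.element.upper(), DEFAULT_RADIUS)
                   for a in atoms_a])
    rb = np.array([VDW_RADII.get(a.element.upper(), DEFAULT_RADIUS)
                   for a in atoms_b])
    if (dmat <= ra[:, None] + rb[None, :] + params.vdw_tolerance).any():
        types.add("vdw")

    ca = np.array([a.element.upper() == "C" for a in atoms_a])
    cb = np.array([a.element.upper() == "C" for a in atoms_b])
    if ca.any() and cb.any():
        if (dmat[np.ix_(ca, cb)] <= params.hydrophobic_max).any():
            types.add("hydrophobic")

    don_a = np.array([a.name in _donor_names(res_a.aa) for a in atoms_a])
    acc_a = np.array([a.name in _acceptor_names(res_a.aa) for a in atoms_a])
    don_b = np.array([a.name in _donor_names(res_b.aa) for a in atoms_b])
    acc_b = np.array([a.name in _acceptor_names(res_b.aa) for a in atoms_b])
    hb = False
    if don_a.any() and acc_b.any():
        hb |= bool((dmat[np.ix_(don_a, acc_b)] <= params.hbond_max).any())
    if acc_a.any() and don_b.any():
        hb |= bool((dmat[np.ix_(acc_a, don_b)] <= params.hbond_max).any())
    if hb:
        types.add("hbond")

    cat_a = np.array([a.name in _cation_names(res_a.aa, params) for a in atoms_a])
    ani_a = np.array([a.name in _anion_names(res_a.aa) for a in atoms_a])
    cat_b = np.array([a.name in _cation_names(res_b.aa, params) for a in atoms_b])
    ani_b = np.array([a.name in _anion_names(res_b.aa) for a in atoms_b])
    ion = False
    if cat_a.any() and ani_b.any():
        ion |= bool((dmat[np.ix_(cat_a, ani_b)] <= params.ionic_max).any())
    if ani_a.any() and cat_b.any():
        ion |= bool((dmat[np.ix_(ani_a, cat_b)] <= params.ionic_max).any())
    if ion:
        types.add("ionic")

    if res_a.aa in AROMATIC_RING and res_b.aa in AROMATIC_RING:
        # ring atoms are all side chain, so the adjacent-residue rule is
        # automatically satisfied for this criterion
        cen_a = _ring_centroid(res_a)
        cen_b = _ring_centroid(res_b)
        if cen_a is not None and cen_b is not None:
            if np.linalg.norm(cen_a - cen_b) <= params.aromatic_centroid_max:
                types.add("aromatic")

    return frozenset(types), min_d, atom_pair


def _make_contact(res_a, res_b, types, min_d, atom_pair) -> Contact:
    if res_b.generic < res_a.generic:
        res_a, res_b = res_b, res_a
        atom_pair = (atom_pair[1], atom_pair[0])
    return Contact(pos_a=res_a.generic, pos_b=res_b.generic,
                   types=types, min_distance=min_d, atom_pair=atom_pair,
                   aa_a=res_a.aa, aa_b=res_b.aa)


def _numbered_residues(s: AnnotatedStructure):
    return [r for r in s.residues if r.generic is not None and r.atoms]


def detect_contacts(s: AnnotatedStructure,
                    params: ContactParams | None = None) -> ContactSet:
    """Detect typed contacts between generically numbered residues.

    Candidate residue pairs are pre-screened with a k-d tree on heavy-atom
    coordinates (atom-pair criteria) and on aromatic ring centroids, then
    each candidate is classified exactly as in the brute-force contract.
    """
    params = params or ContactParams()
    residues = _numbered_residues(s)
    if len(residues) < 2:
        warnings.warn(f"structure {s.structure_id}: fewer than two residues "
                      "with generic numbers; empty contact set")
        return ContactSet(s.structure_id, [],
                          {r.generic for r in residues}, params)

    coords, owner = [], []
    for idx, r in enumerate(residues):
        for a in r.atoms:
            coords.append(a.pos)
            owner.append(idx)
    coords = np.asarray(coords)
    owner = np.asarray(owner)
    tree = cKDTree(coords)
    candidate = set()
    for i, j in tree.query_pairs(params.atom_pair_cutoff):
        a, b = owner[i], owner[j]
        if a != b:
            candidate.add((min(a, b), max(a, b)))

    centroids = {i: c for i, r in enumerate(residues)
                 if (c := _ring_centroid(r)) is not None}
    if len(centroids) >= 2:
        keys = sorted(centroids)
        pts = np.stack([centroids[k] for k in keys])
        ring_tree = cKDTree(pts)
        for i, j in ring_tree.query_pairs(params.aromatic_centroid_max):
            a, b = keys[i], keys[j]
            candidate.add((min(a, b), max(a, b)))

    contacts = []
    for a, b in sorted(candidate):
        types, min_d, atom_pair = _classify_pair(residues[a], residues[b],
                                                 params)
        if types:
            contacts.append(_make_contact(residues[a], residues[b],
                                          types, min_d, atom_pair))
    contacts.sort(key=lambda c: c.pair)
    return ContactSet(s.structure_id, contacts,
                      {r.generic for r in residues}, params)


def detect_contacts_bruteforce(s: AnnotatedStructure,
                               params: ContactParams | None = None) -> ContactSet:
    """Exhaustive all-pairs contact scan (test oracle, no spatial index)."""
    params = params or ContactParams()
    residues = _numbered_residues(s)
    if len(residues) < 2:
        return ContactSet(s.structure_id, [],
                          {r.generic for r in residues}, params)
    contacts = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            types, min_d, atom_pair = _classify_pair(residues[i], residues[j],
                                                     params)
            if types:
                contacts.append(_make_contact(residues[i], residues[j],
                                              types, min_d, atom_pair))
    contacts.sort(key=lambda c: c.pair)
    return ContactSet(s.structure_id, contacts,
                      {r.generic for r in residues}, params)


def write_contact_table(path, contact_set: ContactSet) -> None:
    rows = [{
        "structure_id": contact_set.structure_id,
        "pos_a": str(c.pos_a), "pos_b": str(c.pos_b),
        "types": ",".join(sorted(c.types)),
        "min_distance": round(c.min_distance, 3),
        "atoms": f"{c.atom_pair[0]}-{c.atom_pair[1]}",
        "aa_a": c.aa_a, "aa_b": c.aa_b,
    } for c in contact_set.contacts]
    header = ""
    if contact_set.params is not None:
        kv = " ".join(f"{k}={v}" for k, v in contact_set.params.as_dict().items())
        header = f"# contact_params: {kv}\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(rows, columns=["structure_id", "pos_a", "pos_b", "types",
                                    "min_distance", "atoms", "aa_a", "aa_b"]
                     ).to_csv(fh, sep="\t", index=False)


def read_contact_table(path) -> ContactSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    contacts = []
    sid = ""
    for row in df.itertuples(index=False):
        sid = row.structure_id
        atoms = tuple(str(row.atoms).split("-")) if "-" in str(row.atoms) else ("", "")
        contacts.append(Contact(
            pos_a=GenericPosition.parse(row.pos_a),
            pos_b=GenericPosition.parse(row.pos_b),
            types=frozenset(str(row.types).split(",")),
            min_distance=float(row.min_distance),
            atom_pair=atoms, aa_a=row.aa_a, aa_b=row.aa_b))
    resolved = {p for c in contacts for p in c.pair}
    return ContactSet(str(sid), contacts, resolved)
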
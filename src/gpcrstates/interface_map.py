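"""Ligand- and G-protein-interacting positions and determinant overlay.

A receptor position is ligand-interacting in a structure when any of its
heavy atoms satisfies a contact criterion against a ligand heavy atom
(non-polymer hetero groups above a size floor, or chains flagged as
peptide ligands); interaction frequency is the percentage of
ligand-bearing structures in which this happens.  G-protein interaction
frequencies are computed analogously against a labelled Galpha chain.
Ligand positions are zoned against the membrane frame: only the
orthosteric region (extracellular of the membrane mid within TM1-7, plus
ECL2) is kept by default.  Determinant positions are then overlaid to
count how many sit on ligand sites, on G-protein sites, or on neither
(the transduction path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .contact_engine import ContactParams, VDW_RADII, DEFAULT_RADIUS
from .helix_geometry import MembraneFrame
from .structure_model import AnnotatedStructure, TM_SEGMENTS

__all__ = [
    "InterfaceProfile",
    "DeterminantOverlay",
    "ligand_contact_positions",
    "gprotein_contact_positions",
    "merge_profiles",
    "overlay_determinants",
]

ZONE_ORTHOSTERIC = "upper7TM_ECL2"
ZONE_OTHER = "other"


@dataclass
class InterfaceProfile:
    gpcr_class: str = ""
    #: GenericPosition -> frequency (%) among ligand-bearing structures
    ligand_freq: dict = field(default_factory=dict)
    #: GenericPosition -> frequency (%) among G-protein complexes
    gprotein_freq: dict = field(default_factory=dict)
    #: GenericPosition -> pocket zone
    zone: dict = field(default_factory=dict)
    n_ligand_structures: int = 0
    n_gprotein_structures: int = 0

    def ligand_positions(self) -> set:
        return {p for p, f in self.ligand_freq.items() if f > 0}

    def gprotein_positions(self) -> set:
        return {p for p, f in self.gprotein_freq.items() if f > 0}


def _residue_touches(res, other_xyz: np.ndarray, other_elements,
                     params: ContactParams) -> bool:
    """Any heavy-atom pair within a contact criterion distance.

    For hetero/foreign groups with unknown chemistry the criteria reduce
    to van der Waals overlap, carbon-carbon proximity, and N/O-N/O polar
    pairs within the hydrogen-bond distance.
    """
    if not res.atoms or len(other_xyz) == 0:
        return False
    xa = np.stack([a.pos for a in res.atoms])
    d = cdist(xa, other_xyz)
    ra = np.array([VDW_RADII.get(a.element.upper(), DEFAULT_RADIUS)
                   for a in res.atoms])
    rb = np.array([VDW_RADII.get(str(e).upper(), DEFAULT_RADIUS)
                   for e in other_elements])
    if (d <= ra[:, None] + rb[None, :] + params.vdw_tolerance).any():
        return True
    ca = np.array([a.element.upper() == "C" for a in res.atoms])
    cb = np.array([str(e).upper() == "C" for e in other_elements])
    if ca.any() and cb.any() and (d[np.ix_(ca, cb)] <= params.hydrophobic_max).any():
        return True
    pa = np.array([a.element.upper() in ("N", "O") for a in res.atoms])
    pb = np.array([str(e).upper() in ("N", "O") for e in other_elements])
    if pa.any() and pb.any() and (d[np.ix_(pa, pb)] <= params.hbond_max).any():
        return True
    return False


def _zone(res, frame: MembraneFrame | None) -> str:
    if res.segment == "ECL2":
        return ZONE_ORTHOSTERIC
    if frame is not None and res.segment in TM_SEGMENTS and res.ca is not None:
        if float(frame.height(res.ca)[0]) > 0:
            return ZONE_ORTHOSTERIC
    return ZONE_OTHER


def _foreign_atoms(structure_or_atoms):
    """Heavy-atom coordinates and elements of a ligand/Galpha partner."""
    if isinstance(structure_or_atoms, AnnotatedStructure):
        atoms = [a for r in structure_or_atoms.residues for a in r.atoms]
    else:
        atoms = list(structure_or_atoms)
    if not atoms:
        return np.empty((0, 3)), []
    return np.stack([a.pos for a in atoms]), [a.element for a in atoms]


def ligand_contact_positions(structures, params: ContactParams | None = None,
                             frame: MembraneFrame | None = None,
                             gpcr_class: str = "",
                             peptide_ligands: dict | None = None,
                             orthosteric_only: bool = True) -> InterfaceProfile:
    """Ligand-interaction frequency per generic position.

    ``structures`` are receptor structures whose ``ligands`` side table
    holds the hetero groups; ``peptide_ligands`` optionally maps
    structure_id to an AnnotatedStructure whose residues are a peptide
    ligand.  With ``orthosteric_only`` (default) positions outside the
    orthosteric zone are dropped from the profile, mirroring the omission
    of allosteric sites.
    """
    params = params or ContactParams()
    peptide_ligands = peptide_ligands or {}
    profile = InterfaceProfile(gpcr_class=gpcr_class)
    counts: dict = {}
    n_with_ligand = 0
    for s in structures:
        atom_sets = [lig.atoms for lig in s.ligands]
        pep = peptide_ligands.get(s.structure_id)
        if pep is not None:
            atom_sets.append([a for r in pep.residues for a in r.atoms])
        atom_sets = [a for a in atom_sets if a]
        if not atom_sets:
            continue
        n_with_ligand += 1
        all_atoms = [a for group in atom_sets for a in group]
        xyz, elements = _foreign_atoms(all_atoms)
        for r in s.residues:
            if r.generic is None:
                continue
            if _residue_touches(r, xyz, elements, params):
                counts[r.generic] = counts.get(r.generic, 0) + 1
                profile.zone.setdefault(r.generic, _zone(r, frame))
    if n_with_ligand == 0:
        warnings.warn("no ligand-bearing structures; empty ligand profile")
        return profile
    profile.n_ligand_structures = n_with_ligand
    for pos, k in sorted(counts.items()):
        zone = profile.zone.get(pos, ZONE_OTHER)
        if orthosteric_only and zone != ZONE_ORTHOSTERIC:
            continue
        profile.ligand_freq[pos] = 100.0 * k / n_with_ligand
    return profile


def gprotein_contact_positions(complexes, params: ContactParams | None = None,
                               gpcr_class: str = "") -> InterfaceProfile:
    """G-protein-interaction frequency per generic position.

    ``complexes`` is an iterable of (receptor AnnotatedStructure, Galpha
    partner), the partner being an AnnotatedStructure of the labelled
    Galpha chain or a plain atom list.
    """
    params = params or ContactParams()
    profile = InterfaceProfile(gpcr_class=gpcr_class)
    counts: dict = {}
    n = 0
    for receptor, galpha in complexes:
        xyz, elements = _foreign_atoms(galpha)
        if len(xyz) == 0:
            continue
        n += 1
        for r in receptor.residues:
            if r.generic is None:
                continue
            if _residue_touches(r, xyz, elements, params):
                counts[r.generic] = counts.get(r.generic, 0) + 1
    profile.n_gprotein_structures = n
    for pos, k in sorted(counts.items()):
        profile.gprotein_freq[pos] = 100.0 * k / n
    return profile


def merge_profiles(ligand: InterfaceProfile,
                   gprotein: InterfaceProfile) -> InterfaceProfile:
    merged = InterfaceProfile(
        gpcr_class=ligand.gpcr_class or gprotein.gpcr_class,
        ligand_freq=dict(ligand.ligand_freq),
        gprotein_freq=dict(gprotein.gprotein_freq),
        zone=dict(ligand.zone),
        n_ligand_structures=ligand.n_ligand_structures,
        n_gprotein_structures=gprotein.n_gprotein_structures)
    return merged


@dataclass
class DeterminantOverlay:
    gpcr_class: str
    n_determinants: int
    n_on_ligand: int
    n_on_gprotein: int
    n_transduction: int
    pct_on_ligand: float
    pct_on_gprotein: float
    pct_transduction: float
    switch_sites: dict = field(default_factory=dict)


def overlay_determinants(det_map, profile: InterfaceProfile) -> DeterminantOverlay:
    """Overlay determinant roles on the interface profile.

    A determinant may sit on both a ligand and a G-protein position (it is
    counted in both percentages); the transduction-path count covers
    positions on neither, so ligand-or-G-protein plus transduction counts
    conserve the determinant total.
    """
    if det_map.gpcr_class and profile.gpcr_class and \
            det_map.gpcr_class != profile.gpcr_class:
        raise ValueError("determinant map and profile are from different "
                         "classes")
    ligand = profile.ligand_positions()
    gprot = profile.gprotein_positions()
    n = len(det_map.positions)
    on_lig = on_gp = on_neither = 0
    switch_sites = {}
    for p in det_map.positions:
        hit_l = p.position in ligand
        hit_g = p.position in gprot
        on_lig += hit_l
        on_gp += hit_g
        on_neither += not (hit_l or hit_g)
        if p.role == "switch":
            site = ("ligand" if hit_l else
                    "gprotein" if hit_g else "transduction")
            switch_sites[str(p.position)] = site
    pct = lambda k: 100.0 * k / n if n else 0.0
    return DeterminantOverlay(
        gpcr_class=det_map.gpcr_class,
        n_determinants=n,
        n_on_ligand=on_lig, n_on_gprotein=on_gp, n_transduction=on_neither,
        pct_on_ligand=pct(on_lig), pct_on_gprotein=pct(on_gp),
        pct_transduction=pct(on_neither),
        switch_sites=switch_sites)
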
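"""Geometric detection of the eight protein-ligand interaction classes.

Each fingerprint channel corresponds to one interaction class, in a fixed
order shared by every module of the package:

====  ==========================================
 0    hydrophobic contact
 1    aromatic face-to-face
 2    aromatic edge-to-face
 3    hydrogen bond, protein donor
 4    hydrogen bond, protein acceptor
 5    salt bridge, protein positively charged
 6    salt bridge, protein negatively charged
 7    ionic bond with a metal ion
====  ==========================================

Role perception is rule based and deterministic.  Receptor residues are
typed from a template table keyed by residue and atom names (the twenty
standard amino acids plus the synthetic-pocket templates used by the test
fixtures); ligand atoms are typed from the RDKit topology.  Hydrophobic
atoms are apolar carbons/sulfurs (non-aromatic, no N/O neighbour) so that
aromatic stacking is reported only through the dedicated aromatic channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemio import MoleculeRecord, ReceptorStructure, ResidueRecord

CHANNELS = (
    "hydrophobic",
    "aromatic_f2f",
    "aromatic_e2f",
    "hbond_protein_donor",
    "hbond_protein_acceptor",
    "saltbridge_protein_positive",
    "saltbridge_protein_negative",
    "metal",
)
N_CHANNELS = len(CHANNELS)

METAL_ELEMENTS = {"Zn", "Mg", "Mn", "Fe", "Ca", "Na", "K", "Ni", "Cu", "Co", "Cd"}


@dataclass(frozen=True)
class ContactParams:
    """Geometric cutoffs defining each channel (distances in A, angles in deg).

    Defaults follow common interaction-fingerprint conventions; every value
    is configurable so other fingerprint dialects can be matched.
    """

    hydrophobic_dist: float = 4.0
    aromatic_dist: float = 5.0
    f2f_angle_max: float = 30.0
    e2f_angle_min: float = 60.0
    hbond_dist: float = 3.5
    hbond_angle_min: float = 120.0
    saltbridge_dist: float = 4.0
    metal_dist: float = 2.8

    def __post_init__(self) -> None:
        for name in (
            "hydrophobic_dist", "aromatic_dist", "hbond_dist",
            "saltbridge_dist", "metal_dist",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("f2f_angle_max", "e2f_angle_min", "hbond_angle_min"):
            if not 0.0 <= getattr(self, name) <= 180.0:
                raise ValueError(f"{name} must lie in [0, 180] degrees")


@dataclass(frozen=True)
class Contact:
    """One satisfied (residue, channel) predicate with its realized geometry."""

    residue_index: int
    channel: int
    receptor_atoms: tuple[str, ...]
    ligand_atoms: tuple[int, ...]
    distance: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.channel < N_CHANNELS:
            raise ValueError(f"channel must be 0..{N_CHANNELS - 1}")


@dataclass
class Ring:
    """An aromatic ring: member labels, centroid and unit normal."""

    atoms: tuple
    centroid: np.ndarray
    normal: np.ndarray


@dataclass
class HBondDonor:
    """Donor heavy atom with the coordinates of any explicit hydrogens."""

    atom: object
    xyz: np.ndarray
    h_xyz: list = field(default_factory=list)


@dataclass
class ChargedGroup:
    atoms: tuple
    centroid: np.ndarray


@dataclass
class RoleAssignment:
    """Perceived interaction roles of one monomer (residue or ligand)."""

    hydrophobic: list = field(default_factory=list)   # (label, xyz)
    rings: list[Ring] = field(default_factory=list)
    donors: list[HBondDonor] = field(default_factory=list)
    acceptors: list = field(default_factory=list)     # (label, xyz)
    positive: list[ChargedGroup] = field(default_factory=list)
    negative: list[ChargedGroup] = field(default_factory=list)
    metals: list = field(default_factory=list)        # (label, xyz)


# ---------------------------------------------------------------------------
# receptor residue templates
# ---------------------------------------------------------------------------

# name -> role -> atom-name sets.  "ring" entries are lists of rings.
_RESIDUE_TEMPLATES: dict[str, dict] = {
    "ALA": {"hydrophobic": {"CB"}},
    "VAL": {"hydrophobic": {"CB", "CG1", "CG2"}},
    "LEU": {"hydrophobic": {"CB", "CG", "CD1", "CD2"}},
    "ILE": {"hydrophobic": {"CB", "CG1", "CG2", "CD1"}},
    "MET": {"hydrophobic": {"CB", "CG", "SD", "CE"}},
    "MSE": {"hydrophobic": {"CB", "CG", "CE"}},
    "PRO": {"hydrophobic": {"CB", "CG", "CD"}},
    "GLY": {},
    "CYS": {"hydrophobic": {"CB", "SG"}, "donor": {"SG"}},
    "SER": {"donor": {"OG"}, "acceptor": {"OG"}},
    "THR": {"hydrophobic": {"CG2"}, "donor": {"OG1"}, "acceptor": {"OG1"}},
    "ASN": {"donor": {"ND2"}, "acceptor": {"OD1"}},
    "GLN": {"hydrophobic": {"CB"}, "donor": {"NE2"}, "acceptor": {"OE1"}},
    "ASP": {"acceptor": {"OD1", "OD2"}, "negative": [("CG", "OD1", "OD2")]},
    "GLU": {
        "hydrophobic": {"CB"},
        "acceptor": {"OE1", "OE2"},
        "negative": [("CD", "OE1", "OE2")],
    },
    "LYS": {"hydrophobic": {"CB", "CG", "CD"}, "donor": {"NZ"}, "positive": [("NZ",)]},
    "ARG": {
        "hydrophobic": {"CB", "CG", "CD"},
        "donor": {"NE", "NH1", "NH2"},
        "positive": [("CZ", "NE", "NH1", "NH2")],
    },
    "HIS": {
        "donor": {"ND1", "NE2"},
        "acceptor": {"ND1", "NE2"},
        "rings": [("CG", "ND1", "CD2", "CE1", "NE2")],
    },
    "PHE": {
        "hydrophobic": {"CB"},
        "rings": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    },
    "TYR": {
        "hydrophobic": {"CB"},
        "donor": {"OH"},
        "acceptor": {"OH"},
        "rings": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    },
    "TRP": {
        "hydrophobic": {"CB"},
        "donor": {"NE1"},
        "rings": [
            ("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
        ],
    },
    # synthetic-pocket residue templates (see synthetic_fixtures)
    "HPH": {"hydrophobic": {"C1", "C2"}},
    "ARF": {"rings": [("C1", "C2", "C3", "C4", "C5", "C6")]},
    "DNR": {"donor": {"N1"}},
    "ACC": {"acceptor": {"O1"}},
    "AMM": {"donor": {"N1"}, "positive": [("N1",)]},
    "CRX": {"acceptor": {"O1", "O2"}, "negative": [("C1", "O1", "O2")]},
}

_BACKBONE_DONOR_EXCLUDED = {"PRO"}


def _unit_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through ``coords`` (SVD)."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n = vt[-1]
    return n / np.linalg.norm(n)


def assign_residue_roles(residue: ResidueRecord) -> RoleAssignment:
    """Perceive interaction roles for one receptor residue.

    Uses the template table for known residue names (standard amino acids
    plus fixture templates); unknown residues fall back to element rules
    (C/S -> hydrophobic, N -> donor, O -> acceptor, metal elements -> metal).
    """
    roles = RoleAssignment()
    tpl = _RESIDUE_TEMPLATES.get(residue.name)
    by_name = {a.name: a for a in residue.atoms}

    def h_coords_near(heavy) -> list:
        # explicit hydrogens bonded to the heavy atom: within 1.3 A
        out = []
        for a in residue.atoms:
            if a.element == "H" and np.linalg.norm(a.xyz - heavy.xyz) <= 1.3:
                out.append(a.xyz)
        return out

    # metal ions (single-atom residues such as ZN, MG)
    for a in residue.atoms:
        if a.element in METAL_ELEMENTS:
            roles.metals.append((a.name, a.xyz))
    if roles.metals:
        return roles

    if tpl is not None:
        for name in tpl.get("hydrophobic", ()):
            if name in by_name:
                roles.hydrophobic.append((name, by_name[name].xyz))
        for ring_names in tpl.get("rings", []):
            coords = np.array([by_name[n].xyz for n in ring_names if n in by_name])
            if len(coords) >= 3:
                roles.rings.append(
                    Ring(tuple(ring_names), coords.mean(axis=0), _unit_normal(coords))
                )
        for name in tpl.get("donor", ()):
            if name in by_name:
                heavy = by_name[name]
                roles.donors.append(HBondDonor(name, heavy.xyz, h_coords_near(heavy)))
        for name in tpl.get("acceptor", ()):
            if name in by_name:
                roles.acceptors.append((name, by_name[name].xyz))
        for group in tpl.get("positive", []):
            coords = np.array([by_name[n].xyz for n in group if n in by_name])
            if len(coords):
                roles.positive.append(ChargedGroup(tuple(group), coords.mean(axis=0)))
        for group in tpl.get("negative", []):
            coords = np.array([by_name[n].xyz for n in group if n in by_name])
            if len(coords):
                roles.negative.append(ChargedGroup(tuple(group), coords.mean(axis=0)))
        # backbone donor/acceptor for standard amino acids
        if residue.name in _RESIDUE_TEMPLATES and residue.name not in {
            "HPH", "ARF", "DNR", "ACC", "AMM", "CRX",
        }:
            if "N" in by_name and residue.name not in _BACKBONE_DONOR_EXCLUDED:
                heavy = by_name["N"]
                roles.donors.append(HBondDonor("N", heavy.xyz, h_coords_near(heavy)))
            for name in ("O", "OXT"):
                if name in by_name:
                    roles.acceptors.append((name, by_name[name].xyz))
    else:
        for a in residue.atoms:
            if a.element in {"C", "S"}:
                roles.hydrophobic.append((a.name, a.xyz))
            elif a.element == "N":
                roles.donors.append(HBondDonor(a.name, a.xyz, h_coords_near(a)))
            elif a.element == "O":
                roles.acceptors.append((a.name, a.xyz))
    return roles


# ---------------------------------------------------------------------------
# ligand role assignment
# ---------------------------------------------------------------------------

_CARBOXYLATE = Chem.MolFromSmarts("[CX3](=O)[O-]")
_GUANIDINIUM = Chem.MolFromSmarts("[NX3][CX3](=[NX3+])[NX3]")
_IMIDAZOLIUM = Chem.MolFromSmarts("c1c[nH+]cn1")


def assign_ligand_roles(record: MoleculeRecord) -> RoleAssignment:
    """Perceive interaction roles of a posed small molecule.

    Requires a conformer.  Rules (documented, deterministic):

    * hydrophobic: non-aromatic C/S with no N/O/F neighbour;
    * aromatic rings: rings whose atoms are all flagged aromatic;
    * donors: N/O/S bearing at least one hydrogen (explicit H coordinates
      are collected when present, enabling the donor-angle criterion);
    * acceptors: any O with formal charge <= 0, and neutral N that is
      neither an aromatic N-H nor an amide nitrogen;
    * charged groups: formal charges, grouped by template SMARTS for
      carboxylate / guanidinium / imidazolium, otherwise single atoms.
    """
    if not record.has_conformer():
        raise ValueError(f"molecule {record.name!r} has no 3D coordinates")
    mol = record.mol
    coords = record.coordinates()
    roles = RoleAssignment()

    def is_amide_n(atom) -> bool:
        for nbr in atom.GetNeighbors():
            if nbr.GetSymbol() == "C":
                for b in nbr.GetBonds():
                    other = b.GetOtherAtom(nbr)
                    if (
                        other.GetSymbol() == "O"
                        and b.GetBondType() == Chem.BondType.DOUBLE
                    ):
                        return True
        return False

    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        if sym == "H":
            continue
        nbr_syms = {n.GetSymbol() for n in atom.GetNeighbors()}
        if (
            sym in {"C", "S"}
            and not atom.GetIsAromatic()
            and not nbr_syms & {"N", "O", "F"}
        ):
            roles.hydrophobic.append((i, coords[i]))
        if sym in {"N", "O", "S"} and atom.GetTotalNumHs(includeNeighbors=True) >= 1:
            h_xyz = [
                coords[n.GetIdx()]
                for n in atom.GetNeighbors()
                if n.GetSymbol() == "H"
            ]
            roles.donors.append(HBondDonor(i, coords[i], h_xyz))
        if sym == "O" and atom.GetFormalCharge() <= 0:
            roles.acceptors.append((i, coords[i]))
        elif (
            sym == "N"
            and atom.GetFormalCharge() <= 0
            and not (
                atom.GetIsAromatic()
                and atom.GetTotalNumHs(includeNeighbors=True) >= 1
            )
            and not is_amide_n(atom)
        ):
            roles.acceptors.append((i, coords[i]))
        if sym in METAL_ELEMENTS:
            roles.metals.append((i, coords[i]))

    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            pts = coords[list(ring)]
            roles.rings.append(Ring(tuple(ring), pts.mean(axis=0), _unit_normal(pts)))

    grouped: set[int] = set()
    for patt, sign in ((_CARBOXYLATE, -1), (_GUANIDINIUM, +1), (_IMIDAZOLIUM, +1)):
        if patt is None:
            continue
        for match in mol.GetSubstructMatches(patt):
            pts = coords[list(match)]
            group = ChargedGroup(tuple(match), pts.mean(axis=0))
            (roles.negative if sign < 0 else roles.positive).append(group)
            grouped.update(match)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        if i in grouped:
            continue
        q = atom.GetFormalCharge()
        if q > 0:
            roles.positive.append(ChargedGroup((i,), coords[i]))
        elif q < 0:
            roles.negative.append(ChargedGroup((i,), coords[i]))
    return roles


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------

def _interplane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two ring planes, folded into [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def _hbond(donors, acceptors, params: ContactParams):
    """Best satisfied donor->acceptor pair, or None."""
    best = None
    for d in donors:
        for label, axyz in acceptors:
            dist = float(np.linalg.norm(d.xyz - axyz))
            if dist > params.hbond_dist:
                continue
            angle = None
            if d.h_xyz:
                angle = max(_angle(d.xyz, h, axyz) for h in d.h_xyz)
                if angle < params.hbond_angle_min:
                    continue
            if best is None or dist < best[2]:
                best = (d.atom, label, dist, angle)
    return best


def detect_contacts(
    receptor: ReceptorStructure,
    pose: MoleculeRecord,
    params: ContactParams | None = None,
) -> list[Contact]:
    """Detect every satisfied (residue, channel) interaction predicate.

    Receptor and pose must share one coordinate frame.  At most one contact
    is reported per (residue, channel); the closest realizing pair is kept.
    """
    params = params or ContactParams()
    lig = assign_ligand_roles(pose)
    contacts: list[Contact] = []

    for idx, residue in enumerate(receptor.residues):
        rec = assign_residue_roles(residue)

        # 0 hydrophobic
        best = None
        for rname, rxyz in rec.hydrophobic:
            for li, lxyz in lig.hydrophobic:
                d = float(np.linalg.norm(rxyz - lxyz))
                if d <= params.hydrophobic_dist and (best is None or d < best[2]):
                    best = (rname, li, d)
        if best:
            contacts.append(Contact(idx, 0, (best[0],), (best[1],), best[2]))

        # 1 / 2 aromatic
        best_f2f = best_e2f = None
        for rring in rec.rings:
            for lring in lig.rings:
                d = float(np.linalg.norm(rring.centroid - lring.centroid))
                if d > params.aromatic_dist:
                    continue
                ang = _interplane_angle(rring.normal, lring.normal)
                if ang <= params.f2f_angle_max:
                    if best_f2f is None or d < best_f2f[2]:
                        best_f2f = (rring, lring, d, ang)
                elif params.e2f_angle_min <= ang <= 90.0:
                    if best_e2f is None or d < best_e2f[2]:
                        best_e2f = (rring, lring, d, ang)
        if best_f2f:
            r, l, d, ang = best_f2f
            contacts.append(Contact(idx, 1, tuple(r.atoms), tuple(l.atoms), d, ang))
        if best_e2f:
            r, l, d, ang = best_e2f
            contacts.append(Contact(idx, 2, tuple(r.atoms), tuple(l.atoms), d, ang))

        # 3 protein donor -> ligand acceptor
        hit = _hbond(rec.donors, lig.acceptors, params)
        if hit:
            contacts.append(Contact(idx, 3, (hit[0],), (hit[1],), hit[2], hit[3]))

        # 4 ligand donor -> protein acceptor
        hit = _hbond(lig.donors, rec.acceptors, params)
        if hit:
            contacts.append(Contact(idx, 4, (hit[1],), (hit[0],), hit[2], hit[3]))

        # 5 / 6 salt bridges
        best = None
        for rg in rec.positive:
            for lg in lig.negative:
                d = float(np.linalg.norm(rg.centroid - lg.centroid))
                if d <= params.saltbridge_dist and (best is None or d < best[2]):
                    best = (rg, lg, d)
        if best:
            contacts.append(
                Contact(idx, 5, tuple(best[0].atoms), tuple(best[1].atoms), best[2])
            )
        best = None
        for rg in rec.negative:
            for lg in lig.positive:
                d = float(np.linalg.norm(rg.centroid - lg.centroid))
                if d <= params.saltbridge_dist and (best is None or d < best[2]):
                    best = (rg, lg, d)
        if best:
            contacts.append(
                Contact(idx, 6, tuple(best[0].atoms), tuple(best[1].atoms), best[2])
            )

        # 7 metal coordination
        best = None
        lig_coord = list(lig.acceptors) + [
            (g.atoms[0], g.centroid) for g in lig.negative
        ]
        for mname, mxyz in rec.metals:
            for label, axyz in lig_coord:
                d = float(np.linalg.norm(mxyz - axyz))
                if d <= params.metal_dist and (best is None or d < best[2]):
                    best = (mname, label, d)
        if best:
            contacts.append(Contact(idx, 7, (best[0],), (best[1],), best[2]))

    return contacts


def contacts_to_rows(contacts: list[Contact], receptor: ReceptorStructure) -> list[dict]:
    """Flatten contacts for CSV export."""
    rows = []
    for c in contacts:
        res = receptor.residues[c.residue_index]
        rows.append(
            {
                "residue": f"{res.chain_id}:{res.name}{res.number}{res.icode}",
                "residue_index": c.residue_index,
                "channel": CHANNELS[c.channel],
                "receptor_atoms": "+".join(map(str, c.receptor_atoms)),
                "ligand_atoms": "+".join(map(str, c.ligand_atoms)),
                "distance": round(c.distance, 3),
                "angle": None if c.angle is None else round(c.angle, 1),
            }
        )
    return rows
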
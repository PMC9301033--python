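"""Synthetic protein-ligand complexes with exactly known interactions.

Every other module is testable against these fixtures without downloading
a single structure.  A toy complex consists of a multi-group ligand laid
out on a circle around the origin and, for each *planted* interaction, one
minimal residue template placed at ideal geometry just outside the matching
ligand group.  Because the geometry is constructed from the channel cutoffs
themselves, the planted (residue, channel) list IS the ground truth: the
default :class:`~ifpgrow.interactions.ContactParams` must recover it
exactly at zero noise.

Residue templates use idealized internal geometry (standard bond lengths
and angles), not fragments of real structures, so the ground truth is exact
by construction.  The geometry of each slot is tuned so that no secondary
predicate fires: e.g. salt-bridge partners keep their donor-acceptor heavy
atoms beyond the hydrogen-bond cutoff, and stacked rings sit beyond the
hydrophobic cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemio import AtomRecord, MoleculeRecord, ReceptorStructure, ResidueRecord
from .evolve import attach_fragment
from .interactions import N_CHANNELS
from .posegen import _set_conformer

#: channel index -> residue template name placed for it
CHANNEL_TEMPLATES = {
    0: "HPH", 1: "ARF", 2: "ARF", 3: "DNR",
    4: "ACC", 5: "AMM", 6: "CRX", 7: "ZN",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one toy complex.

    ``channels`` lists the planted interactions: slot ``i`` produces residue
    ``i`` engaging the ligand through channel ``channels[i]``.  ``sigma``
    adds Gaussian coordinate noise (A) to both partners; ``templates`` may
    override the residue template per slot but must stay role-consistent
    with the planted channel.
    """

    channels: tuple[int, ...]
    sigma: float = 0.0
    seed: int = 0
    circle_radius: float = 8.0
    templates: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one planted interaction is required")
        for c in self.channels:
            if not 0 <= c < N_CHANNELS:
                raise ValueError(f"invalid channel {c}")
        if self.templates is not None:
            if len(self.templates) != len(self.channels):
                raise ValueError("templates must match channels in length")
            for c, t in zip(self.channels, self.templates):
                if t != CHANNEL_TEMPLATES[c]:
                    raise ValueError(
                        f"template {t!r} cannot realize channel {c} "
                        f"(needs {CHANNEL_TEMPLATES[c]!r})"
                    )
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


# ---------------------------------------------------------------------------
# local-frame group geometry (x = outward direction of the slot)
# ---------------------------------------------------------------------------

def _ring_coords(center: np.ndarray, u: np.ndarray, v: np.ndarray, r=1.39):
    """Six-membered ring in the plane spanned by unit vectors u, v."""
    return [
        center + r * (np.cos(a) * u + np.sin(a) * v)
        for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)
    ]


_GROUPS: dict[int, tuple[str, list[list[float]]]] = {
    # channel: (SMILES parsed with explicit H kept, atom coordinates in order)
    0: ("C", [[0.0, 0.0, 0.0]]),
    3: ("COC", [[-0.80, 1.16, 0.0], [0.0, 0.0, 0.0], [-0.80, -1.16, 0.0]]),
    7: ("COC", [[-0.80, 1.16, 0.0], [0.0, 0.0, 0.0], [-0.80, -1.16, 0.0]]),
    4: ("[H]OC", [[0.96, 0.0, 0.0], [0.0, 0.0, 0.0], [-0.46, 1.33, 0.0]]),
    5: (
        "CC(=O)[O-]",
        [
            [-1.52, 0.0, 0.0],       # methyl
            [0.0, 0.0, 0.0],         # carboxylate C
            [0.625, 1.083, 0.0],     # O
            [0.625, -1.083, 0.0],    # O-
        ],
    ),
    6: (
        "[H][N+]([H])([H])C",
        [
            [0.0, 1.02, 0.0],
            [0.0, 0.0, 0.0],         # N+
            [0.0, -0.51, 0.88],
            [0.0, -0.51, -0.88],
            [-1.50, 0.0, 0.0],       # methyl
        ],
    ),
}


def _ligand_piece(channel: int) -> tuple[Chem.Mol, np.ndarray]:
    if channel in (1, 2):
        mol = Chem.MolFromSmiles("c1ccccc1")
        coords = np.array(
            _ring_coords(
                np.zeros(3), np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
            )
        )
        return mol, coords
    smi, coords = _GROUPS[channel]
    ps = Chem.SmilesParserParams()
    ps.removeHs = False
    mol = Chem.MolFromSmiles(smi, ps)
    return mol, np.asarray(coords, dtype=float)


def _residue_atoms(channel: int) -> list[tuple[str, str, list[float]]]:
    """(atom name, element, local coords) for the slot's residue template."""
    if channel == 0:  # HPH: ethane-like hydrophobe
        return [("C1", "C", [3.8, 0.0, 0.0]), ("C2", "C", [5.3, 0.0, 0.0])]
    if channel == 1:  # ARF parallel ring (normal x), stacked at 4.5 A
        ring = _ring_coords(
            np.array([4.5, 0.0, 0.0]),
            np.array([0.0, 1.0, 0.0]),
            np.array([0.0, 0.0, 1.0]),
        )
        return [(f"C{i+1}", "C", list(p)) for i, p in enumerate(ring)]
    if channel == 2:  # ARF perpendicular ring (normal z): edge-to-face
        ring = _ring_coords(
            np.array([4.5, 0.0, 0.0]),
            np.array([1.0, 0.0, 0.0]),
            np.array([0.0, 1.0, 0.0]),
        )
        return [(f"C{i+1}", "C", list(p)) for i, p in enumerate(ring)]
    if channel == 3:  # DNR: N-H aimed at the ligand ether oxygen
        return [
            ("N1", "N", [2.9, 0.0, 0.0]),
            ("H1", "H", [1.9, 0.0, 0.0]),
            ("C1", "C", [4.37, 0.0, 0.0]),
        ]
    if channel == 4:  # ACC: carbonyl-like acceptor facing the ligand O-H
        return [
            ("O1", "O", [2.9, 0.0, 0.0]),
            ("C1", "C", [4.13, 0.0, 0.0]),
        ]
    if channel == 5:  # AMM: methylammonium tip, N-H pointing sideways
        return [
            ("N1", "N", [4.2, 0.0, 0.0]),
            ("H11", "H", [4.2, 1.02, 0.0]),
            ("H12", "H", [4.2, -0.51, 0.88]),
            ("H13", "H", [4.2, -0.51, -0.88]),
            ("C1", "C", [5.7, 0.0, 0.0]),
        ]
    if channel == 6:  # CRX: carboxylate facing the ligand ammonium
        return [
            ("C1", "C", [4.2, 0.0, 0.0]),
            ("O1", "O", [3.575, 1.083, 0.0]),
            ("O2", "O", [3.575, -1.083, 0.0]),
        ]
    if channel == 7:  # ZN: a single metal ion at coordination distance
        return [("ZN", "Zn", [2.4, 0.0, 0.0])]
    raise ValueError(f"invalid channel {channel}")


def _slot_rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_toy_complex(
    spec: FixtureSpec,
) -> tuple[ReceptorStructure, MoleculeRecord, list[tuple[int, int]]]:
    """Build one toy complex.

    Returns the receptor (one residue per planted slot, in slot order), the
    posed multi-group ligand, and the ground-truth (residue index, channel)
    list, which the default contact parameters recover exactly at sigma 0.
    """
    rng = np.random.default_rng(spec.seed)
    K = len(spec.channels)
    residues: list[ResidueRecord] = []
    lig_mol: Chem.Mol | None = None
    lig_coords: list[np.ndarray] = []
    ground_truth: list[tuple[int, int]] = []

    for slot, channel in enumerate(spec.channels):
        theta = 2.0 * np.pi * slot / K
        rot = _slot_rotation(theta)
        anchor = rot @ np.array([spec.circle_radius, 0.0, 0.0])

        piece, local = _ligand_piece(channel)
        world = (rot @ local.T).T + anchor
        if spec.sigma > 0:
            world = world + rng.normal(0.0, spec.sigma, world.shape)
        lig_mol = piece if lig_mol is None else Chem.CombineMols(lig_mol, piece)
        lig_coords.append(world)

        atoms = []
        for name, element, xyz in _residue_atoms(channel):
            # residue local coords are expressed relative to the slot anchor
            pos = rot @ np.asarray(xyz) + anchor
            if spec.sigma > 0:
                pos = pos + rng.normal(0.0, spec.sigma, 3)
            atoms.append(
                AtomRecord(name=name, element=element, coords=tuple(map(float, pos)))
            )
        residues.append(
            ResidueRecord(
                chain_id="A",
                number=slot + 1,
                icode="",
                name=CHANNEL_TEMPLATES[channel],
                atoms=tuple(atoms),
            )
        )
        ground_truth.append((slot, channel))

    Chem.SanitizeMol(lig_mol)
    coords = np.vstack(lig_coords)
    _set_conformer(lig_mol, coords)
    ligand = MoleculeRecord(lig_mol, name=f"toy_ligand_seed{spec.seed}")
    receptor = ReceptorStructure(residues=residues, source=f"toy:{spec.seed}")
    return receptor, ligand, ground_truth


# ---------------------------------------------------------------------------
# a connected-ligand pocket for end-to-end evolution demos
# ---------------------------------------------------------------------------

KINASE_SITE_LIGAND = "COc1cc(C)ccc1O"


def make_kinase_site(
    seed: int = 0,
) -> tuple[ReceptorStructure, MoleculeRecord, list[tuple[int, int]]]:
    """A pocket around one connected, drug-like reference ligand.

    The ligand (a methyl-methoxy-phenol) is ETKDG-embedded, then four
    residue templates are placed at ideal geometry against its perceived
    roles, emulating a kinase hinge environment: a backbone-like acceptor
    opposite the phenol O-H (channel 4), a backbone-like donor at the
    methoxy oxygen (channel 3), an aromatic ring stacked on the benzene
    ring (channel 1), and a hydrophobe at the ring methyl (channel 0).
    Useful as the reference complex of evolution runs, because growing
    fragments toward this ligand's topology recovers its contacts.
    """
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(KINASE_SITE_LIGAND))
    ps = AllChem.ETKDGv3()
    ps.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(mol, ps) != 0:  # pragma: no cover
        raise RuntimeError("embedding of the site ligand failed")
    mol = Chem.RemoveHs(mol)
    coords = np.asarray(mol.GetConformer().GetPositions())

    def unit(v):
        return v / np.linalg.norm(v)

    # locate the functional groups
    phenol_o = methoxy_o = methyl_c = None
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "O" and atom.GetTotalNumHs() >= 1:
            phenol_o = atom
        elif atom.GetSymbol() == "O":
            methoxy_o = atom
        elif (
            atom.GetSymbol() == "C"
            and not atom.GetIsAromatic()
            and all(n.GetIsAromatic() for n in atom.GetNeighbors())
        ):
            methyl_c = atom
    ring = next(
        r
        for r in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
    )
    ring_pts = coords[list(ring)]
    centroid = ring_pts.mean(axis=0)
    centered = ring_pts - centroid
    normal = np.linalg.svd(centered)[2][-1]
    normal = unit(normal)

    residues = []

    # channel 4: acceptor opposite the phenol oxygen, pointing away from ring
    o = coords[phenol_o.GetIdx()]
    u = unit(o - coords[phenol_o.GetNeighbors()[0].GetIdx()])
    residues.append(
        ResidueRecord(
            "A", 1, "", "ACC",
            (
                AtomRecord("O1", "O", tuple(o + 2.9 * u)),
                AtomRecord("C1", "C", tuple(o + 4.13 * u)),
            ),
        )
    )
    # channel 3: donor at the methoxy oxygen, along the lone-pair bisector
    o = coords[methoxy_o.GetIdx()]
    nbrs = [coords[n.GetIdx()] for n in methoxy_o.GetNeighbors()]
    u = unit(-(unit(nbrs[0] - o) + unit(nbrs[1] - o)))
    residues.append(
        ResidueRecord(
            "A", 2, "", "DNR",
            (
                AtomRecord("N1", "N", tuple(o + 2.9 * u)),
                AtomRecord("H1", "H", tuple(o + 1.9 * u)),
                AtomRecord("C1", "C", tuple(o + 4.37 * u)),
            ),
        )
    )
    # channel 1: parallel aromatic ring stacked along the ring normal
    ring_center = centroid + 4.5 * normal
    v1 = unit(centered[0])
    v2 = unit(np.cross(normal, v1))
    stacked = _ring_coords(ring_center, v1, v2)
    residues.append(
        ResidueRecord(
            "A", 3, "", "ARF",
            tuple(
                AtomRecord(f"C{i+1}", "C", tuple(p)) for i, p in enumerate(stacked)
            ),
        )
    )
    # channel 0: hydrophobe near the ring methyl, pointing outward
    c = coords[methyl_c.GetIdx()]
    u = unit(c - coords[methyl_c.GetNeighbors()[0].GetIdx()])
    residues.append(
        ResidueRecord(
            "A", 4, "", "HPH",
            (
                AtomRecord("C1", "C", tuple(c + 3.8 * u)),
                AtomRecord("C2", "C", tuple(c + 5.3 * u)),
            ),
        )
    )
    receptor = ReceptorStructure(residues=residues, source=f"kinase-site:{seed}")
    ligand = MoleculeRecord(mol, name="site_reference")
    ground_truth = [(0, 4), (1, 3), (2, 1), (3, 0)]
    return receptor, ligand, ground_truth


# ---------------------------------------------------------------------------
# fragment libraries
# ---------------------------------------------------------------------------

_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "c1cncnc1", "C1CCCCC1", "C1CCNCC1", "c1ccc2ccccc2c1", "Oc1ccccc1",
    "COc1ccccc1", "Nc1ccccc1",
]
_DECORATIONS = ["C", "CC", "O", "N", "CO", "C(C)C", "OC", "C#N", "F", "Cl"]


def make_fragment_library(
    n: int, seed: int = 0, mw_range: tuple[float, float] | None = (100.0, 150.0)
) -> list[MoleculeRecord]:
    """Generate ``n`` small, valence-correct fragments deterministically.

    Fragments are enumerated by single-bond decoration of a fixed scaffold
    set and, when ``mw_range`` is given, gated to the fragment-like
    molecular-weight window of 100-150 Da used for de novo seeding.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool: dict[str, Chem.Mol] = {}

    def consider(mol: Chem.Mol | None):
        if mol is None:
            return
        smi = Chem.MolToSmiles(mol)
        if smi in pool:
            return
        if mw_range is not None:
            mw = Descriptors.MolWt(mol)
            if not mw_range[0] <= mw <= mw_range[1]:
                return
        pool[smi] = mol

    singles = []
    for smi in _SCAFFOLDS:
        scaffold = Chem.MolFromSmiles(smi)
        consider(scaffold)
        for dec in _DECORATIONS:
            frag = Chem.MolFromSmiles(dec)
            sites = [
                a.GetIdx()
                for a in scaffold.GetAtoms()
                if a.GetSymbol() in {"C", "N"} and a.GetTotalNumHs() >= 1
            ]
            fsites = [
                a.GetIdx()
                for a in frag.GetAtoms()
                if a.GetSymbol() in {"C", "N", "O"} and a.GetTotalNumHs() >= 1
            ]
            for si in sites[:3]:
                for fi in fsites[:1]:
                    child = attach_fragment(scaffold, frag, si, fi)
                    if child is not None:
                        singles.append(child)
                        consider(child)
    # second decoration round to fill the weight window
    for base in singles:
        for dec in _DECORATIONS[:5]:
            frag = Chem.MolFromSmiles(dec)
            sites = [
                a.GetIdx()
                for a in base.GetAtoms()
                if a.GetSymbol() in {"C", "N"} and a.GetTotalNumHs() >= 1
            ]
            if not sites:
                continue
            child = attach_fragment(base, frag, sites[0], 0)
            consider(child)
        if len(pool) >= max(4 * n, 200):
            break

    smiles = sorted(pool)
    if len(smiles) < n:
        raise ValueError(
            f"only {len(smiles)} distinct fragments available in the requested "
            f"weight window, cannot return {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(len(smiles))[:n]
    return [
        MoleculeRecord(pool[smiles[i]], name=f"frag{k}")
        for k, i in enumerate(sorted(chosen))
    ]
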
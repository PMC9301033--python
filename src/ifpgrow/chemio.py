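"""Readers, writers and run configuration.

The package works with two in-memory containers: :class:`ReceptorStructure`
(an ordered list of polymer residues parsed from a PDB file, which defines
the residue indexing of every interaction fingerprint) and
:class:`MoleculeRecord` (a thin named wrapper around an RDKit molecule,
optionally carrying a 3D conformer used as a docking pose).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger("ifpgrow")

#: Residue names treated as polymer even when they appear in HETATM records.
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class ParseError(ValueError):
    """A structure or molecule file could not be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a receptor residue (coordinates in Angstrom)."""

    name: str
    element: str
    coords: tuple[float, float, float]
    formal_charge: int = 0

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: identity key is (chain_id, number, icode)."""

    chain_id: str
    number: int
    icode: str
    name: str
    atoms: tuple[AtomRecord, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class ReceptorStructure:
    """Ordered polymer residues of a receptor.

    ``residues`` follow file order and define the fingerprint residue index
    0..r-1.  Non-polymer HETATM groups (waters, ligands, ions) are kept in
    ``hetero`` and never contribute to the index.
    """

    residues: list[ResidueRecord]
    hetero: list[ResidueRecord] = field(default_factory=list)
    source: str = ""

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


class MoleculeRecord:
    """A named small molecule, optionally with one 3D conformer (a pose).

    Wraps an RDKit ``Mol``; the canonical SMILES, heavy-atom coordinates and
    per-atom partial charges are derived on demand from the wrapped topology.
    """

    def __init__(self, mol: Chem.Mol, name: str = "", props: dict | None = None):
        if mol is None:
            raise ParseError("cannot build a MoleculeRecord from a null molecule")
        self.mol = mol
        self.name = name or (mol.GetProp("_Name") if mol.HasProp("_Name") else "")
        self.props: dict = dict(props or {})

    # -- constructors -------------------------------------------------
    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ParseError(f"invalid SMILES: {smiles!r}")
        return cls(mol, name=name)

    # -- basic views --------------------------------------------------
    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def has_conformer(self) -> bool:
        return self.mol.GetNumConformers() > 0

    def coordinates(self) -> np.ndarray:
        """All-atom coordinates of the (single) conformer, in Angstrom."""
        if not self.has_conformer():
            raise ValueError(f"molecule {self.name!r} has no conformer")
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    def copy(self) -> "MoleculeRecord":
        return MoleculeRecord(Chem.Mol(self.mol), name=self.name, props=dict(self.props))

    def partial_charges(self) -> np.ndarray:
        """Per-atom partial charges; Gasteiger-assigned on first request."""
        if not all(a.HasProp("_GasteigerCharge") for a in self.mol.GetAtoms()):
            AllChem.ComputeGasteigerCharges(self.mol)
            self.props.setdefault("charge_model", "gasteiger")
        q = np.array(
            [float(a.GetProp("_GasteigerCharge")) for a in self.mol.GetAtoms()]
        )
        return np.nan_to_num(q)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MoleculeRecord({self.name or self.smiles!r})"


# ---------------------------------------------------------------------------
# receptor reading / writing
# ---------------------------------------------------------------------------

def read_receptor(path: str | Path) -> ReceptorStructure:
    """Read a PDB file into a :class:`ReceptorStructure`.

    ATOM records (and HETATM records whose residue name is a standard amino
    acid) form the polymer residue list, in file order.  Everything else —
    waters, ligands, ions — is collected separately in ``hetero``.
    Duplicate (chain, number, icode) keys are an error because they would
    corrupt fingerprint indexing.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"receptor file not found: {path}")
    # pre-scan raw records: the permissive parser would silently merge
    # residues that share a (chain, number, icode) key
    seen_keys: dict[tuple, tuple] = {}
    last_key = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        key = (line[21], line[22:26].strip(), line[26].strip())
        resname = line[17:20].strip()
        if (key, resname) != last_key:
            if key in seen_keys and seen_keys[key] != resname:
                raise ParseError(
                    f"duplicate residue key {key} at line {lineno} of {path}: "
                    "fingerprint indexing would be ambiguous"
                )
            seen_keys[key] = resname
            last_key = (key, resname)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # unreadable / malformed
            raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc

    residues: list[ResidueRecord] = []
    hetero: list[ResidueRecord] = []
    seen: set[tuple[str, int, str]] = set()
    model = next(structure.get_models(), None)
    if model is None:
        raise ParseError(f"no model found in {path}")
    for chain in model:
        for res in chain:
            hetfield, resseq, icode = res.id
            atoms = tuple(
                AtomRecord(
                    name=a.get_name(),
                    element=(a.element or "").strip().capitalize(),
                    coords=tuple(float(x) for x in a.coord),
                )
                for a in res
            )
            rec = ResidueRecord(
                chain_id=chain.id,
                number=int(resseq),
                icode=icode.strip(),
                name=res.get_resname().strip(),
                atoms=atoms,
            )
            is_polymer = hetfield == " " or (
                hetfield.startswith("H_") and rec.name in STANDARD_RESIDUES
            )
            if rec.name in WATER_NAMES:
                is_polymer = False
            if is_polymer:
                if rec.key in seen:
                    raise ParseError(
                        f"duplicate residue key {rec.key} in {path}: fingerprint "
                        "indexing would be ambiguous"
                    )
                seen.add(rec.key)
                residues.append(rec)
            else:
                hetero.append(rec)
    if not residues:
        raise ParseError(f"no polymer residues found in {path}")
    return ReceptorStructure(residues=residues, hetero=hetero, source=str(path))


def write_receptor(receptor: ReceptorStructure, path: str | Path) -> None:
    """Write a receptor as minimal PDB ATOM records (file order preserved)."""
    lines = []
    serial = 1
    for res in receptor.residues + receptor.hetero:
        record = "ATOM  " if res in receptor.residues else "HETATM"
        for a in res.atoms:
            x, y, z = a.coords
            lines.append(
                f"{record}{serial:>5} {a.name:<4}{'':1}{res.name:<3} {res.chain_id}"
                f"{res.number:>4}{res.icode or ' ':1}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# molecule reading / writing
# ---------------------------------------------------------------------------

def read_molecules(path: str | Path) -> list[MoleculeRecord]:
    """Read a ``.smi``/``.smiles`` or ``.sdf`` file into MoleculeRecords.

    Invalid entries are skipped with a logged warning; the number skipped is
    available on the returned list via the ``read_molecules.last_skipped``
    attribute.  An empty usable set is an error.
    """
    path = Path(path)
    ext = path.suffix.lower()
    records: list[MoleculeRecord] = []
    skipped = 0
    if ext in {".smi", ".smiles", ".txt"}:
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                skipped += 1
                logger.warning("skipping invalid SMILES on line %d of %s", i, path)
                continue
            records.append(MoleculeRecord(mol, name=name))
    elif ext in {".sdf", ".mol", ".sd"}:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                logger.warning("skipping unreadable SDF block %d of %s", i, path)
                continue
            records.append(MoleculeRecord(mol))
    else:
        raise ParseError(f"unrecognized molecule file extension: {path}")
    if not records:
        raise ParseError(f"no usable molecules in {path} ({skipped} skipped)")
    read_molecules.last_skipped = skipped  # type: ignore[attr-defined]
    return records


read_molecules.last_skipped = 0  # type: ignore[attr-defined]


def write_molecules(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write records to ``.sdf`` (with conformers) or ``.smi``."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".sdf":
        writer = Chem.SDWriter(str(path))
        for rec in records:
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.name)
            for k, v in rec.props.items():
                mol.SetProp(str(k), str(v))
            writer.write(mol)
        writer.close()
    elif ext in {".smi", ".smiles"}:
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f"{rec.smiles} {rec.name}\n")
    else:
        raise ParseError(f"unrecognized output extension: {path}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS: dict[str, object] = {
    "mode": "de_novo",
    "generations": 5,
    "mutants": 8,
    "crossovers": 4,
    "elites": 1,
    "survivors": 4,
    "seed": 0,
    "receptor": "",
    "reference_ligand": "",
    "scorer": "ifp_cs",
    "poses_per_molecule": 3,
    "jitter_sigma": 0.25,
    "max_heavy_atoms": 40,
    "contact_params": {},
    "pharmacophore": {},
    "similarity_thresholds": [0.50, 0.75, 1.00],
}

_MODES = {"de_novo", "lead_opt"}
_SCORERS = {"ifp_cs", "external"}


@dataclass
class RunConfig:
    """Validated configuration for an evolution run (JSON-serialisable)."""

    mode: str = "de_novo"
    generations: int = 5
    mutants: int = 8
    crossovers: int = 4
    elites: int = 1
    survivors: int = 4
    seed: int = 0
    receptor: str = ""
    reference_ligand: str = ""
    scorer: str = "ifp_cs"
    poses_per_molecule: int = 3
    jitter_sigma: float = 0.25
    max_heavy_atoms: int = 40
    contact_params: dict = field(default_factory=dict)
    pharmacophore: dict = field(default_factory=dict)
    similarity_thresholds: list[float] = field(default_factory=lambda: [0.50, 0.75, 1.00])

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"invalid value for key 'mode': {self.mode!r}")
        if self.scorer not in _SCORERS:
            raise ValueError(f"invalid value for key 'scorer': {self.scorer!r}")
        for key in ("generations", "mutants", "crossovers", "elites"):
            if int(getattr(self, key)) < 0:
                raise ValueError(f"invalid value for key {key!r}: must be >= 0")
        if int(self.survivors) < 1:
            raise ValueError("invalid value for key 'survivors': must be >= 1")
        if float(self.jitter_sigma) < 0:
            raise ValueError("invalid value for key 'jitter_sigma': must be >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _CONFIG_DEFAULTS}

    def with_updates(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def load_config(path_or_dict: str | Path | dict) -> RunConfig:
    """Load and validate a JSON run configuration.

    Unknown keys raise a logged warning; invalid values raise ``ValueError``
    naming the offending key.  Absent optional keys take defaults.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        raw = json.loads(Path(path_or_dict).read_text())
        if not isinstance(raw, dict):
            raise ValueError("run configuration must be a JSON object")
    known = {}
    for key, value in raw.items():
        if key not in _CONFIG_DEFAULTS:
            logger.warning("ignoring unknown configuration key %r", key)
            continue
        known[key] = value
    return RunConfig(**known)


def provenance_header(config: RunConfig, version: str) -> dict:
    """JSON provenance block written at the top of every run output."""
    return {"config": config.to_dict(), "seed": config.seed, "version": version}
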
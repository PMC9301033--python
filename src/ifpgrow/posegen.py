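"""Pose providers.

Docking engines are deliberately out of scope: the package defines a small
provider contract (``propose`` a bounded number of posed molecules,
deterministically under a seed) with two implementations — a toy provider
that aligns an embedded conformer onto a reference ligand pose by maximum
common substructure (sufficient for desk-scale testing of the scoring and
evolution machinery), and a file adapter that ingests poses written by an
external engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS, rdMolAlign
from rdkit.Geometry import Point3D

from .chemio import MoleculeRecord, ParseError


class PoseGenerationError(RuntimeError):
    """A pose could not be generated for a molecule."""


@dataclass(frozen=True)
class ProviderCapabilities:
    max_poses: int
    requires_reference: bool


@runtime_checkable
class PoseProvider(Protocol):
    """Contract every pose provider implements."""

    capabilities: ProviderCapabilities

    def propose(
        self, molecule: MoleculeRecord, n: int, seed: int
    ) -> list[MoleculeRecord]:
        ...  # pragma: no cover


def _set_conformer(mol: Chem.Mol, coords: np.ndarray) -> None:
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol.RemoveAllConformers()
    mol.AddConformer(conf, assignId=True)


def _embed(mol: Chem.Mol, seed: int) -> Chem.Mol:
    molh = Chem.AddHs(mol)
    ps = AllChem.ETKDGv3()
    ps.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(molh, ps) != 0:
        raise PoseGenerationError(
            f"3D embedding failed for molecule {Chem.MolToSmiles(mol)!r}"
        )
    return Chem.RemoveHs(molh)


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1]  # descending variance
    # deterministic sign: largest-magnitude component of each axis positive
    for j in range(3):
        k = int(np.argmax(np.abs(axes[:, j])))
        if axes[k, j] < 0:
            axes[:, j] = -axes[:, j]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes


class ToyAlignProvider:
    """Deterministic desk-scale pose provider.

    Pose 1 places the molecule on the reference ligand pose: if the molecule
    has the reference topology its conformer is copied atom-for-atom (so the
    reference molecule reproduces the reference pose exactly); otherwise a
    seeded ETKDG conformer is rigidly superposed on the reference over the
    maximum common substructure, falling back to principal-axis alignment
    when no meaningful MCS exists.  Poses 2..n add seeded Gaussian
    coordinate noise of ``jitter_sigma`` Angstrom.
    """

    def __init__(
        self,
        reference: MoleculeRecord,
        jitter_sigma: float = 0.25,
        max_poses: int = 10,
        mcs_timeout: int = 2,
    ):
        if not reference.has_conformer():
            raise ValueError("reference molecule must carry a conformer")
        self.reference = reference
        self.jitter_sigma = float(jitter_sigma)
        self.mcs_timeout = int(mcs_timeout)
        self.capabilities = ProviderCapabilities(
            max_poses=max_poses, requires_reference=True
        )
        self._ref_noh = Chem.RemoveHs(Chem.Mol(reference.mol))

    def _place(self, molecule: MoleculeRecord, seed: int) -> Chem.Mol:
        mol = Chem.RemoveHs(Chem.Mol(molecule.mol))
        ref = self._ref_noh
        ref_coords = np.asarray(ref.GetConformer().GetPositions())

        # exact-topology short circuit: copy the reference conformer
        if Chem.MolToSmiles(mol) == Chem.MolToSmiles(ref):
            match = mol.GetSubstructMatch(ref)
            if match:
                coords = np.zeros((mol.GetNumAtoms(), 3))
                for ref_idx, mol_idx in enumerate(match):
                    coords[mol_idx] = ref_coords[ref_idx]
                _set_conformer(mol, coords)
                return mol

        mol = _embed(mol, seed)
        mcs = rdFMCS.FindMCS(
            [mol, ref], timeout=self.mcs_timeout, matchValences=False,
            ringMatchesRingOnly=True,
        )
        patt = Chem.MolFromSmarts(mcs.smartsString) if mcs.numAtoms >= 3 else None
        if patt is not None:
            # RDKit's first substructure match is canonical-order deterministic
            m_mol = mol.GetSubstructMatch(patt)
            m_ref = ref.GetSubstructMatch(patt)
            if m_mol and m_ref:
                rdMolAlign.AlignMol(mol, ref, atomMap=list(zip(m_mol, m_ref)))
                return mol
        # fallback: principal-axis alignment
        coords = np.asarray(mol.GetConformer().GetPositions())
        axes_m = _principal_axes(coords)
        axes_r = _principal_axes(ref_coords)
        rot = axes_r @ axes_m.T
        coords = (coords - coords.mean(axis=0)) @ rot.T + ref_coords.mean(axis=0)
        _set_conformer(mol, coords)
        return mol

    def propose(
        self, molecule: MoleculeRecord, n: int, seed: int
    ) -> list[MoleculeRecord]:
        if n < 1:
            raise ValueError("n must be >= 1")
        n = min(n, self.capabilities.max_poses)
        base = self._place(molecule, seed)
        rng = np.random.default_rng(seed)
        poses = []
        base_coords = np.asarray(base.GetConformer().GetPositions())
        for k in range(n):
            mol = Chem.Mol(base)
            if k > 0 and self.jitter_sigma > 0:
                noisy = base_coords + rng.normal(
                    0.0, self.jitter_sigma, base_coords.shape
                )
                _set_conformer(mol, noisy)
            poses.append(
                MoleculeRecord(mol, name=f"{molecule.name or 'mol'}_pose{k + 1}")
            )
        return poses


def read_external_poses(
    path: str | Path, topology: MoleculeRecord | None = None
) -> list[MoleculeRecord]:
    """Parse an external engine's pose file (SDF or PDB) into records.

    ``topology``, when given, is the molecule the engine docked: every pose
    must match its atom count.  Unparseable blocks and mismatches raise with
    the offending block index.
    """
    path = Path(path)
    ext = path.suffix.lower()
    poses: list[MoleculeRecord] = []
    if ext in {".sdf", ".sd", ".mol"}:
        try:
            supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
        except OSError as exc:
            raise ParseError(f"cannot open pose file {path}: {exc}") from exc
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ParseError(f"unparseable pose block {i} in {path}")
            if mol.GetNumConformers() == 0:
                raise ParseError(f"pose block {i} in {path} has no coordinates")
            poses.append(MoleculeRecord(mol))
    elif ext == ".pdb":
        mol = Chem.MolFromPDBFile(str(path), removeHs=True, sanitize=True)
        if mol is None:
            raise ParseError(f"unparseable pose block 0 in {path}")
        poses.append(MoleculeRecord(mol, name=path.stem))
    else:
        raise ParseError(f"unrecognized pose file extension: {path}")
    if not poses:
        raise ParseError(f"no poses found in {path}")
    if topology is not None:
        expected = Chem.RemoveHs(Chem.Mol(topology.mol)).GetNumAtoms()
        for i, pose in enumerate(poses):
            got = Chem.RemoveHs(Chem.Mol(pose.mol)).GetNumAtoms()
            if got != expected:
                raise ParseError(
                    f"pose block {i} in {path}: atom count {got} does not match "
                    f"topology ({expected})"
                )
    return poses
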
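"""Cross-docking benchmark analytics.

Cross-docking docks every ligand of a complex set into every receptor of
the set (under one or more docking protocols) and asks which receptor
conformation best reproduces crystallographic binding modes.  This module
provides the analytics around such an experiment: symmetry-corrected
heavy-atom RMSD in the docked frame, best-pose RMSD matrices, per-receptor
success rates at a threshold (strictly below, default 2 A), consensus
averaging across protocols, and job enumeration.  The docking engines
themselves are external.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import MoleculeRecord

logger = logging.getLogger("ifpgrow")

MAX_AUTOMORPHISMS = 10_000


class TopologyMismatch(ValueError):
    """The two poses do not share a molecular topology."""


def heavy_atom_rmsd(
    a: MoleculeRecord,
    b: MoleculeRecord,
    symmetry: bool = True,
    max_automorphisms: int = MAX_AUTOMORPHISMS,
) -> float:
    """Heavy-atom RMSD between two poses of the same molecule, in Angstrom.

    No re-superposition is performed: poses are compared in the docked
    frame.  With ``symmetry=True`` the RMSD is minimised over the graph
    automorphisms of the heavy-atom topology (so a benzene rotated by 60
    degrees scores 0); the automorphism count is capped, falling back to
    the identity mapping with a warning beyond the cap.
    """
    ma = Chem.RemoveHs(Chem.Mol(a.mol))
    mb = Chem.RemoveHs(Chem.Mol(b.mol))
    if ma.GetNumAtoms() != mb.GetNumAtoms():
        raise TopologyMismatch(
            f"atom counts differ: {ma.GetNumAtoms()} vs {mb.GetNumAtoms()}"
        )
    ca = np.asarray(ma.GetConformer().GetPositions())
    cb = np.asarray(mb.GetConformer().GetPositions())
    matches = ma.GetSubstructMatches(
        mb, uniquify=False, maxMatches=max_automorphisms + 1
    ) if symmetry else ()
    if symmetry and not matches:
        raise TopologyMismatch(
            f"poses are not the same molecule: {Chem.MolToSmiles(ma)} vs "
            f"{Chem.MolToSmiles(mb)}"
        )
    if not symmetry or len(matches) > max_automorphisms:
        if symmetry:
            logger.warning(
                "more than %d automorphisms; falling back to identity mapping",
                max_automorphisms,
            )
        match = ma.GetSubstructMatch(mb)
        if not match:
            raise TopologyMismatch("poses are not the same molecule")
        matches = (match,)
    best = math.inf
    for match in matches:
        # match[j] is the atom of `a` corresponding to atom j of `b`
        diff = ca[list(match)] - cb
        best = min(best, float(np.sqrt((diff * diff).sum(axis=1).mean())))
    return best


def best_pose_rmsd(
    poses: list[MoleculeRecord], reference: MoleculeRecord, **kw
) -> float:
    """Minimum RMSD over a docking run's poses; NaN marks an empty run."""
    if not poses:
        logger.warning("no poses for %s: marking cell missing", reference.name)
        return math.nan
    return min(heavy_atom_rmsd(p, reference, **kw) for p in poses)


@dataclass
class RmsdMatrix:
    """Best-pose RMSD per (ligand, receptor, protocol); NaN = missing cell."""

    ligand_ids: list[str]
    receptor_ids: list[str]
    protocols: list[str]
    values: np.ndarray = field(default=None)  # shape (L, R, P)

    def __post_init__(self) -> None:
        shape = (len(self.ligand_ids), len(self.receptor_ids), len(self.protocols))
        if self.values is None:
            self.values = np.full(shape, np.nan)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != shape:
            raise ValueError(f"values must have shape {shape}")
        finite = self.values[~np.isnan(self.values)]
        if (finite < 0).any():
            raise ValueError("RMSD values must be non-negative")

    def set(self, ligand: str, receptor: str, protocol: str, rmsd: float) -> None:
        i = self.ligand_ids.index(ligand)
        j = self.receptor_ids.index(receptor)
        k = self.protocols.index(protocol)
        self.values[i, j, k] = rmsd

    def to_frame(self, protocol: str) -> pd.DataFrame:
        k = self.protocols.index(protocol)
        return pd.DataFrame(
            self.values[:, :, k], index=self.ligand_ids, columns=self.receptor_ids
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "RmsdMatrix":
        """Build from a long table with columns ligand, receptor, protocol, rmsd."""
        ligands = sorted(df["ligand"].unique())
        receptors = sorted(df["receptor"].unique())
        protocols = sorted(df["protocol"].unique())
        m = cls(ligands, receptors, protocols)
        for row in df.itertuples(index=False):
            m.set(row.ligand, row.receptor, row.protocol, float(row.rmsd))
        return m

    def to_long(self) -> pd.DataFrame:
        rows = [
            {
                "ligand": l, "receptor": r, "protocol": p,
                "rmsd": self.values[i, j, k],
            }
            for i, l in enumerate(self.ligand_ids)
            for j, r in enumerate(self.receptor_ids)
            for k, p in enumerate(self.protocols)
            if not math.isnan(self.values[i, j, k])
        ]
        return pd.DataFrame(rows)


@dataclass
class SuccessReport:
    """Per-receptor success fractions and their cross-protocol consensus."""

    threshold: float
    per_receptor: pd.DataFrame  # index receptor, columns protocols + consensus
    ranking: list[str]          # receptors by descending consensus, ties by id


def success_rate(matrix: RmsdMatrix, threshold: float = 2.0) -> SuccessReport:
    """Fraction of docking runs strictly below the RMSD threshold.

    Per receptor and protocol, the success fraction counts non-missing
    cells with RMSD < threshold (a cell exactly at the threshold fails).
    The consensus is the arithmetic mean of the protocol fractions.
    Receptors with no data in some protocol get an undefined fraction and
    are excluded from the ranking with a warning.
    """
    if not np.isfinite(matrix.values).any():
        raise ValueError("RMSD matrix is empty")
    rows = {}
    for j, receptor in enumerate(matrix.receptor_ids):
        fractions = {}
        for k, protocol in enumerate(matrix.protocols):
            col = matrix.values[:, j, k]
            valid = ~np.isnan(col)
            fractions[protocol] = (
                float((col[valid] < threshold).mean()) if valid.any() else math.nan
            )
        vals = list(fractions.values())
        fractions["consensus"] = (
            float(np.mean(vals)) if not any(math.isnan(v) for v in vals) else math.nan
        )
        rows[receptor] = fractions
    per_receptor = pd.DataFrame(rows).T
    per_receptor.index.name = "receptor"
    undefined = per_receptor.index[per_receptor["consensus"].isna()].tolist()
    for rec in undefined:
        logger.warning("receptor %s has undefined success rate; excluded", rec)
    ranked = per_receptor.drop(index=undefined)
    ranking = sorted(
        ranked.index, key=lambda r: (-ranked.loc[r, "consensus"], r)
    )
    return SuccessReport(threshold=threshold, per_receptor=per_receptor, ranking=ranking)


def job_matrix(
    ligand_ids: list[str], receptor_ids: list[str], protocols: list[str]
) -> list[tuple[str, str, str]]:
    """Full Cartesian product of docking jobs, ligand-major stable order."""
    if not ligand_ids or not receptor_ids or not protocols:
        raise ValueError("all job axes must be non-empty")
    return list(itertools.product(ligand_ids, receptor_ids, protocols))
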
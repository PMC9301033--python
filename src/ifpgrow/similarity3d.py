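"""Gaussian shape and electrostatic similarity (ET_combo-style, 0-2 scale).

Each heavy atom is modelled as a spherical Gaussian whose volume integral
matches its van der Waals hard sphere (amplitude p = 2.7, width
``alpha = pi * (3 p / (4 pi))**(2/3) / R_vdw**2``).  The shape Tanimoto of
two posed molecules is ``V_ab / (V_aa + V_bb - V_ab)`` over first-order
pairwise Gaussian overlaps; the electrostatic Tanimoto weights the same
overlaps by signed partial-charge products and clamps anti-correlated
(negative) values to 0.  ``et_combo`` is their sum, so a self-comparison
scores exactly 2.  Poses are compared in their given frame — no overlay
optimisation is performed — which matches a workflow where generated poses
and reference ligands already share the receptor frame.  This is an openly
declared stand-alone implementation on the familiar 0-2 combo scale; no
numerical agreement with any commercial shape package is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chemio import MoleculeRecord

_P = 2.7
_KAPPA = np.pi * (3.0 * _P / (4.0 * np.pi)) ** (2.0 / 3.0)
_PT = Chem.GetPeriodicTable()


@dataclass(frozen=True)
class ComboScore:
    shape_tanimoto: float
    electrostatic_tanimoto: float
    best_reference: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.shape_tanimoto <= 1.0 + 1e-9:
            raise ValueError("shape tanimoto out of [0, 1]")
        if not 0.0 <= self.electrostatic_tanimoto <= 1.0 + 1e-9:
            raise ValueError("electrostatic tanimoto out of [0, 1]")

    @property
    def et_combo(self) -> float:
        return self.shape_tanimoto + self.electrostatic_tanimoto


def _heavy_gaussians(record: MoleculeRecord):
    """(coords, alphas, heavy-atom indices) of a posed molecule."""
    if not record.has_conformer():
        raise ValueError(f"molecule {record.name!r} has no conformer")
    coords = record.coordinates()
    idx, alphas = [], []
    for atom in record.mol.GetAtoms():
        if atom.GetAtomicNum() <= 1:
            continue
        idx.append(atom.GetIdx())
        r = _PT.GetRvdw(atom.GetAtomicNum())
        alphas.append(_KAPPA / (r * r))
    return coords[idx], np.asarray(alphas), idx


def _overlap_matrix(xa, aa, xb, ab) -> np.ndarray:
    """First-order Gaussian pair overlaps V_ij for two atom sets."""
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    asum = aa[:, None] + ab[None, :]
    return _P * _P * np.exp(-aa[:, None] * ab[None, :] / asum * d2) * (
        np.pi / asum
    ) ** 1.5


def gaussian_overlap_volume(a: MoleculeRecord, b: MoleculeRecord) -> float:
    """Total first-order overlap volume V_ab of two posed molecules."""
    xa, aa, _ = _heavy_gaussians(a)
    xb, ab, _ = _heavy_gaussians(b)
    return float(_overlap_matrix(xa, aa, xb, ab).sum())


def shape_tanimoto(a: MoleculeRecord, b: MoleculeRecord) -> float:
    """Gaussian-volume shape Tanimoto in [0, 1] (1 for identical poses)."""
    vab = gaussian_overlap_volume(a, b)
    vaa = gaussian_overlap_volume(a, a)
    vbb = gaussian_overlap_volume(b, b)
    denom = vaa + vbb - vab
    if denom <= 0:
        return 0.0
    return float(np.clip(vab / denom, 0.0, 1.0))


def electrostatic_tanimoto(a: MoleculeRecord, b: MoleculeRecord) -> float:
    """Charge-weighted Gaussian-overlap Tanimoto, clamped to [0, 1].

    Partial charges are taken from the records (Gasteiger-assigned on
    demand).  Anti-correlated charge distributions give negative raw
    values, reported as 0; two molecules with all-zero charges score 0 by
    convention.
    """
    xa, aa, ia = _heavy_gaussians(a)
    xb, ab, ib = _heavy_gaussians(b)
    qa = a.partial_charges()[ia]
    qb = b.partial_charges()[ib]
    if not qa.any() and not qb.any():
        return 0.0

    def weighted(x1, a1, q1, x2, a2, q2) -> float:
        return float((np.outer(q1, q2) * _overlap_matrix(x1, a1, x2, a2)).sum())

    eab = weighted(xa, aa, qa, xb, ab, qb)
    eaa = weighted(xa, aa, qa, xa, aa, qa)
    ebb = weighted(xb, ab, qb, xb, ab, qb)
    denom = eaa + ebb - eab
    if denom <= 0:
        return 0.0
    return float(np.clip(eab / denom, 0.0, 1.0))


def et_combo(a: MoleculeRecord, b: MoleculeRecord) -> float:
    """Sum of shape and electrostatic Tanimoto, in [0, 2]."""
    return shape_tanimoto(a, b) + electrostatic_tanimoto(a, b)


def best_combo(
    query: MoleculeRecord, references: list[MoleculeRecord]
) -> ComboScore:
    """Best et_combo of a query over a reference set, with the argmax kept."""
    if not references:
        raise ValueError("reference list is empty")
    best: ComboScore | None = None
    for i, ref in enumerate(references):
        score = ComboScore(
            shape_tanimoto=shape_tanimoto(query, ref),
            electrostatic_tanimoto=electrostatic_tanimoto(query, ref),
            best_reference=ref.name or f"ref{i}",
        )
        if best is None or score.et_combo > best.et_combo:
            best = score
    return best
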
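"""Interaction fingerprints and the negative-cosine pose score (IFP_CS).

A pose's contacts are encoded into a bit vector of length ``8 * r`` (r =
number of receptor residues); bit ``8*i + c`` is set when residue ``i``
engages the ligand through channel ``c``.  Two fingerprints A (reference)
and B (query) are compared by

    IFP_CS = -1 * (A . B) / (||A|| ||B||)

so scores run from -1 (identical interaction pattern, maximum coherence)
to 0 (no shared interactions); a genetic algorithm minimising the score is
thereby driven toward reference-like binding modes.  By convention the
similarity involving an all-zero fingerprint is 0, so poses with no
detected interactions rank worst instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .chemio import MoleculeRecord, ReceptorStructure
from .interactions import Contact, ContactParams, N_CHANNELS, detect_contacts


@dataclass(frozen=True)
class InteractionFingerprint:
    """Dense bit vector of length ``8 * r`` with fixed channel order."""

    bits: np.ndarray
    n_residues: int
    channel_order: str = "ifp8-v1"
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        bits = np.ascontiguousarray(np.asarray(self.bits, dtype=np.uint8))
        if bits.ndim != 1 or bits.size != N_CHANNELS * self.n_residues:
            raise ValueError(
                f"fingerprint length must be {N_CHANNELS} * r = "
                f"{N_CHANNELS * self.n_residues}, got {bits.size}"
            )
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def on_bits(self) -> list[int]:
        """Sparse form: sorted indices of set bits."""
        return np.flatnonzero(self.bits).tolist()

    def to_bitstring(self) -> str:
        return "".join(map(str, self.bits.tolist()))

    @classmethod
    def from_on_bits(
        cls, on_bits, n_residues: int, **kw
    ) -> "InteractionFingerprint":
        bits = np.zeros(N_CHANNELS * n_residues, dtype=np.uint8)
        bits[list(on_bits)] = 1
        return cls(bits, n_residues, **kw)


def encode(contacts: list[Contact], n_residues: int, **provenance) -> InteractionFingerprint:
    """Encode contacts into a fingerprint; bit ``8*i + c`` per (i, c) contact."""
    bits = np.zeros(N_CHANNELS * n_residues, dtype=np.uint8)
    for c in contacts:
        if c.residue_index >= n_residues:
            raise ValueError(
                f"contact residue index {c.residue_index} out of range "
                f"(r = {n_residues})"
            )
        bits[N_CHANNELS * c.residue_index + c.channel] = 1
    return InteractionFingerprint(bits, n_residues, provenance=dict(provenance))


def _as_vector(fp) -> np.ndarray:
    if isinstance(fp, InteractionFingerprint):
        return fp.bits.astype(float)
    return np.asarray(fp, dtype=float).ravel()


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two equal-length fingerprints, in [0, 1].

    All-zero vectors have similarity 0 with everything (by convention —
    a pose with no detected interactions must still be rankable).
    """
    va, vb = _as_vector(a), _as_vector(b)
    if va.size != vb.size:
        raise ValueError(f"fingerprint length mismatch: {va.size} vs {vb.size}")
    na2, nb2 = float(np.dot(va, va)), float(np.dot(vb, vb))
    if na2 == 0.0 or nb2 == 0.0:
        return 0.0
    # single sqrt keeps the self-comparison exactly 1 for bit vectors
    return float(np.dot(va, vb) / np.sqrt(na2 * nb2))


def ifp_cs(reference, query) -> float:
    """The fingerprint score: negative cosine similarity, in [-1, 0]."""
    return -1.0 * cosine_similarity(reference, query)


def score_pose(
    receptor: ReceptorStructure,
    pose: MoleculeRecord,
    reference_fp: InteractionFingerprint,
    params: ContactParams | None = None,
) -> float:
    """Score one pose against a precomputed reference fingerprint."""
    if receptor.n_residues != reference_fp.n_residues:
        raise ValueError(
            f"receptor has r = {receptor.n_residues} residues but the reference "
            f"fingerprint was built with r = {reference_fp.n_residues}"
        )
    query = encode(detect_contacts(receptor, pose, params), receptor.n_residues)
    return ifp_cs(reference_fp, query)


class InteractionFingerprinter(TransformerMixin, BaseEstimator):
    """Transformer mapping posed molecules to fingerprint bit rows.

    ``fit`` binds a receptor (fixing the residue count r); ``transform``
    turns a list of posed :class:`MoleculeRecord` into an ``(n, 8*r)``
    uint8 array, one fingerprint per pose.
    """

    def __init__(self, contact_params: ContactParams | None = None):
        self.contact_params = contact_params

    def fit(self, receptor: ReceptorStructure, y=None) -> "InteractionFingerprinter":
        if receptor.n_residues < 1:
            raise ValueError("receptor must contain at least one residue")
        self.receptor_ = receptor
        self.n_residues_ = receptor.n_residues
        return self

    def fingerprint(self, pose: MoleculeRecord) -> InteractionFingerprint:
        contacts = detect_contacts(self.receptor_, pose, self.contact_params)
        return encode(contacts, self.n_residues_, pose=pose.name)

    def transform(self, poses) -> np.ndarray:
        if not hasattr(self, "receptor_"):
            raise ValueError("InteractionFingerprinter is not fitted; call fit first")
        return np.vstack([self.fingerprint(p).bits for p in poses])


class IFPScorer(BaseEstimator):
    """Pose rescorer based on interaction-fingerprint cosine similarity.

    ``fit`` takes the reference complex (receptor + crystallographic ligand
    pose), computes the reference fingerprint once and caches it; ``predict``
    returns one IFP_CS score in [-1, 0] per query pose.  Query poses must be
    placed in the same coordinate frame, against a receptor of the same
    residue count.
    """

    def __init__(self, contact_params: ContactParams | None = None):
        self.contact_params = contact_params

    def fit(
        self, receptor: ReceptorStructure, reference_pose: MoleculeRecord
    ) -> "IFPScorer":
        fper = InteractionFingerprinter(self.contact_params).fit(receptor)
        self.receptor_ = receptor
        self.fingerprinter_ = fper
        self.reference_fp_ = fper.fingerprint(reference_pose)
        self.n_residues_ = receptor.n_residues
        return self

    def score_pose(self, pose: MoleculeRecord) -> float:
        if not hasattr(self, "reference_fp_"):
            raise ValueError("IFPScorer is not fitted; call fit first")
        return ifp_cs(self.reference_fp_, self.fingerprinter_.fingerprint(pose))

    def predict(self, poses) -> np.ndarray:
        return np.array([self.score_pose(p) for p in poses], dtype=float)

    def score_molecule(self, poses) -> float:
        """Best (most negative) score over a molecule's poses."""
        if not len(poses):
            raise ValueError("no poses to score")
        return float(self.predict(poses).min())
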
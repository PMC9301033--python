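"""Generational fragment-growing loop (mutation, crossover, elitist selection).

The loop mirrors the grow/merge semantics of genetic-algorithm de novo
design: each generation is produced from the previous one's survivors by

* **mutation** — attaching one library fragment to a hydrogen-bearing
  heavy atom of a parent through a single bond (growing), and
* **crossover** — recombining BRICS fragments of two parents at compatible
  link points (merging),

followed by pose generation, scoring (most-negative-is-best), and
promotion of the top ``survivors``.  ``elites`` members are carried over
unchanged, which makes the per-generation best score non-worsening.
Operators return ``None`` as a skip signal when no chemistry is possible;
the caller draws another parent.  Everything is deterministic under the
run seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .chemio import MoleculeRecord, RunConfig, write_molecules
from .posegen import PoseGenerationError, PoseProvider

logger = logging.getLogger("ifpgrow")

LINEAGES = ("seed", "mutant", "crossover", "elite")


@dataclass
class GenerationMember:
    record: MoleculeRecord
    pose: MoleculeRecord | None
    score: float
    lineage: str
    parents: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        return self.record.name

    @property
    def smiles(self) -> str:
        return self.record.smiles


@dataclass
class GenerationRecord:
    """One scored population; index 0 holds the seed molecules."""

    index: int
    members: list[GenerationMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.members]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate member names in generation {self.index}")

    def best(self) -> GenerationMember:
        return min(self.members, key=lambda m: (m.score, m.smiles))

    def scores(self) -> np.ndarray:
        return np.array([m.score for m in self.members])


@dataclass(frozen=True)
class EvolutionParams:
    """Per-run genetic-algorithm knobs (usually carried inside RunConfig)."""

    generations: int = 5
    mutants: int = 8
    crossovers: int = 4
    elites: int = 1
    survivors: int = 4
    max_heavy_atoms: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 0 or self.survivors < 1:
            raise ValueError("generations must be >= 0 and survivors >= 1")


# ---------------------------------------------------------------------------
# chemistry operators
# ---------------------------------------------------------------------------

_ATTACHABLE = {"C", "N"}


def _attachment_points(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() in _ATTACHABLE and a.GetTotalNumHs() >= 1
    ]


def attach_fragment(
    parent: Chem.Mol, fragment: Chem.Mol, parent_idx: int, frag_idx: int
) -> Chem.Mol | None:
    """Join two molecules by a single bond between the given atoms.

    Both atoms must bear at least one hydrogen (consumed by the new bond).
    Returns the sanitized child or ``None`` if the valences do not allow it.
    """
    parent = Chem.RemoveHs(parent)
    fragment = Chem.RemoveHs(fragment)
    if parent.GetAtomWithIdx(parent_idx).GetTotalNumHs() < 1:
        return None
    if fragment.GetAtomWithIdx(frag_idx).GetTotalNumHs() < 1:
        return None
    combined = Chem.RWMol(Chem.CombineMols(parent, fragment))
    combined.AddBond(
        parent_idx, parent.GetNumAtoms() + frag_idx, Chem.BondType.SINGLE
    )
    child = combined.GetMol()
    try:
        Chem.SanitizeMol(child)
    except Exception:
        return None
    return child


def mutate(
    parent: MoleculeRecord,
    fragment_library: list[MoleculeRecord],
    rng: np.random.Generator,
    max_heavy_atoms: int | None = None,
) -> MoleculeRecord | None:
    """Grow a parent by one seeded-random single-bond fragment attachment.

    Returns ``None`` (skip signal) when the parent is at the heavy-atom cap
    or offers no hydrogen-bearing attachment point.
    """
    if not fragment_library:
        raise ValueError("fragment library is empty")
    pmol = Chem.RemoveHs(Chem.Mol(parent.mol))
    if max_heavy_atoms is not None and pmol.GetNumHeavyAtoms() >= max_heavy_atoms:
        return None
    p_sites = _attachment_points(pmol)
    if not p_sites:
        return None
    frag = fragment_library[int(rng.integers(len(fragment_library)))]
    fmol = Chem.RemoveHs(Chem.Mol(frag.mol))
    f_sites = _attachment_points(fmol)
    if not f_sites:
        return None
    pi = p_sites[int(rng.integers(len(p_sites)))]
    fi = f_sites[int(rng.integers(len(f_sites)))]
    child = attach_fragment(pmol, fmol, pi, fi)
    if child is None or Chem.MolToSmiles(child) == parent.smiles:
        return None
    return MoleculeRecord(child, name=f"{parent.name}*{frag.name}")


def _brics_fragments(mol: Chem.Mol) -> list[Chem.Mol]:
    frags = []
    for smi in sorted(BRICS.BRICSDecompose(mol)):
        m = Chem.MolFromSmiles(smi)
        if m is not None:
            frags.append(m)
    return frags


def _cap_dummies(mol: Chem.Mol) -> Chem.Mol | None:
    rw = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def crossover(
    a: MoleculeRecord, b: MoleculeRecord, rng: np.random.Generator
) -> MoleculeRecord | None:
    """Recombine one BRICS fragment of each parent at a compatible junction.

    Parents must each decompose into at least two BRICS fragments; if no
    fragment pair has compatible link chemistry, returns ``None``.
    Duplicates of a parent are possible (the caller flags them).
    """
    frags_a = _brics_fragments(Chem.RemoveHs(Chem.Mol(a.mol)))
    frags_b = _brics_fragments(Chem.RemoveHs(Chem.Mol(b.mol)))
    if len(frags_a) < 2 or len(frags_b) < 2:
        return None
    pairs = [(i, j) for i in range(len(frags_a)) for j in range(len(frags_b))]
    order = rng.permutation(len(pairs))
    for k in order:
        i, j = pairs[int(k)]
        try:
            products = BRICS.BRICSBuild(
                [Chem.Mol(frags_a[i]), Chem.Mol(frags_b[j])],
                scrambleReagents=False,
                maxDepth=2,
            )
            product = next(products, None)
        except Exception:
            product = None
        if product is None:
            continue
        product.UpdatePropertyCache(strict=False)
        product = _cap_dummies(product)
        if product is None:
            continue
        return MoleculeRecord(product, name=f"{a.name}x{b.name}")
    return None


# ---------------------------------------------------------------------------
# selection and the main loop
# ---------------------------------------------------------------------------

def select(
    members: list[GenerationMember], k: int
) -> list[GenerationMember]:
    """The ``k`` most-negative-scoring members; ties broken by SMILES order."""
    if k > len(members):
        raise ValueError(f"cannot select {k} from {len(members)} members")
    return sorted(members, key=lambda m: (m.score, m.smiles))[:k]


def _score_member(
    record: MoleculeRecord,
    provider: PoseProvider,
    scorer,
    n_poses: int,
    seed: int,
    lineage: str,
    parents: tuple[str, ...],
) -> GenerationMember | None:
    try:
        poses = provider.propose(record, n=n_poses, seed=seed)
    except PoseGenerationError as exc:
        logger.warning("dropping %s: %s", record.name, exc)
        return None
    if not poses:
        logger.warning("dropping %s: provider returned no poses", record.name)
        return None
    scores = [scorer.score_pose(p) for p in poses]
    best = int(np.argmin(scores))
    return GenerationMember(
        record=record,
        pose=poses[best],
        score=float(scores[best]),
        lineage=lineage,
        parents=parents,
    )


def run_evolution(
    config: RunConfig,
    seeds: list[MoleculeRecord],
    provider: PoseProvider,
    scorer,
    fragment_library: list[MoleculeRecord],
) -> list[GenerationRecord]:
    """Run the full generational loop.

    Returns ``generations + 1`` records (index 0 is the scored seed
    population).  Individual provider/scorer failures drop the member with
    a logged warning; the run fails only if a generation ends up empty.
    Terminates early when an entire generation yields only skip signals.
    """
    if not seeds:
        raise ValueError("seed population is empty")
    rng = np.random.default_rng(config.seed)

    def draw_seed() -> int:
        return int(rng.integers(2**31 - 1))

    members: list[GenerationMember] = []
    seen: set[str] = set()
    for i, rec in enumerate(seeds):
        rec = rec.copy()
        rec.name = rec.name or f"seed{i}"
        if rec.smiles in seen:
            logger.info("duplicate seed %s collapsed", rec.name)
            continue
        seen.add(rec.smiles)
        m = _score_member(
            rec, provider, scorer, config.poses_per_molecule, draw_seed(),
            "seed", (),
        )
        if m is not None:
            members.append(m)
    if not members:
        raise RuntimeError("no seed molecule could be posed and scored")
    records = [GenerationRecord(0, members)]

    for g in range(1, config.generations + 1):
        prev = records[-1].members
        breeders = select(prev, min(config.survivors, len(prev)))
        elites = select(prev, min(config.elites, len(prev)))
        gen_members: list[GenerationMember] = []
        seen_smiles: set[str] = set()
        for e in elites:
            gen_members.append(
                GenerationMember(
                    record=e.record, pose=e.pose, score=e.score,
                    lineage="elite", parents=(e.name,),
                )
            )
            seen_smiles.add(e.smiles)
        n_children = 0

        def admit(child, lineage, parents, tag):
            nonlocal n_children
            if child is None:
                return
            if child.smiles in seen_smiles:
                logger.info("duplicate child %s collapsed", child.name)
                return
            child.name = tag
            m = _score_member(
                child, provider, scorer, config.poses_per_molecule, draw_seed(),
                lineage, parents,
            )
            if m is not None:
                seen_smiles.add(m.smiles)
                gen_members.append(m)
                n_children += 1

        for j in range(config.mutants):
            parent = breeders[int(rng.integers(len(breeders)))]
            child = mutate(
                parent.record, fragment_library, rng,
                max_heavy_atoms=config.max_heavy_atoms,
            )
            admit(child, "mutant", (parent.name,), f"g{g}_m{j}")
        for j in range(config.crossovers):
            pa = breeders[int(rng.integers(len(breeders)))]
            pb = breeders[int(rng.integers(len(breeders)))]
            child = crossover(pa.record, pb.record, rng)
            admit(child, "crossover", (pa.name, pb.name), f"g{g}_c{j}")

        if n_children == 0 and (config.mutants or config.crossovers):
            logger.info("generation %d produced only skip signals; stopping", g)
            break
        if not gen_members:
            raise RuntimeError(f"generation {g} is empty")
        records.append(GenerationRecord(g, gen_members))
    return records


# ---------------------------------------------------------------------------
# run artifacts
# ---------------------------------------------------------------------------

def generations_to_rows(records: list[GenerationRecord]) -> list[dict]:
    rows = []
    for rec in records:
        for m in rec.members:
            rows.append(
                {
                    "generation": rec.index,
                    "name": m.name,
                    "smiles": m.smiles,
                    "score": None if math.isnan(m.score) else round(m.score, 6),
                    "lineage": m.lineage,
                    "parents": "+".join(m.parents),
                }
            )
    return rows


def export_generations(
    records: list[GenerationRecord], out_dir: str | Path
) -> None:
    """Write one SDF (posed members) and one CSV row set per generation."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(generations_to_rows(records)).to_csv(
        out_dir / "generations.csv", index=False
    )
    for rec in records:
        posed = [m.pose for m in rec.members if m.pose is not None]
        if posed:
            write_molecules(posed, out_dir / f"generation_{rec.index}.sdf")
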
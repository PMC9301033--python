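"""Shared fixtures: synthetic complexes, embedded molecules, fragment sets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from rdkit import Chem
from rdkit.Chem import AllChem

from ifpgrow import MoleculeRecord
from ifpgrow.posegen import _set_conformer
from ifpgrow.synthetic_fixtures import (
    FixtureSpec,
    make_fragment_library,
    make_kinase_site,
    make_toy_complex,
)


def embed(smiles: str, name: str = "", seed: int = 1) -> MoleculeRecord:
    """A MoleculeRecord with a seeded ETKDG conformer (hydrogens removed)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    ps = AllChem.ETKDGv3()
    ps.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, ps) == 0
    return MoleculeRecord(Chem.RemoveHs(mol), name=name or smiles)


def translate(record: MoleculeRecord, shift) -> MoleculeRecord:
    out = record.copy()
    _set_conformer(out.mol, record.coordinates() + np.asarray(shift, dtype=float))
    return out


def ideal_benzene(name: str = "benzene") -> MoleculeRecord:
    """Benzene with an exact regular-hexagon conformer in the xy plane."""
    mol = Chem.MolFromSmiles("c1ccccc1")
    angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    coords = np.stack(
        [1.39 * np.cos(angles), 1.39 * np.sin(angles), np.zeros(6)], axis=1
    )
    _set_conformer(mol, coords)
    return MoleculeRecord(mol, name=name)


@pytest.fixture(scope="session")
def all_channel_complex():
    return make_toy_complex(FixtureSpec(channels=(0, 1, 2, 3, 4, 5, 6, 7)))


@pytest.fixture(scope="session")
def kinase_site():
    return make_kinase_site(seed=3)


@pytest.fixture(scope="session")
def fragment_library():
    return make_fragment_library(20, seed=1)


@pytest.fixture(scope="session")
def ga_seeds():
    return [
        MoleculeRecord.from_smiles(s, n)
        for s, n in [
            ("Oc1ccccc1", "phenol"),
            ("COc1ccccc1", "anisole"),
            ("Cc1ccccc1", "toluene"),
            ("c1ccccc1", "benzene"),
        ]
    ]
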
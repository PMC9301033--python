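"""Cross-docking analytics: RMSD, success rates, job enumeration."""

import math

import numpy as np
import pandas as pd
import pytest

from ifpgrow import (
    RmsdMatrix,
    best_pose_rmsd,
    heavy_atom_rmsd,
    job_matrix,
    success_rate,
)
from ifpgrow.crossdock import TopologyMismatch
from ifpgrow.posegen import _set_conformer

from conftest import embed, ideal_benzene, translate


def rotated_benzene(angle_deg: float):
    rec = ideal_benzene()
    theta = np.radians(angle_deg)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    out = rec.copy()
    _set_conformer(out.mol, rec.coordinates() @ rot.T)
    return rec, out


class TestHeavyAtomRmsd:
    def test_identical_poses_score_zero(self):
        mol = embed("CCO")
        assert heavy_atom_rmsd(mol, mol) == 0.0

    def test_uniform_translation_equals_the_shift(self):
        mol = embed("CCO")
        assert heavy_atom_rmsd(mol, translate(mol, (3.0, 0, 0))) == pytest.approx(3.0)

    def test_benzene_sixty_degree_rotation_is_symmetry_equivalent(self):
        ref, rot = rotated_benzene(60.0)
        assert heavy_atom_rmsd(ref, rot) == pytest.approx(0.0, abs=1e-9)
        assert heavy_atom_rmsd(ref, rot, symmetry=False) > 1.0

    def test_benzene_matches_brute_force_automorphism_oracle(self):
        # oracle: the hexagon's 12 automorphisms are the 6 rotations and 6
        # reflections of the cycle; minimise RMSD over them by hand
        ref, rot = rotated_benzene(37.0)
        ca, cb = ref.coordinates(), rot.coordinates()
        perms = []
        for shift in range(6):
            perms.append([(i + shift) % 6 for i in range(6)])
            perms.append([(shift - i) % 6 for i in range(6)])
        oracle = min(
            float(np.sqrt(((ca[p] - cb) ** 2).sum(axis=1).mean())) for p in perms
        )
        assert heavy_atom_rmsd(ref, rot) == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_correction_never_exceeds_identity_mapping(self):
        rng = np.random.default_rng(5)
        for smiles in ("c1ccccc1", "CC(C)C", "O=C(O)c1ccccc1"):
            mol = embed(smiles)
            noisy = mol.copy()
            _set_conformer(
                noisy.mol, mol.coordinates() + rng.normal(0, 1.0, mol.coordinates().shape)
            )
            assert heavy_atom_rmsd(mol, noisy) <= heavy_atom_rmsd(
                mol, noisy, symmetry=False
            ) + 1e-12

    def test_rigid_motion_applied_to_both_poses_is_invariant(self):
        mol = embed("CCO")
        moved = translate(mol, (2.0, 0, 0))
        d = heavy_atom_rmsd(mol, moved)
        shift = (9.0, -4.0, 1.0)
        assert heavy_atom_rmsd(
            translate(mol, shift), translate(moved, shift)
        ) == pytest.approx(d, abs=1e-12)

    def test_topology_mismatch_rejected(self):
        with pytest.raises(TopologyMismatch):
            heavy_atom_rmsd(embed("CCO"), embed("CCC"))


class TestBestPoseRmsd:
    def test_minimum_over_poses(self):
        ref = embed("CCO")
        poses = [translate(ref, (d, 0, 0)) for d in (0.8, 2.4, 5.1)]
        assert best_pose_rmsd(poses, ref) == pytest.approx(0.8)

    def test_single_pose(self):
        ref = embed("CCO")
        assert best_pose_rmsd([translate(ref, (1.5, 0, 0))], ref) == pytest.approx(1.5)

    def test_empty_run_marks_missing_cell(self):
        assert math.isnan(best_pose_rmsd([], embed("CCO")))


class TestSuccessRate:
    def matrix_from(self, rows):
        return RmsdMatrix.from_long(
            pd.DataFrame(rows, columns=["ligand", "receptor", "protocol", "rmsd"])
        )

    def test_two_of_four_below_threshold_is_fifty_percent(self):
        rows = [(f"l{i}", "R", "gold", v) for i, v in enumerate([1.0, 2.5, 0.5, 3.0])]
        report = success_rate(self.matrix_from(rows))
        assert report.per_receptor.loc["R", "gold"] == pytest.approx(0.5)

    def test_all_below_threshold_is_full_success(self):
        rows = [(f"l{i}", "R", "gold", 0.5) for i in range(4)]
        report = success_rate(self.matrix_from(rows))
        assert report.per_receptor.loc["R", "gold"] == 1.0

    def test_boundary_cell_at_threshold_fails(self):
        rows = [("l0", "R", "gold", 2.0), ("l1", "R", "gold", 1.9)]
        report = success_rate(self.matrix_from(rows), threshold=2.0)
        assert report.per_receptor.loc["R", "gold"] == pytest.approx(0.5)

    def test_consensus_is_mean_of_protocol_fractions(self):
        rows = (
            [(f"l{i}", "R", "gold", v) for i, v in enumerate([1.0, 1.0, 3.0, 3.0, 3.0])]
            + [(f"l{i}", "R", "plants", v) for i, v in enumerate([1.0, 1.0, 1.0, 3.0, 3.0])]
        )
        report = success_rate(self.matrix_from(rows))
        assert report.per_receptor.loc["R", "consensus"] == pytest.approx(0.5)

    def test_success_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"l{i}", "R", "gold", float(v))
            for i, v in enumerate(rng.uniform(0, 5, 40))
        ]
        m = self.matrix_from(rows)
        fracs = [
            success_rate(m, threshold=t).per_receptor.loc["R", "gold"]
            for t in (0.5, 1.0, 2.0, 3.0, 5.0)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_ranking_ties_broken_by_receptor_id(self):
        rows = [
            ("l0", "B", "gold", 1.0), ("l0", "A", "gold", 1.0),
            ("l0", "C", "gold", 3.0),
        ]
        report = success_rate(self.matrix_from(rows))
        assert report.ranking == ["A", "B", "C"]

    def test_long_form_round_trip(self):
        rows = [("l0", "A", "gold", 1.25), ("l1", "A", "gold", 2.5)]
        m = self.matrix_from(rows)
        back = RmsdMatrix.from_long(m.to_long())
        np.testing.assert_allclose(back.values, m.values)


class TestJobMatrix:
    def test_paper_scale_product(self):
        ligs = [f"l{i}" for i in range(24)]
        recs = [f"r{i}" for i in range(24)]
        jobs = job_matrix(ligs, recs, ["gold", "plants"])
        assert len(jobs) == 1152

    def test_single_cell(self):
        assert job_matrix(["l"], ["r"], ["p"]) == [("l", "r", "p")]

    def test_ligand_major_order(self):
        jobs = job_matrix(["l0", "l1"], ["r0", "r1", "r2"], ["p"])
        assert len(jobs) == 6
        assert jobs[0][0] == jobs[1][0] == jobs[2][0] == "l0"

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            job_matrix([], ["r"], ["p"])
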
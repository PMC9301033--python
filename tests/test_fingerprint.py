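"""Fingerprint encoding and the negative-cosine score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics.pairwise import cosine_similarity as sk_cosine

from ifpgrow import (
    IFPScorer,
    InteractionFingerprint,
    InteractionFingerprinter,
    cosine_similarity,
    detect_contacts,
    encode,
    ifp_cs,
    score_pose,
)
from ifpgrow.interactions import Contact
from ifpgrow.synthetic_fixtures import FixtureSpec, make_toy_complex

from conftest import translate


class TestEncode:
    def test_no_contacts_gives_all_zero_vector_of_length_8r(self):
        fp = encode([], n_residues=5)
        assert len(fp) == 40
        assert fp.popcount == 0

    def test_single_contact_sets_exactly_bit_8i_plus_c(self):
        contact = Contact(1, 3, ("N",), (0,), 2.9)
        fp = encode([contact], n_residues=2)
        assert fp.on_bits() == [11]

    def test_popcount_equals_distinct_planted_pairs(self, all_channel_complex):
        receptor, ligand, truth = all_channel_complex
        fp = encode(detect_contacts(receptor, ligand), receptor.n_residues)
        assert fp.popcount == len(set(truth))

    def test_out_of_range_residue_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            encode([Contact(5, 0, (), (), 1.0)], n_residues=3)

    def test_sparse_and_dense_forms_agree(self, all_channel_complex):
        receptor, ligand, _ = all_channel_complex
        fp = encode(detect_contacts(receptor, ligand), receptor.n_residues)
        again = InteractionFingerprint.from_on_bits(fp.on_bits(), fp.n_residues)
        assert np.array_equal(fp.bits, again.bits)


class TestCosine:
    def test_hand_computed_pair(self):
        a = InteractionFingerprint(np.array([1, 1, 0, 0, 0, 0, 0, 0]), 1)
        b = InteractionFingerprint(np.array([1, 0, 1, 0, 0, 0, 0, 0]), 1)
        assert cosine_similarity(a, b) == pytest.approx(0.5)
        assert ifp_cs(a, b) == pytest.approx(-0.5)

    def test_identity_and_orthogonality(self):
        a = InteractionFingerprint.from_on_bits([0, 5], 1)
        b = InteractionFingerprint.from_on_bits([1, 2], 1)
        assert ifp_cs(a, a) == -1.0
        assert ifp_cs(a, b) == 0.0

    def test_zero_vector_convention(self):
        zero = InteractionFingerprint(np.zeros(8, dtype=np.uint8), 1)
        some = InteractionFingerprint.from_on_bits([3], 1)
        assert cosine_similarity(zero, some) == 0.0
        assert cosine_similarity(zero, zero) == 0.0

    def test_length_mismatch_rejected(self):
        a = InteractionFingerprint(np.zeros(8, dtype=np.uint8), 1)
        b = InteractionFingerprint(np.zeros(16, dtype=np.uint8), 2)
        with pytest.raises(ValueError, match="mismatch"):
            cosine_similarity(a, b)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**24 - 1), st.integers(0, 2**24 - 1))
    def test_agrees_with_sklearn_on_nonzero_vectors(self, x, y):
        a = np.array([(x >> i) & 1 for i in range(24)], dtype=np.uint8)
        b = np.array([(y >> i) & 1 for i in range(24)], dtype=np.uint8)
        if not a.any() or not b.any():
            return
        expected = float(sk_cosine(a.reshape(1, -1), b.reshape(1, -1))[0, 0])
        fa = InteractionFingerprint(a, 3)
        fb = InteractionFingerprint(b, 3)
        assert cosine_similarity(fa, fb) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(1, 2**16 - 1), st.integers(1, 2**16 - 1))
    def test_score_bounds_and_self_score(self, x, y):
        a = InteractionFingerprint(
            np.array([(x >> i) & 1 for i in range(16)], dtype=np.uint8), 2
        )
        b = InteractionFingerprint(
            np.array([(y >> i) & 1 for i in range(16)], dtype=np.uint8), 2
        )
        s = ifp_cs(a, b)
        assert -1.0 <= s <= 0.0
        assert ifp_cs(a, a) == -1.0
        assert ifp_cs(a, b) == ifp_cs(b, a)

    def test_joint_residue_permutation_leaves_score_unchanged(self):
        rng = np.random.default_rng(0)
        bits_a = rng.integers(0, 2, 40).astype(np.uint8)
        bits_b = rng.integers(0, 2, 40).astype(np.uint8)
        perm = rng.permutation(5)
        pa = bits_a.reshape(5, 8)[perm].ravel()
        pb = bits_b.reshape(5, 8)[perm].ravel()
        assert ifp_cs(
            InteractionFingerprint(pa, 5), InteractionFingerprint(pb, 5)
        ) == pytest.approx(
            ifp_cs(InteractionFingerprint(bits_a, 5), InteractionFingerprint(bits_b, 5))
        )


class TestScorePose:
    def test_reference_scores_minus_one_against_its_own_complex(self, kinase_site):
        receptor, reference, _ = kinase_site
        scorer = IFPScorer().fit(receptor, reference)
        assert scorer.score_pose(reference) == -1.0

    def test_displaced_pose_scores_zero(self, kinase_site):
        receptor, reference, _ = kinase_site
        scorer = IFPScorer().fit(receptor, reference)
        assert scorer.score_pose(translate(reference, (50, 0, 0))) == 0.0

    def test_jittered_reference_stays_in_range(self, kinase_site):
        receptor, reference, _ = kinase_site
        rng = np.random.default_rng(17)
        noisy = translate(reference, 0.0)
        from ifpgrow.posegen import _set_conformer

        _set_conformer(
            noisy.mol, reference.coordinates() + rng.normal(0, 0.1, (reference.mol.GetNumAtoms(), 3))
        )
        scorer = IFPScorer().fit(receptor, reference)
        s = scorer.score_pose(noisy)
        assert -1.0 <= s <= 0.0
        # regression baseline: at sigma = 0.1 A all four contacts survive
        assert s == pytest.approx(-1.0)

    def test_residue_count_mismatch_rejected(self, kinase_site, all_channel_complex):
        receptor, reference, _ = kinase_site
        other_receptor, _, _ = all_channel_complex
        scorer = IFPScorer().fit(receptor, reference)
        with pytest.raises(ValueError, match="r ="):
            score_pose(other_receptor, reference, scorer.reference_fp_)

    def test_transformer_emits_one_row_per_pose(self, kinase_site):
        receptor, reference, _ = kinase_site
        fper = InteractionFingerprinter().fit(receptor)
        X = fper.transform([reference, translate(reference, (50, 0, 0))])
        assert X.shape == (2, 8 * receptor.n_residues)
        assert X[0].sum() > 0 and X[1].sum() == 0
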
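"""Fingerprint construction: sign rule, key means, dense layout."""

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from padifwf import padif
from padifwf.dock_io import PoseRecord, ProteinAtom
from padifwf.errors import EmptyInputError, LayoutError, VocabularyError
from padifwf.vocab import (
    DEFAULT_ATOM_CLASSES,
    DEFAULT_LAYOUT,
    INTERACTION_TERMS,
    PadifLayout,
    STANDARD_RESIDUES,
)

from conftest import make_pose


class TestSignRule:
    def test_first_three_terms_inverted(self):
        pose = make_pose(contributions={1: np.array([-2.5, 1.0, -0.5, 1.3, 0, 0, 0, 0.2])})
        raw = padif.compute_raw_padif(pose)
        npt.assert_allclose(raw.entries[1], [2.5, -1.0, 0.5, 1.3, 0, 0, 0, 0.2])

    def test_all_zero_vector_retained(self):
        raw = padif.compute_raw_padif(make_pose(contributions={1: np.zeros(8)}))
        npt.assert_array_equal(raw.entries[1], np.zeros(8))

    def test_empty_contribution_map(self):
        with pytest.raises(EmptyInputError):
            padif.compute_raw_padif(make_pose(contributions={}))

    @given(arrays(float, 8, elements=st.floats(-100, 100, allow_nan=False)))
    def test_sign_standardization_is_an_involution(self, vec):
        once = padif.compute_raw_padif(make_pose(contributions={1: vec}))
        twice = padif.compute_raw_padif(
            make_pose(contributions={1: once.entries[1]})
        )
        npt.assert_allclose(twice.entries[1], vec)


class TestStandardize:
    def test_mean_over_matching_atoms(self, tiny_protein):
        pose = make_pose(
            contributions={
                1: np.array([-2.0, 0, 0, 0, 0, 0, 0, 0]),
                2: np.array([-4.0, 0, 0, 0, 0, 0, 0, 0]),
            }
        )
        std = padif.standardize(padif.compute_raw_padif(pose), tiny_protein)
        assert std.keys[("GLU", "ChemScore.PLP.Hbond", "DONOR")] == pytest.approx(3.0)

    def test_single_atom_key_equals_its_value(self, tiny_protein):
        pose = make_pose(contributions={3: np.array([0, 0, 0, 0, 0, 0, 1.3, 0])})
        std = padif.standardize(padif.compute_raw_padif(pose), tiny_protein)
        assert std.keys[("ALA", "PLP.S(nonpolar)", "NONPOLAR")] == pytest.approx(1.3)

    def test_full_site_occupies_800_keys(self):
        protein, pose = _full_coverage_pose()
        std = padif.standardize(padif.compute_raw_padif(pose), protein)
        assert len(std.keys) == 800

    def test_matches_brute_force_group_by_mean(self, tiny_protein):
        rng = np.random.default_rng(5)
        contributions = {aid: rng.normal(size=8) for aid in tiny_protein}
        raw = padif.compute_raw_padif(make_pose(contributions=contributions))
        std = padif.standardize(raw, tiny_protein)
        rows = []
        for aid, vec in raw.entries.items():
            atom = tiny_protein[aid]
            for term, v in zip(INTERACTION_TERMS, vec):
                rows.append((atom.residue_name, term, atom.atom_class, v))
        oracle = (
            pd.DataFrame(rows, columns=["res", "term", "cls", "v"])
            .groupby(["res", "term", "cls"])["v"]
            .mean()
        )
        assert len(std.keys) == len(oracle)
        for key, value in std.keys.items():
            assert value == pytest.approx(oracle.loc[key])

    def test_atom_order_permutation_invariance(self, tiny_protein):
        rng = np.random.default_rng(6)
        items = [(aid, rng.normal(size=8)) for aid in tiny_protein]
        fwd = padif.standardize(
            padif.compute_raw_padif(make_pose(contributions=dict(items))), tiny_protein
        )
        rev = padif.standardize(
            padif.compute_raw_padif(make_pose(contributions=dict(reversed(items)))),
            tiny_protein,
        )
        assert fwd.keys.keys() == rev.keys.keys()
        for k in fwd.keys:
            assert fwd.keys[k] == pytest.approx(rev.keys[k])

    def test_unknown_atom_class_is_vocabulary_error(self):
        protein = {1: ProteinAtom(1, "GLU", 10, "A", "WEIRD")}
        raw = padif.compute_raw_padif(make_pose(contributions={1: np.ones(8)}))
        with pytest.raises(VocabularyError, match="atom class"):
            padif.standardize(raw, protein)

    def test_nonstandard_residue_error_and_other_bucket(self):
        protein = {1: ProteinAtom(1, "MSE", 10, "A", "DONOR")}
        raw = padif.compute_raw_padif(make_pose(contributions={1: np.ones(8)}))
        with pytest.raises(VocabularyError, match="residue"):
            padif.standardize(raw, protein)
        layout = DEFAULT_LAYOUT.with_other_residue()
        std = padif.standardize(raw, protein, layout, nonstandard_policy="other")
        assert ("OTHER", "PLP.S(bond)", "DONOR") in std.keys

    def test_positive_only_drops_unfavorable_keys(self, tiny_protein):
        pose = make_pose(
            contributions={3: np.array([0, 0, 0, 0, 0, 0, 1.3, -0.8])}
        )
        std = padif.standardize(
            padif.compute_raw_padif(pose), tiny_protein, positive_only=True
        )
        assert ("ALA", "PLP.S(nonpolar)", "NONPOLAR") in std.keys
        assert ("ALA", "PLP.S(repulsive)", "NONPOLAR") not in std.keys


def _full_coverage_pose():
    protein = {}
    contributions = {}
    aid = 1
    for r, res in enumerate(STANDARD_RESIDUES):
        for cls in DEFAULT_ATOM_CLASSES:
            protein[aid] = ProteinAtom(aid, res, r + 1, "A", cls)
            contributions[aid] = np.ones(8)
            aid += 1
    return protein, make_pose(contributions=contributions)


class TestVectorize:
    def test_default_layout_gives_length_800(self):
        protein, pose = _full_coverage_pose()
        std = padif.standardize(padif.compute_raw_padif(pose), protein)
        assert padif.vectorize(std).shape == (800,)

    def test_empty_fingerprint_is_zero_vector(self):
        vec = padif.vectorize(padif.StdPADIF("m", {}, DEFAULT_LAYOUT.layout_id))
        assert vec.shape == (800,)
        assert not vec.any()

    def test_round_trip_preserves_nonzero_keys(self, tiny_protein):
        rng = np.random.default_rng(7)
        raw = padif.compute_raw_padif(
            make_pose(contributions={aid: rng.normal(size=8) for aid in tiny_protein})
        )
        std = padif.standardize(raw, tiny_protein)
        back = padif.devectorize(padif.vectorize(std), molecule_id="m")
        assert back.keys.keys() == std.keys.keys()
        for k in std.keys:
            assert back.keys[k] == pytest.approx(std.keys[k])

    def test_layout_mismatch_is_layout_error(self):
        other = PadifLayout(STANDARD_RESIDUES[:5])
        std = padif.StdPADIF("m", {}, DEFAULT_LAYOUT.layout_id)
        with pytest.raises(LayoutError):
            padif.vectorize(std, other)


class TestCosine:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert padif.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_one_hots(self):
        assert padif.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert padif.cosine_similarity([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)

    def test_zero_vector_is_undefined(self):
        with pytest.raises(ValueError, match="zero vector"):
            padif.cosine_similarity([0, 0], [1, 0])


def test_vectorizer_transform_matches_manual_pipeline(tiny_protein):
    rng = np.random.default_rng(8)
    poses = [
        make_pose(f"m{i}", 0, 50.0, {aid: rng.normal(size=8) for aid in tiny_protein})
        for i in range(3)
    ]
    vec = padif.PadifVectorizer(protein=tiny_protein).fit(poses)
    mat = vec.transform(poses)
    manual = np.vstack(
        [
            padif.vectorize(
                padif.standardize(padif.compute_raw_padif(p), tiny_protein)
            )
            for p in poses
        ]
    )
    npt.assert_allclose(mat, manual)
    assert vec.molecule_ids_ == ["m0", "m1", "m2"]
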
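"""Curation filters, decoy builders, external carve-out and splitters."""

import numpy as np
import pandas as pd
import pytest

from padifwf import datasets, synthgen
from padifwf.datasets import (
    ACTIVE,
    ALLOWED_ACTIVITY_TYPES,
    DCM_DECOY,
    TRUE_INACTIVE,
    ZNC_DECOY,
)
from padifwf.errors import (
    CapacityError,
    ConsistencyError,
    EmptyInputError,
    ParameterError,
    SplitInfeasibleError,
)
from padifwf.synthgen import SynthSpec

from conftest import make_pose


def compound_row(cid, smiles="c1ccccc1CC", a_type="IC50", value=1.0, conf=9, mw=300.0):
    return {
        "compound_id": cid,
        "smiles": smiles,
        "activity_type": a_type,
        "activity_value_um": value,
        "confidence_class": conf,
        "mw": mw,
    }


class TestCuration:
    @pytest.mark.parametrize(
        "override, kept",
        [
            ({}, True),
            ({"mw": 150.0}, False),
            ({"mw": 180.0}, True),
            ({"mw": 900.0}, True),
            ({"mw": 900.1}, False),
            ({"value": 5.0, "conf": 9, "mw": 300.0}, True),
            ({"value": 10.0}, False),
            ({"value": 9.99}, True),
            ({"conf": 7}, False),
            ({"a_type": "AC50"}, False),
            ({"smiles": "not_a_smiles("}, False),
        ],
    )
    def test_filter_boundaries(self, override, kept):
        table = pd.DataFrame([compound_row("c1", **override)])
        out = datasets.curate_actives(table)
        assert (len(out) == 1) is kept

    def test_duplicates_collapse_to_most_potent(self):
        table = pd.DataFrame(
            [
                compound_row("weak", smiles="C1CCCCC1CC", value=5.0),
                compound_row("strong", smiles="C1CCCCC1CC", value=0.5),
            ]
        )
        out = datasets.curate_actives(table)
        assert list(out["compound_id"]) == ["strong"]

    def test_matches_brute_force_row_filter(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(200):
            rows.append(
                compound_row(
                    f"c{i}",
                    smiles="c1ccccc1" + "C" * int(rng.integers(1, 12)),
                    a_type=str(rng.choice(["IC50", "EC50", "Ki", "Kd", "AC50", "pIC50"])),
                    value=float(rng.uniform(0.01, 20.0)),
                    conf=int(rng.integers(5, 10)),
                    mw=float(rng.uniform(100.0, 1000.0)),
                )
            )
        table = pd.DataFrame(rows)
        out = datasets.curate_actives(table)

        survivors = {}
        for row in rows:  # independent loop-based oracle, most potent per SMILES
            ok = (
                180.0 <= row["mw"] <= 900.0
                and row["activity_type"] in ALLOWED_ACTIVITY_TYPES
                and row["confidence_class"] in (8, 9)
                and row["activity_value_um"] < 10.0
            )
            if not ok:
                continue
            prev = survivors.get(row["smiles"])
            if prev is None or row["activity_value_um"] < prev["activity_value_um"]:
                survivors[row["smiles"]] = row
        assert set(out["compound_id"]) == {r["compound_id"] for r in survivors.values()}

    def test_generator_ground_truth_agrees(self, small_spec):
        table, expected = synthgen.gen_compound_table(small_spec)
        out = datasets.curate_actives(table)
        assert set(out["compound_id"]) == expected


class TestDissimilarityFilter:
    def actives(self):
        return pd.DataFrame([compound_row("a1", smiles="c1ccccc1CCCO")])

    def test_identical_inactive_removed(self):
        inactives = pd.DataFrame([compound_row("i1", smiles="c1ccccc1CCCO")])
        out = datasets.filter_dissimilar_inactives(inactives, self.actives(), 0.99)
        assert len(out) == 0

    def test_dissimilar_inactive_kept(self):
        inactives = pd.DataFrame([compound_row("i1", smiles="C1CSCCS1")])
        out = datasets.filter_dissimilar_inactives(inactives, self.actives(), 0.40)
        assert list(out["compound_id"]) == ["i1"]
        assert (out["label"] == TRUE_INACTIVE).all()

    def test_zero_threshold_removes_everything(self):
        inactives = pd.DataFrame([compound_row("i1", smiles="C1CSCCS1")])
        out = datasets.filter_dissimilar_inactives(inactives, self.actives(), 0.0)
        assert len(out) == 0

    def test_empty_inputs(self):
        with pytest.raises(EmptyInputError):
            datasets.filter_dissimilar_inactives(pd.DataFrame(), self.actives(), 0.4)


class TestRandomDecoys:
    def pool(self, n=300):
        return synthgen.gen_decoy_pool(SynthSpec(seed=1), n)

    def test_four_to_one_ratio(self):
        out = datasets.sample_random_decoys(self.pool(), n_actives=50, ratio=4, seed=0)
        assert len(out) == 200

    def test_seeded_determinism(self):
        a = datasets.sample_random_decoys(self.pool(), 20, 4, seed=7)
        b = datasets.sample_random_decoys(self.pool(), 20, 4, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_pool_names_counts(self):
        with pytest.raises(CapacityError, match="200.*100"):
            datasets.sample_random_decoys(self.pool(100), 50, 4, seed=0)

    @pytest.mark.parametrize("label", [ZNC_DECOY, DCM_DECOY, TRUE_INACTIVE])
    def test_built_dataset_counts_exact(self, label):
        actives = pd.DataFrame([compound_row(f"a{i}") for i in range(30)])
        ds = datasets.build_decoy_dataset(actives, self.pool(), label, ratio=4, seed=1)
        assert (ds["label"] == ACTIVE).sum() == 30
        assert (ds["label"] == label).sum() == 120


class TestRmsd:
    def test_identity(self):
        c = np.zeros((5, 3))
        assert datasets.rmsd(c, c) == 0.0

    def test_uniform_translation(self):
        c = np.random.default_rng(0).normal(size=(7, 3))
        assert datasets.rmsd(c, c + [1.0, 0, 0]) == pytest.approx(1.0)

    def test_two_atom_hand_example(self):
        a = np.zeros((2, 3))
        b = np.array([[3.0, 0, 0], [0, 4.0, 0]])
        assert datasets.rmsd(a, b) == pytest.approx(np.sqrt(12.5))

    def test_shape_mismatch(self):
        with pytest.raises(ConsistencyError):
            datasets.rmsd(np.zeros((2, 3)), np.zeros((3, 3)))


class TestDivDecoys:
    def poses_with_offsets(self, offsets, scores=None):
        base = np.random.default_rng(1).normal(size=(6, 3))
        poses = []
        for i, off in enumerate(offsets):
            score = 60.0 - i if scores is None else scores[i]
            poses.append(
                make_pose("m", i, score, {1: np.ones(8)}, base + np.array([off, 0, 0]))
            )
        return poses

    def test_best_pose_never_retained_and_min_separation(self, small_spec):
        spec = small_spec
        spec.poses_per_molecule = 20
        poses, _, best_idx = synthgen.gen_docking_output(
            spec, {f"m{i}": 1 for i in range(5)}
        )
        out = datasets.build_div_decoys(poses, 1.5, seed=0)
        assert out, "diversity filter retained no poses at all"
        by_mol = {}
        for p in out:
            assert p.pose_index != best_idx[p.molecule_id]
            by_mol.setdefault(p.molecule_id, []).append(p)
        for mol, ps in by_mol.items():
            for i in range(len(ps)):
                for j in range(i + 1, len(ps)):
                    assert datasets.rmsd(ps[i].ligand_coords, ps[j].ligand_coords) >= 1.5

    def test_near_duplicate_poses_yield_nothing(self):
        poses = self.poses_with_offsets([0.0, 0.1, 0.2, 0.15])
        assert datasets.build_div_decoys(poses, 1.5, seed=0) == []

    def test_single_pose_contributes_no_decoys(self):
        poses = self.poses_with_offsets([0.0])
        assert datasets.build_div_decoys(poses, 1.5, seed=0) == []

    def test_greedy_retains_far_poses(self):
        poses = self.poses_with_offsets([0.0, 2.0, 4.0, 2.1])
        out = datasets.build_div_decoys(poses, 1.5, seed=0)
        assert {p.pose_index for p in out} == {1, 2}

    def test_missing_coordinates_is_an_error(self):
        poses = [make_pose("m", 0, 60.0), make_pose("m", 1, 50.0)]
        with pytest.raises(ConsistencyError, match="coordinates"):
            datasets.build_div_decoys(poses, 1.5, seed=0)

    def test_max_per_molecule_subsampling_is_seeded(self):
        poses = self.poses_with_offsets([0.0, 2.0, 4.0, 6.0, 8.0, 10.0])
        a = datasets.build_div_decoys(poses, 1.5, seed=3, max_per_molecule=2)
        b = datasets.build_div_decoys(poses, 1.5, seed=3, max_per_molecule=2)
        assert [p.pose_index for p in a] == [p.pose_index for p in b]
        assert len(a) == 2


class TestExternalCarve:
    def dataset(self, n_act=100, n_inact=60):
        rows = [dict(compound_row(f"a{i}"), label=ACTIVE) for i in range(n_act)]
        rows += [dict(compound_row(f"i{i}"), label=TRUE_INACTIVE) for i in range(n_inact)]
        return pd.DataFrame(rows)

    def test_ten_percent_per_label(self):
        external, remainder = datasets.carve_external_validation(self.dataset(), 0.10, 1)
        assert (external["label"] == ACTIVE).sum() == 10
        assert (external["label"] == TRUE_INACTIVE).sum() == 6
        assert len(external) + len(remainder) == 160

    def test_round_half_up(self):
        external, _ = datasets.carve_external_validation(self.dataset(25, 4), 0.10, 1)
        assert (external["label"] == ACTIVE).sum() == 3  # 2.5 rounds up
        assert (external["label"] == TRUE_INACTIVE).sum() == 0

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 2.0])
    def test_fraction_domain(self, fraction):
        with pytest.raises(ParameterError):
            datasets.carve_external_validation(self.dataset(), fraction, 1)

    def test_seeded_determinism_and_disjointness(self):
        a_ext, a_rem = datasets.carve_external_validation(self.dataset(), 0.10, 42)
        b_ext, _ = datasets.carve_external_validation(self.dataset(), 0.10, 42)
        assert list(a_ext["compound_id"]) == list(b_ext["compound_id"])
        assert not set(a_ext["compound_id"]) & set(a_rem["compound_id"])


class TestSplit:
    def dataset(self, n=60, seed=2):
        spec = SynthSpec(n_actives=n, seed=seed)
        table, _ = synthgen.gen_compound_table(spec)
        out = datasets.curate_actives(table)
        out["label"] = ACTIVE
        return out

    def test_random_split_fractions(self):
        rows = [dict(compound_row(f"a{i}"), label=ACTIVE) for i in range(700)]
        rows += [dict(compound_row(f"d{i}"), label=ZNC_DECOY) for i in range(300)]
        ds = pd.DataFrame(rows)
        out = datasets.split(ds, "random", 0.70, seed=0)
        n_train = (out.assignments["part"] == "TRAIN").sum()
        assert abs(n_train - 700) <= 1

    @pytest.mark.parametrize("method", ["scaffold", "fingerprint"])
    def test_groups_never_straddle_parts(self, method):
        from rdkit.Chem.Scaffolds import MurckoScaffold

        ds = self.dataset(80)
        out = datasets.split(ds, method, 0.70, seed=5)
        if method == "scaffold":
            key = [MurckoScaffold.MurckoScaffoldSmiles(smiles=s) for s in ds["smiles"]]
            frame = out.assignments.assign(key=key)
            straddling = frame.groupby("key")["part"].nunique()
            assert (straddling == 1).all()

    def test_identical_molecules_are_infeasible_for_fingerprint_split(self):
        ds = pd.DataFrame(
            [dict(compound_row(f"c{i}", smiles="c1ccccc1CC"), label=ACTIVE) for i in range(10)]
        )
        with pytest.raises(SplitInfeasibleError):
            datasets.split(ds, "fingerprint", 0.70, seed=0)

    def test_unknown_method_and_bad_fraction(self):
        ds = self.dataset(10)
        with pytest.raises(ParameterError):
            datasets.split(ds, "cluster", 0.7, 0)
        with pytest.raises(ParameterError):
            datasets.split(ds, "random", 1.2, 0)

    def test_manifest_round_trip(self, tmp_path):
        out = datasets.split(self.dataset(20), "random", 0.70, seed=1)
        out.to_manifest(tmp_path / "man.csv")
        man = pd.read_csv(tmp_path / "man.csv")
        assert set(man.columns) == {"compound_id", "part", "method", "seed"}
        assert set(man["part"]) <= {"TRAIN", "TEST"}
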
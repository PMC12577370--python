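import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from padifwf.dock_io import PoseRecord, ProteinAtom
from padifwf.synthgen import SynthSpec

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_protein() -> dict[int, ProteinAtom]:
    """Four-atom receptor: two GLU donors, an ALA nonpolar, an ASP acceptor."""
    atoms = [
        ProteinAtom(1, "GLU", 10, "A", "DONOR"),
        ProteinAtom(2, "GLU", 10, "A", "DONOR"),
        ProteinAtom(3, "ALA", 11, "A", "NONPOLAR"),
        ProteinAtom(4, "ASP", 12, "A", "ACCEPTOR"),
    ]
    return {a.atom_id: a for a in atoms}


@pytest.fixture
def small_spec() -> SynthSpec:
    return SynthSpec(n_actives=12, poses_per_molecule=5, seed=11)


def make_pose(
    molecule_id="mol1",
    pose_index=0,
    total_score=50.0,
    contributions=None,
    coords=None,
):
    return PoseRecord(
        molecule_id,
        pose_index,
        total_score,
        contributions if contributions is not None else {1: np.zeros(8)},
        None if coords is None else np.asarray(coords, dtype=float),
    )
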
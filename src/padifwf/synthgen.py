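"""Synthetic inputs with the statistical structure the workflow assumes.

Every stage of the pipeline — per-atom score parsing, fingerprint
standardization, decoy building, splitting, training, enrichment metrics —
is testable without docking software or database downloads through three
generators:

* :func:`gen_protein_site` — a receptor atom table covering the residue
  and atom-class vocabularies with configurable multiplicity.
* :func:`gen_docking_output` — multi-pose docking results.  Per-atom term
  contributions are drawn from class-conditional normal distributions:
  the *best* pose of an active molecule carries a mean shift of
  ``effect_size`` standard deviations on a fixed, logged subset of
  (residue, term, atom class) keys; every other pose — wrong poses of
  actives, and all poses of non-actives — draws from the background
  distribution.  Ligand coordinates are a base conformation plus per-pose
  rigid translation whose magnitude straddles the 1.5 Å diversity-filter
  boundary.  Values are written with the docking file convention (the
  three ChemScore-derived terms carry the inverted sign) and rounded to
  the fixture dialect's 6 significant digits so file round trips are
  exact.
* :func:`gen_compound_table` — a curation-filter exercise table with rows
  on both sides of every boundary (MW 180/900 Da, activity 10 µM,
  confidence 7/8/9, disallowed activity types, duplicates, an unparsable
  SMILES) together with its own ground-truth survivor set.

What the generator does *not* emulate: physically realistic poses or
energies, correlated term structure within an atom, and chemically
meaningful SMILES beyond parseability and scaffold diversity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .dock_io import PoseRecord, ProteinAtom, round_sig

RDLogger.DisableLog("rdApp.*")
from .vocab import (
    DEFAULT_ATOM_CLASSES,
    INTERACTION_TERMS,
    N_INVERTED_TERMS,
    N_TERMS,
    PadifLayout,
    STANDARD_RESIDUES,
)

__all__ = [
    "SynthSpec",
    "gen_protein_site",
    "signal_keys",
    "gen_docking_output",
    "gen_compound_table",
    "gen_inactive_table",
    "gen_decoy_pool",
]

#: sign convention of the docking files: first three terms inverted
_FILE_SIGNS = np.array([-1.0] * N_INVERTED_TERMS + [1.0] * (N_TERMS - N_INVERTED_TERMS))

#: ring scaffolds used to give generated SMILES Murcko-scaffold diversity;
#: the "core" set seeds actives/inactives, the disjoint "pool" set seeds
#: purchasable-library and dark-chemical-matter pools (real decoy libraries
#: occupy a different chemotype distribution than a target's active series)
_SCAFFOLDS = (
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "C1CCCCC1", "c1ccoc1",
    "c1ccsc1", "C1CCNCC1", "c1ccc2nccnc2c1", "C1CCOC1", "c1ccc(cc1)c1ccccc1",
    "c1cnoc1", "C1CCCNC1", "c1ccc2ncccc2c1", "C1CCCOC1", "c1csc(n1)C",
)

_POOL_SCAFFOLDS = (
    "c1ccc2c(c1)CCCC2", "C1OCCOC1", "C1CSCCS1", "c1cc[nH]c1", "c1cn[nH]c1",
    "C1CCOCC1", "c1ccc(cc1)Oc1ccccc1", "C1CCC2CCCCC2C1", "c1ccc2[nH]ccc2c1",
    "C1CCSC1",
)


@dataclass
class SynthSpec:
    """Study conditions for one synthetic target.

    Defaults mirror the emulated protocol: 20-pose docking runs, a
    20-residue x 5-atom-class binding site, activity curation bounds at
    180–900 Da and 10 µM.  ``effect_size`` is the separation (in noise SD
    units) between the class-conditional contribution means on the signal
    keys; ``jitter_range`` is the per-pose rigid displacement range (Å),
    chosen to straddle the 1.5 Å RMSD diversity cutoff.
    """

    n_actives: int = 50
    n_decoys: int = 200
    n_residues: int = 20
    n_atom_classes: int = 5
    atoms_per_pair: int = 1
    poses_per_molecule: int = 20
    effect_size: float = 3.0
    noise_sd: float = 0.5
    base_mean: float = 1.0
    n_signal_keys: int = 40
    n_ligand_atoms: int = 10
    jitter_range: tuple[float, float] = (0.3, 3.0)
    mw_range: tuple[float, float] = (180.0, 900.0)
    max_activity_um: float = 10.0
    seed: int = 0

    def layout(self) -> PadifLayout:
        return PadifLayout(
            STANDARD_RESIDUES[: self.n_residues],
            DEFAULT_ATOM_CLASSES[: self.n_atom_classes],
        )


def gen_protein_site(spec: SynthSpec) -> dict[int, ProteinAtom]:
    """Receptor atoms covering residues x atom classes.

    ``atoms_per_pair`` atoms per (residue, class) pair; with defaults
    20 x 5 x 1 = 100 atoms, so every fingerprint key can be occupied.
    """
    if spec.n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    atoms: dict[int, ProteinAtom] = {}
    atom_id = 1
    for r in range(spec.n_residues):
        res = STANDARD_RESIDUES[r]
        for c in range(spec.n_atom_classes):
            cls = DEFAULT_ATOM_CLASSES[c]
            for _ in range(spec.atoms_per_pair):
                atoms[atom_id] = ProteinAtom(atom_id, res, r + 1, "A", cls)
                atom_id += 1
    return atoms


def signal_keys(spec: SynthSpec) -> list[tuple[str, str, str]]:
    """The fixed, evenly spaced key subset carrying the class signal."""
    layout = spec.layout()
    all_keys = list(layout.keys())
    n = min(spec.n_signal_keys, len(all_keys))
    idx = np.linspace(0, len(all_keys) - 1, n).astype(int)
    return [all_keys[i] for i in idx]


def _mean_matrix(spec: SynthSpec, protein: dict[int, ProteinAtom], with_signal: bool) -> np.ndarray:
    """Per-atom, per-term contribution means (standardized sign)."""
    atoms = sorted(protein)
    mat = np.full((len(atoms), N_TERMS), spec.base_mean)
    if with_signal:
        keys = set(signal_keys(spec))
        for i, aid in enumerate(atoms):
            atom = protein[aid]
            for t, term in enumerate(INTERACTION_TERMS):
                if (atom.residue_name, term, atom.atom_class) in keys:
                    mat[i, t] += spec.effect_size * spec.noise_sd
    return mat


def gen_docking_output(
    spec: SynthSpec,
    molecule_classes: dict[str, int] | Sequence[tuple[str, int]],
) -> tuple[list[PoseRecord], dict[int, ProteinAtom], dict[str, int]]:
    """Multi-pose docking results for a labeled molecule collection.

    Parameters
    ----------
    spec : SynthSpec
        Study conditions; ``spec.seed`` drives all randomness.
    molecule_classes : mapping of molecule_id -> {0, 1}
        1 marks an active molecule (its best pose carries the signal).

    Returns
    -------
    (poses, protein, best_pose_index)
        All pose records (``poses_per_molecule`` per molecule), the shared
        receptor table, and the ground-truth best pose index per molecule.
    """
    items = list(molecule_classes.items()) if isinstance(molecule_classes, dict) else list(molecule_classes)
    rng = np.random.default_rng(spec.seed)
    protein = gen_protein_site(spec)
    atom_ids = sorted(protein)
    mean_bg = _mean_matrix(spec, protein, with_signal=False)
    mean_sig = _mean_matrix(spec, protein, with_signal=True)

    poses: list[PoseRecord] = []
    best_index: dict[str, int] = {}
    for mol_id, cls in items:
        scores = rng.normal(60.0, 5.0, size=spec.poses_per_molecule)
        best = int(np.argmax(scores))
        best_index[mol_id] = best
        base_coords = rng.uniform(0.0, 10.0, size=(spec.n_ligand_atoms, 3))
        for p in range(spec.poses_per_molecule):
            means = mean_sig if (cls == 1 and p == best) else mean_bg
            values = rng.normal(means, spec.noise_sd)
            if p == best:
                coords = base_coords
            else:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                shift = rng.uniform(*spec.jitter_range)
                coords = base_coords + shift * direction
            contributions = {
                aid: np.array([round_sig(v) for v in values[i] * _FILE_SIGNS])
                for i, aid in enumerate(atom_ids)
            }
            poses.append(
                PoseRecord(
                    molecule_id=mol_id,
                    pose_index=p,
                    total_score=round_sig(float(scores[p])),
                    contributions=contributions,
                    ligand_coords=np.round(coords, 4),
                )
            )
    return poses, protein, best_index


def _make_smiles(
    rng: np.random.Generator,
    used: set[str],
    scaffolds: tuple[str, ...] = _SCAFFOLDS,
) -> str:
    """A parseable, previously unused SMILES with a ring scaffold.

    Active-series molecules carry plain alkyl(-ol) chains; pool molecules
    (``_POOL_SCAFFOLDS``) carry short ether/amine chains, keeping their
    Morgan-fingerprint overlap with the active series realistically low.
    """
    pool_style = scaffolds is _POOL_SCAFFOLDS
    for _ in range(60):
        scaffold = scaffolds[rng.integers(len(scaffolds))]
        if pool_style:
            chain = (
                "C" * int(rng.integers(0, 5))
                + str(rng.choice(["", "O", "N"]))
                + "C" * int(rng.integers(0, 4))
            )
        else:
            chain = "C" * int(rng.integers(1, 9)) + ("O" if rng.random() < 0.3 else "")
        smi = scaffold + chain
        if smi not in used and Chem.MolFromSmiles(smi) is not None:
            used.add(smi)
            return smi
    # deterministic fallback: chain length grows without bound
    k = len(used)
    while True:
        smi = scaffolds[k % len(scaffolds)] + "C" * (k // len(scaffolds) + 1)
        if smi not in used:
            used.add(smi)
            return smi
        k += 1


def gen_compound_table(
    spec: SynthSpec, prefix: str = "ACT"
) -> tuple[pd.DataFrame, set[str]]:
    """Curation exercise table plus its ground-truth survivor ids.

    The table contains ``spec.n_actives`` clean survivors plus a fixed
    battery of boundary and failure rows: molecular weights just inside
    and outside 180/900 Da, activity exactly at and just below 10 µM,
    confidence classes 7/8/9, a disallowed activity type, a duplicate
    canonical-SMILES pair (the more potent record survives), and an
    unparsable SMILES.  The expected-survivor set is constructed by the
    generator's own bookkeeping, independent of the curation code.
    """
    rng = np.random.default_rng(spec.seed + 1)
    used: set[str] = set()
    rows: list[dict] = []
    survivors: set[str] = set()
    types = sorted({"IC50", "EC50", "Ki", "Kd"})

    def add(cid, smiles, a_type, value, conf, mw, survives):
        rows.append(
            {
                "compound_id": cid,
                "smiles": smiles,
                "activity_type": a_type,
                "activity_value_um": value,
                "confidence_class": conf,
                "mw": mw,
            }
        )
        if survives:
            survivors.add(cid)

    for i in range(spec.n_actives):
        add(
            f"{prefix}{i:04d}",
            _make_smiles(rng, used),
            types[int(rng.integers(len(types)))],
            round(float(rng.uniform(0.01, spec.max_activity_um * 0.95)), 4),
            int(rng.choice([8, 9])),
            round(float(rng.uniform(*spec.mw_range)), 2),
            True,
        )
    b = f"{prefix}B"
    lo, hi = spec.mw_range
    add(f"{b}00", _make_smiles(rng, used), "IC50", 1.0, 9, lo - 0.1, False)   # below MW range
    add(f"{b}01", _make_smiles(rng, used), "IC50", 1.0, 9, lo, True)          # at lower MW bound
    add(f"{b}02", _make_smiles(rng, used), "IC50", 1.0, 9, hi, True)          # at upper MW bound
    add(f"{b}03", _make_smiles(rng, used), "IC50", 1.0, 9, hi + 0.1, False)   # above MW range
    add(f"{b}04", _make_smiles(rng, used), "Ki", spec.max_activity_um, 8, 300.0, False)  # at cutoff, strict
    add(f"{b}05", _make_smiles(rng, used), "Ki", spec.max_activity_um - 0.01, 8, 300.0, True)
    add(f"{b}06", _make_smiles(rng, used), "EC50", 1.0, 7, 300.0, False)      # confidence too low
    add(f"{b}07", _make_smiles(rng, used), "AC50", 1.0, 9, 300.0, False)      # disallowed type
    dup = _make_smiles(rng, used)
    add(f"{b}08", dup, "Kd", 5.0, 9, 400.0, False)                            # duplicate, less potent
    add(f"{b}09", dup, "Kd", 0.5, 9, 400.0, True)                             # duplicate, survivor
    add(f"{b}10", "not_a_smiles(", "IC50", 1.0, 9, 300.0, False)              # unparsable
    return pd.DataFrame(rows), survivors


def gen_inactive_table(
    spec: SynthSpec,
    n: int,
    prefix: str = "INA",
    seed_offset: int = 5,
    similar_fraction: float = 0.2,
) -> pd.DataFrame:
    """Confirmed non-binders for the TRUE strategy.

    A ``similar_fraction`` of rows reuse the active-series scaffolds —
    these are the non-binders the structural dissimilarity filter is
    expected to remove; the rest draw from the disjoint pool scaffolds.
    """
    rng = np.random.default_rng(spec.seed + seed_offset)
    used: set[str] = set()
    rows = []
    for i in range(n):
        scaffolds = _SCAFFOLDS if rng.random() < similar_fraction else _POOL_SCAFFOLDS
        rows.append(
            {
                "compound_id": f"{prefix}{i:05d}",
                "smiles": _make_smiles(rng, used, scaffolds),
                "activity_type": "IC50",
                "activity_value_um": round(float(rng.uniform(50.0, 500.0)), 2),
                "confidence_class": int(rng.choice([8, 9])),
                "mw": round(float(rng.uniform(*spec.mw_range)), 2),
            }
        )
    return pd.DataFrame(rows)


def gen_decoy_pool(
    spec: SynthSpec,
    n: int,
    prefix: str = "ZNC",
    seed_offset: int = 2,
    scaffold_set: str = "pool",
) -> pd.DataFrame:
    """Pool of presumed-inactive compounds (no measured activity).

    ``scaffold_set="pool"`` (default) draws from a scaffold family
    disjoint from the active series, as real screening libraries do;
    ``"core"`` reuses the active-series scaffolds.
    """
    rng = np.random.default_rng(spec.seed + seed_offset)
    scaffolds = _POOL_SCAFFOLDS if scaffold_set == "pool" else _SCAFFOLDS
    used: set[str] = set()
    rows = [
        {
            "compound_id": f"{prefix}{i:05d}",
            "smiles": _make_smiles(rng, used, scaffolds),
            "activity_type": "",
            "activity_value_um": np.nan,
            "confidence_class": np.nan,
            "mw": round(float(rng.uniform(*spec.mw_range)), 2),
        }
        for i in range(n)
    ]
    return pd.DataFrame(rows)
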
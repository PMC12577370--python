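"""Dataset curation, decoy assembly, external carve-out and splitting.

Compound tables are plain :class:`pandas.DataFrame` objects with the
columns ``compound_id, smiles, activity_type, activity_value_um,
confidence_class, mw`` (see :data:`COMPOUND_COLUMNS`); builders add a
``label`` column drawn from :data:`LABELS`.

The four negative-example strategies mirror the workflow under study:

* TRUE — experimentally confirmed non-binders, kept only when structurally
  dissimilar (Morgan/Tanimoto) to every active;
* ZNC — random draws from a large purchasable-compound pool;
* DCM — random draws from a dark-chemical-matter pool (recurrent HTS
  non-binders);
* DIV — "wrong pose" decoys: diverse low-scoring docking conformations of
  the actives themselves, pairwise >= 1.5 Å RMSD apart and never the
  best-scoring pose.

TRUE/ZNC/DCM datasets hold exactly ``ratio`` (default 4) decoys per active.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.ML.Cluster import Butina

from .dock_io import PoseRecord, group_poses, select_best_pose
from .errors import (
    CapacityError,
    ConsistencyError,
    EmptyInputError,
    ParameterError,
    SchemaError,
    SplitInfeasibleError,
)

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "COMPOUND_COLUMNS",
    "LABELS",
    "read_compound_table",
    "write_compound_table",
    "curate_actives",
    "filter_dissimilar_inactives",
    "sample_random_decoys",
    "build_decoy_dataset",
    "build_true_dataset",
    "rmsd",
    "build_div_decoys",
    "carve_external_validation",
    "split",
    "SplitAssignment",
]

COMPOUND_COLUMNS = (
    "compound_id",
    "smiles",
    "activity_type",
    "activity_value_um",
    "confidence_class",
    "mw",
)

ACTIVE = "ACTIVE"
TRUE_INACTIVE = "TRUE_INACTIVE"
ZNC_DECOY = "ZNC_DECOY"
DCM_DECOY = "DCM_DECOY"
DIV_DECOY = "DIV_DECOY"
LABELS = (ACTIVE, TRUE_INACTIVE, ZNC_DECOY, DCM_DECOY, DIV_DECOY)

ALLOWED_ACTIVITY_TYPES = frozenset({"IC50", "EC50", "Ki", "Kd"})
ALLOWED_CONFIDENCE = frozenset({8, 9})
MW_RANGE = (180.0, 900.0)
MAX_ACTIVITY_UM = 10.0

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def read_compound_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COMPOUND_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing compound columns {missing}")
    return df


def write_compound_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def _canonical_smiles(smi) -> str | None:
    if not isinstance(smi, str):
        return None
    mol = Chem.MolFromSmiles(smi)
    return None if mol is None else Chem.MolToSmiles(mol)


def _fingerprints(smiles: Iterable[str]):
    fps = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
        fps.append(None if mol is None else _MORGAN.GetFingerprint(mol))
    return fps


def curate_actives(
    table: pd.DataFrame,
    *,
    mw_range: tuple[float, float] = MW_RANGE,
    activity_types: frozenset[str] = ALLOWED_ACTIVITY_TYPES,
    confidence_classes: frozenset[int] = ALLOWED_CONFIDENCE,
    max_activity_um: float = MAX_ACTIVITY_UM,
) -> pd.DataFrame:
    """Apply the active-compound curation filters.

    Keeps unique molecules with molecular weight within ``mw_range``
    (inclusive), activity type among IC50/EC50/Ki/Kd, assay confidence
    class 8 or 9, and activity strictly below 10 µM.  Duplicates (same
    canonical SMILES) collapse to the most potent record.  Rows with
    unparsable SMILES are skipped with a logged warning.
    """
    missing = [c for c in COMPOUND_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"compound table missing columns {missing}")
    df = table.copy()
    df["_canonical"] = [_canonical_smiles(s) for s in df["smiles"]]
    n_bad = int(df["_canonical"].isna().sum())
    if n_bad:
        logger.warning("curate_actives: skipped %d rows with unparsable SMILES", n_bad)
    df = df[df["_canonical"].notna()]

    mw = pd.to_numeric(df["mw"], errors="coerce")
    act = pd.to_numeric(df["activity_value_um"], errors="coerce")
    conf = pd.to_numeric(df["confidence_class"], errors="coerce")
    keep = (
        (mw >= mw_range[0])
        & (mw <= mw_range[1])
        & df["activity_type"].isin(activity_types)
        & conf.isin(confidence_classes)
        & (act < max_activity_um)
    )
    df = df[keep.fillna(False)].copy()
    # unique molecules: collapse by canonical SMILES, keep the most potent
    df = df.sort_values(["activity_value_um", "compound_id"], kind="mergesort")
    df = df.drop_duplicates(subset="_canonical", keep="first")
    df = df.drop(columns="_canonical").reset_index(drop=True)
    df["label"] = ACTIVE
    return df


def filter_dissimilar_inactives(
    inactives: pd.DataFrame,
    actives: pd.DataFrame,
    max_similarity: float = 0.40,
) -> pd.DataFrame:
    """Keep confirmed non-binders dissimilar to every active.

    A non-binder survives when its maximal Morgan(r=2, 2048 bits) Tanimoto
    similarity to any active is strictly below ``max_similarity``.
    """
    if len(inactives) == 0 or len(actives) == 0:
        raise EmptyInputError("filter_dissimilar_inactives: empty input collection")
    active_fps = [fp for fp in _fingerprints(actives["smiles"]) if fp is not None]
    keep = []
    for fp in _fingerprints(inactives["smiles"]):
        if fp is None:
            keep.append(False)
            continue
        max_sim = max(DataStructs.BulkTanimotoSimilarity(fp, active_fps), default=0.0)
        keep.append(max_sim < max_similarity)
    out = inactives[np.asarray(keep, dtype=bool)].copy().reset_index(drop=True)
    out["label"] = TRUE_INACTIVE
    return out


def sample_random_decoys(
    pool: pd.DataFrame, n_actives: int, ratio: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Uniform seeded sample of ``ratio * n_actives`` pool compounds."""
    need = ratio * n_actives
    if len(pool) < need:
        raise CapacityError(
            f"decoy pool too small: need {need} (= {ratio} x {n_actives}), have {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pool), size=need, replace=False))
    return pool.iloc[idx].copy().reset_index(drop=True)


def build_decoy_dataset(
    actives: pd.DataFrame,
    pool: pd.DataFrame,
    label: str,
    ratio: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Actives plus exactly ``ratio`` pool decoys per active, labeled."""
    if label not in (ZNC_DECOY, DCM_DECOY, TRUE_INACTIVE):
        raise ParameterError(f"unsupported decoy label {label!r}")
    decoys = sample_random_decoys(pool, len(actives), ratio, seed)
    decoys = decoys.copy()
    decoys["label"] = label
    act = actives.copy()
    act["label"] = ACTIVE
    return pd.concat([act, decoys], ignore_index=True)


def build_true_dataset(
    actives: pd.DataFrame,
    inactives: pd.DataFrame,
    ratio: int = 4,
    max_similarity: float = 0.40,
    seed: int = 0,
) -> pd.DataFrame:
    """TRUE dataset: dissimilarity-filtered non-binders at ratio:1."""
    filtered = filter_dissimilar_inactives(inactives, actives, max_similarity)
    return build_decoy_dataset(actives, filtered, TRUE_INACTIVE, ratio, seed)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation (Å) without superposition.

    Docking poses share the rigid receptor frame, so no alignment is
    applied; atom order must match.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ConsistencyError(f"rmsd: coordinate shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def build_div_decoys(
    poses: Iterable[PoseRecord] | Mapping[str, Sequence[PoseRecord]],
    min_rmsd: float = 1.5,
    seed: int = 0,
    max_per_molecule: int | None = None,
) -> list[PoseRecord]:
    """Diverse wrong-pose decoys from a multi-pose docking run.

    Per molecule the best-scoring pose is excluded, then the remaining
    poses are greedily retained in descending score order so that every
    retained pose lies at least ``min_rmsd`` Å (no superposition) from the
    best pose and from every other retained pose.  When
    ``max_per_molecule`` is set, a seeded uniform subsample of the eligible
    poses is returned.  Molecules with a single pose contribute nothing
    (logged, not an error).
    """
    by_mol = poses if isinstance(poses, Mapping) else group_poses(poses)
    rng = np.random.default_rng(seed)
    out: list[PoseRecord] = []
    for mol_id in by_mol:
        mol_poses = list(by_mol[mol_id])
        if len(mol_poses) < 2:
            logger.info("build_div_decoys: %s has a single pose, no decoys", mol_id)
            continue
        for p in mol_poses:
            if p.ligand_coords is None:
                raise ConsistencyError(
                    f"build_div_decoys: pose {mol_id}/{p.pose_index} lacks ligand coordinates"
                )
        best = select_best_pose(mol_poses)
        candidates = sorted(
            (p for p in mol_poses if p.pose_index != best.pose_index),
            key=lambda p: (-p.total_score, p.pose_index),
        )
        retained: list[PoseRecord] = []
        for cand in candidates:
            ok = rmsd(cand.ligand_coords, best.ligand_coords) >= min_rmsd and all(
                rmsd(cand.ligand_coords, r.ligand_coords) >= min_rmsd for r in retained
            )
            if ok:
                retained.append(cand)
        if max_per_molecule is not None and len(retained) > max_per_molecule:
            pick = np.sort(rng.choice(len(retained), size=max_per_molecule, replace=False))
            retained = [retained[i] for i in pick]
        out.extend(retained)
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def carve_external_validation(
    dataset: pd.DataFrame, fraction: float = 0.10, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split off the external validation set, stratified by label.

    Per label, round-half-up(fraction * count) records are drawn at random
    (seeded) into the EXTERNAL part; the remainder feeds dataset building
    and the train/test split.
    """
    if not 0 < fraction < 1:
        raise ParameterError(f"external fraction must be in (0, 1), got {fraction}")
    if "label" not in dataset.columns:
        raise SchemaError("carve_external_validation: dataset lacks a label column")
    rng = np.random.default_rng(seed)
    ext_idx: list[int] = []
    for _, group in dataset.groupby("label", sort=True):
        n_ext = _round_half_up(fraction * len(group))
        perm = rng.permutation(len(group))
        ext_idx.extend(group.index[perm[:n_ext]])
    mask = dataset.index.isin(ext_idx)
    external = dataset[mask].copy().reset_index(drop=True)
    remainder = dataset[~mask].copy().reset_index(drop=True)
    return external, remainder


@dataclass
class SplitAssignment:
    """Train/test assignment of one dataset under one splitter."""

    assignments: pd.DataFrame  # columns: compound_id, part
    method: str
    seed: int

    def part(self, name: str) -> pd.Index:
        return pd.Index(
            self.assignments.loc[self.assignments["part"] == name, "compound_id"]
        )

    def to_manifest(self, path: str | Path) -> None:
        man = self.assignments.copy()
        man["method"] = self.method
        man["seed"] = self.seed
        man.to_csv(path, index=False)


def _murcko(smiles: str) -> str:
    try:
        scaffold = MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles)
    except Exception:
        return ""
    return scaffold


def _greedy_group_fill(
    groups: list[list[int]], n_total: int, train_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Assign whole groups to TRAIN, largest first, until the target is met."""
    if len(groups) < 2:
        raise SplitInfeasibleError(
            f"grouped split needs at least 2 groups, found {len(groups)}"
        )
    order = rng.permutation(len(groups))  # shuffles ties between equal sizes
    order = sorted(order, key=lambda g: -len(groups[g]))
    target = _round_half_up(train_fraction * n_total)
    part = np.full(n_total, "TEST", dtype=object)
    n_train = 0
    for g in order:
        if n_train >= target:
            break
        part[groups[g]] = "TRAIN"
        n_train += len(groups[g])
    return part


def split(
    dataset: pd.DataFrame,
    method: str = "random",
    train_fraction: float = 0.70,
    seed: int = 0,
    cluster_cutoff: float = 0.35,
) -> SplitAssignment:
    """Partition a dataset into TRAIN/TEST by one of three strategies.

    ``random`` is a label-stratified shuffle (round-half-up per label,
    remainder reconciled from the majority label).  ``scaffold`` groups by
    Murcko scaffold and ``fingerprint`` by Butina clusters of Morgan(r=2)
    Tanimoto distance (``cluster_cutoff`` is the distance threshold); both
    assign whole groups to TRAIN largest-first until the train fraction is
    met, so no scaffold or cluster straddles TRAIN and TEST.
    """
    if method not in ("random", "scaffold", "fingerprint"):
        raise ParameterError(f"unknown split method {method!r}")
    if not 0 < train_fraction < 1:
        raise ParameterError(f"train fraction must be in (0, 1), got {train_fraction}")
    if len(dataset) == 0:
        raise EmptyInputError("split: empty dataset")
    rng = np.random.default_rng(seed)
    df = dataset.reset_index(drop=True)

    if method == "random":
        part = np.full(len(df), "TEST", dtype=object)
        labels = df["label"] if "label" in df.columns else pd.Series(["_"] * len(df))
        target_total = _round_half_up(train_fraction * len(df))
        counts = {}
        for lab, group in df.groupby(labels, sort=True):
            counts[lab] = (_round_half_up(train_fraction * len(group)), group.index)
        # reconcile rounding drift against the majority label
        drift = target_total - sum(n for n, _ in counts.values())
        if drift and counts:
            major = max(counts, key=lambda k: len(counts[k][1]))
            n, idx = counts[major]
            counts[major] = (min(max(n + drift, 0), len(idx)), idx)
        for n_train, idx in counts.values():
            perm = rng.permutation(len(idx))
            part[idx[perm[:n_train]]] = "TRAIN"
    else:
        if method == "scaffold":
            keys = [_murcko(s) for s in df["smiles"]]
            groups_map: dict[str, list[int]] = {}
            for i, k in enumerate(keys):
                groups_map.setdefault(k, []).append(i)
            groups = list(groups_map.values())
        else:
            fps = _fingerprints(df["smiles"])
            if any(fp is None for fp in fps):
                raise ParameterError("fingerprint split: unparsable SMILES in dataset")
            dists = []
            for i in range(1, len(fps)):
                sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
                dists.extend(1.0 - s for s in sims)
            clusters = Butina.ClusterData(dists, len(fps), cluster_cutoff, isDistData=True)
            groups = [list(c) for c in clusters]
        part = _greedy_group_fill(groups, len(df), train_fraction, rng)

    assignments = pd.DataFrame({"compound_id": df["compound_id"], "part": part})
    return SplitAssignment(assignments, method, seed)
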
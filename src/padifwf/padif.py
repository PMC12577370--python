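"""Build and standardize protein per-atom score contribution fingerprints.

The raw fingerprint (:class:`RawPADIF`) is the per-protein-atom 8-term
contribution map of one docking pose after sign standardization: the three
ChemScore-derived terms (Hbond, CHO, Metal) are reported by the docking
engine with the opposite sign convention from the five PLP surface terms,
so their signs are inverted, making "more favorable" point the same way
for every term.

The standardized fingerprint (:class:`StdPADIF`) projects the raw map onto
the target-independent key space (residue type, interaction term, atom
class): each key's value is the arithmetic mean of the contributions of
all protein atoms matching that triple.  With the default vocabularies the
dense layout has 20 x 8 x 5 = 800 keys; keys of unoccupied triples are
absent from the sparse map and zero-filled when vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dock_io import PoseRecord, ProteinAtom, best_poses
from .errors import EmptyInputError, LayoutError, VocabularyError
from .vocab import (
    DEFAULT_LAYOUT,
    INTERACTION_TERMS,
    N_INVERTED_TERMS,
    N_TERMS,
    OTHER_RESIDUE,
    PadifLayout,
)

__all__ = [
    "RawPADIF",
    "StdPADIF",
    "compute_raw_padif",
    "standardize",
    "vectorize",
    "devectorize",
    "cosine_similarity",
    "PadifVectorizer",
    "padif_matrix",
    "write_std_csv",
    "read_std_csv",
]

#: sign applied per term during standardization (involution)
_SIGNS = np.array([-1.0] * N_INVERTED_TERMS + [1.0] * (N_TERMS - N_INVERTED_TERMS))


@dataclass
class RawPADIF:
    """Sign-standardized per-atom contribution map of one pose."""

    molecule_id: str
    pose_index: int
    entries: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class StdPADIF:
    """Standardized fingerprint in the (residue, term, atom class) key space."""

    molecule_id: str
    keys: dict[tuple[str, str, str], float] = field(default_factory=dict)
    layout_id: str = DEFAULT_LAYOUT.layout_id


def compute_raw_padif(pose: PoseRecord) -> RawPADIF:
    """Sign-standardize one pose's per-atom contributions.

    The first three interaction terms are negated; the five PLP surface
    terms pass through unchanged.  Atoms whose contribution vector is
    all-zero are retained — they count toward key means downstream.
    """
    if not pose.contributions:
        raise EmptyInputError(
            f"pose {pose.molecule_id}/{pose.pose_index}: empty contribution map"
        )
    entries = {aid: np.asarray(vec, dtype=float) * _SIGNS for aid, vec in pose.contributions.items()}
    return RawPADIF(pose.molecule_id, pose.pose_index, entries)


def standardize(
    raw: RawPADIF,
    protein: Mapping[int, ProteinAtom],
    layout: PadifLayout = DEFAULT_LAYOUT,
    *,
    include_zero_atoms: bool = True,
    positive_only: bool = False,
    nonstandard_policy: str = "error",
) -> StdPADIF:
    """Collapse a raw fingerprint onto the (residue, term, atom class) keys.

    Parameters
    ----------
    raw : RawPADIF
        Sign-standardized per-atom map.
    protein : mapping of atom_id -> ProteinAtom
        Receptor atom table; every atom id in ``raw`` must resolve here.
    layout : PadifLayout
        Declares the residue and atom-class vocabularies.
    include_zero_atoms : bool
        If True (default) atoms with an all-zero contribution vector count
        toward the means of their triple; if False they are dropped first.
    positive_only : bool
        If True, only strictly positive (favorable, post sign
        standardization) per-atom term values enter the means; keys with
        no positive contributor are absent.  Default keeps all terms.
    nonstandard_policy : {"error", "other"}
        What to do with residues outside the layout vocabulary: raise, or
        bucket them under the OTHER residue (the layout must contain it,
        see :meth:`PadifLayout.with_other_residue`).
    """
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for atom_id, vec in raw.entries.items():
        atom = protein.get(atom_id)
        if atom is None:
            raise VocabularyError(f"atom_id {atom_id} missing from the protein table")
        res = atom.residue_name
        if res not in layout.residues:
            if nonstandard_policy == "other" and OTHER_RESIDUE in layout.residues:
                res = OTHER_RESIDUE
            else:
                raise VocabularyError(
                    f"residue {res!r} (atom {atom_id}) outside the layout vocabulary"
                )
        if atom.atom_class not in layout.atom_classes:
            raise VocabularyError(
                f"atom class {atom.atom_class!r} (atom {atom_id}) outside the layout vocabulary"
            )
        if not include_zero_atoms and not np.any(vec):
            continue
        groups.setdefault((res, atom.atom_class), []).append(vec)

    keys: dict[tuple[str, str, str], float] = {}
    for (res, cls), vecs in groups.items():
        mat = np.vstack(vecs)
        for t, term in enumerate(INTERACTION_TERMS):
            col = mat[:, t]
            if positive_only:
                col = col[col > 0]
                if col.size == 0:
                    continue
            keys[(res, term, cls)] = float(np.mean(col))
    return StdPADIF(raw.molecule_id, keys, layout.layout_id)


def vectorize(std: StdPADIF, layout: PadifLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """Dense vector in canonical key order; absent keys are zero."""
    if std.layout_id != layout.layout_id:
        raise LayoutError(
            f"fingerprint layout {std.layout_id} does not match {layout.layout_id}"
        )
    vec = np.zeros(layout.size)
    for (res, term, cls), value in std.keys.items():
        vec[layout.index(res, term, cls)] = value
    return vec


def devectorize(
    vec: np.ndarray, layout: PadifLayout = DEFAULT_LAYOUT, molecule_id: str = ""
) -> StdPADIF:
    """Sparse map of the nonzero entries of a dense vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (layout.size,):
        raise LayoutError(f"vector length {vec.shape} does not match layout size {layout.size}")
    keys = {key: float(v) for key, v in zip(layout.keys(), vec) if v != 0.0}
    return StdPADIF(molecule_id, keys, layout.layout_id)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of two fingerprint vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise LayoutError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


class PadifVectorizer(TransformerMixin, BaseEstimator):
    """Transform docking poses into dense standardized fingerprint rows.

    A scikit-learn transformer: ``transform`` maps a sequence of
    :class:`~padifwf.dock_io.PoseRecord` (one per molecule; use
    ``best_pose_only=True`` to reduce a multi-pose collection first) to an
    ``(n_molecules, layout.size)`` array.

    Parameters
    ----------
    protein : mapping of atom_id -> ProteinAtom
        Receptor atom table shared by all poses.
    layout : PadifLayout, optional
        Key-space layout (default: 20 residues x 8 terms x 5 classes, 800).
    best_pose_only : bool
        If True, ``transform`` accepts a multi-pose collection and keeps
        only the highest-scoring pose per molecule.
    include_zero_atoms, positive_only : bool
        Forwarded to :func:`standardize`.
    """

    def __init__(
        self,
        protein: Mapping[int, ProteinAtom] | None = None,
        layout: PadifLayout | None = None,
        best_pose_only: bool = False,
        include_zero_atoms: bool = True,
        positive_only: bool = False,
    ):
        self.protein = protein
        self.layout = layout
        self.best_pose_only = best_pose_only
        self.include_zero_atoms = include_zero_atoms
        self.positive_only = positive_only

    def fit(self, X: Sequence[PoseRecord], y=None) -> "PadifVectorizer":
        if self.protein is None:
            raise ValueError("PadifVectorizer requires a protein atom table")
        self.layout_ = self.layout or DEFAULT_LAYOUT
        self.n_features_out_ = self.layout_.size
        return self

    def transform(self, X: Sequence[PoseRecord]) -> np.ndarray:
        if not hasattr(self, "layout_"):
            self.fit(X)
        poses = list(best_poses(X).values()) if self.best_pose_only else list(X)
        rows = []
        self.molecule_ids_ = []
        for pose in poses:
            std = standardize(
                compute_raw_padif(pose),
                self.protein,
                self.layout_,
                include_zero_atoms=self.include_zero_atoms,
                positive_only=self.positive_only,
            )
            rows.append(vectorize(std, self.layout_))
            self.molecule_ids_.append(pose.molecule_id)
        if not rows:
            return np.empty((0, self.layout_.size))
        return np.vstack(rows)


def padif_matrix(
    poses: Iterable[PoseRecord],
    protein: Mapping[int, ProteinAtom],
    layout: PadifLayout = DEFAULT_LAYOUT,
    *,
    best_pose_only: bool = True,
    **std_kwargs,
) -> pd.DataFrame:
    """Fingerprint matrix as a DataFrame (rows: molecules, 800 columns)."""
    vec = PadifVectorizer(
        protein=protein, layout=layout, best_pose_only=best_pose_only, **std_kwargs
    ).fit([])
    mat = vec.transform(list(poses))
    return pd.DataFrame(mat, index=vec.molecule_ids_, columns=layout.column_names())


def write_std_csv(path: str | Path, frame: pd.DataFrame) -> None:
    """One row per molecule, canonical dense columns, 6-digit scores."""
    frame.to_csv(Path(path), index_label="molecule_id", float_format="%.6g")


def read_std_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), index_col="molecule_id")
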
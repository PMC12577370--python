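"""Read and write docking outputs carrying per-atom score contributions.

Two dialects are supported:

``fixture_table``
    The package's own strict TSV dialect (extension ``.padif.tsv``).  One
    ``POSE`` header line per docking solution (molecule id, pose index,
    total ChemPLP fitness), followed by one row per protein atom carrying
    the atom descriptor and the 8 interaction-term contributions, and
    optionally ``COORD`` rows with the ligand heavy-atom coordinates of
    that pose.  Scores are written with 6 significant digits, so a
    write -> read round trip is value-identical at that precision.

``gold_mol2``
    Best-effort reader for GOLD-style concatenated mol2 output with
    per-atom score comment blocks.  The on-disk layout of that output is
    not standardised; constructs outside the supported subset raise
    :class:`~padifwf.errors.ParseError` naming the offending line.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConsistencyError, EmptyInputError, ParseError, SchemaError
from .vocab import N_TERMS

__all__ = [
    "ProteinAtom",
    "PoseRecord",
    "read_per_atom_scores",
    "write_fixture",
    "select_best_pose",
    "best_poses",
]

FIXTURE_SUFFIX = ".padif.tsv"

#: significant digits used when writing score fields
SCORE_DIGITS = 6


@dataclass(frozen=True)
class ProteinAtom:
    """One receptor atom as seen by the scoring function."""

    atom_id: int
    residue_name: str
    residue_number: int
    chain_id: str
    atom_class: str


@dataclass
class PoseRecord:
    """One docking solution of one molecule.

    ``contributions`` maps protein ``atom_id`` to the 8-term contribution
    vector (canonical term order, see :data:`padifwf.vocab.INTERACTION_TERMS`).
    ``ligand_coords`` optionally carries the ligand heavy-atom coordinates
    (Å) in a fixed atom order shared by all poses of the molecule.
    """

    molecule_id: str
    pose_index: int
    total_score: float
    contributions: dict[int, np.ndarray] = field(default_factory=dict)
    ligand_coords: np.ndarray | None = None


def _fmt(x: float) -> str:
    return f"{x:.{SCORE_DIGITS}g}"


def round_sig(x: float, digits: int = SCORE_DIGITS) -> float:
    """Round to ``digits`` significant digits (text round-trip precision)."""
    return float(f"{x:.{digits}g}")


# ---------------------------------------------------------------------------
# fixture_table dialect


def write_fixture(
    path: str | Path,
    poses: Iterable[PoseRecord],
    protein: Mapping[int, ProteinAtom],
) -> None:
    """Write poses in the fixture TSV dialect.

    Every pose block repeats the atom descriptor columns; the reader checks
    they agree across poses.  Scores carry 6 significant digits, ligand
    coordinates 4 decimals.
    """
    path = Path(path)
    lines = ["# padifwf fixture v1"]
    for pose in poses:
        lines.append(
            "POSE\t{}\t{}\t{}".format(pose.molecule_id, pose.pose_index, _fmt(pose.total_score))
        )
        for atom_id in sorted(pose.contributions):
            atom = protein[atom_id]
            vals = "\t".join(_fmt(v) for v in pose.contributions[atom_id])
            lines.append(
                f"{atom.atom_id}\t{atom.residue_name}\t{atom.residue_number}\t"
                f"{atom.chain_id}\t{atom.atom_class}\t{vals}"
            )
        if pose.ligand_coords is not None:
            for xyz in np.asarray(pose.ligand_coords):
                lines.append("COORD\t" + "\t".join(f"{v:.4f}" for v in xyz))
    path.write_text("\n".join(lines) + "\n")


def _parse_fixture(path: Path, protein: dict[int, ProteinAtom] | None):
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"{path}: empty docking file")
    known: dict[int, ProteinAtom] = dict(protein) if protein else {}
    closed_table = protein is not None
    poses: list[PoseRecord] = []
    current: PoseRecord | None = None
    coords: list[list[float]] = []

    def flush() -> None:
        nonlocal coords
        if current is None:
            return
        if coords:
            current.ligand_coords = np.asarray(coords, dtype=float)
        coords = []
        poses.append(current)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "POSE":
            flush()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: POSE header needs 3 fields")
            try:
                current = PoseRecord(fields[1], int(fields[2]), float(fields[3]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad POSE header: {exc}") from None
        elif fields[0] == "COORD":
            if current is None:
                raise ParseError(f"{path}:{lineno}: COORD before any POSE header")
            try:
                coords.append([float(v) for v in fields[1:4]])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad coordinate row") from None
        else:
            if current is None:
                raise ParseError(f"{path}:{lineno}: atom row before any POSE header")
            if len(fields) != 5 + N_TERMS:
                raise SchemaError(
                    f"{path}:{lineno}: atom row needs {5 + N_TERMS} columns, got {len(fields)}"
                )
            try:
                atom = ProteinAtom(
                    int(fields[0]), fields[1], int(fields[2]), fields[3], fields[4]
                )
                values = np.array([float(v) for v in fields[5:]], dtype=float)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad atom row: {exc}") from None
            prior = known.get(atom.atom_id)
            if prior is None:
                if closed_table:
                    raise ConsistencyError(
                        f"{path}:{lineno}: atom_id {atom.atom_id} absent from the protein table"
                    )
                known[atom.atom_id] = atom
            elif prior != atom:
                raise ConsistencyError(
                    f"{path}:{lineno}: atom_id {atom.atom_id} descriptor disagrees "
                    f"with earlier pose ({prior} != {atom})"
                )
            if atom.atom_id in current.contributions:
                raise ConsistencyError(
                    f"{path}:{lineno}: duplicate atom_id {atom.atom_id} within a pose"
                )
            current.contributions[atom.atom_id] = values
    flush()
    if not poses:
        raise EmptyInputError(f"{path}: no pose blocks found")
    return poses, known


# ---------------------------------------------------------------------------
# gold_mol2 dialect (best effort)

_TRIPOS_RE = re.compile(r"^@<TRIPOS>(\w+)")
_TAG_RE = re.compile(r"^>\s*<(?P<tag>[^>]+)>\s*$")


def _parse_gold_mol2(path: Path):
    """Best-effort reader for GOLD concatenated mol2 with per-atom scores.

    Supported subset: molecules delimited by ``@<TRIPOS>MOLECULE``; a
    ``@<TRIPOS>COMMENT`` section per molecule containing a
    ``> <Gold.PLP.Fitness>`` tag followed by the fitness value and a
    ``> <Gold.Protein.ScoreContributions>`` tag followed by a header line
    (atom_id residue_name residue_number chain atom_class + 8 term columns)
    and one data row per contributing protein atom.
    """
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"{path}: empty docking file")
    lines = text.splitlines()
    poses: list[PoseRecord] = []
    protein: dict[int, ProteinAtom] = {}
    pose_counter: dict[str, int] = {}

    i = 0
    n = len(lines)
    while i < n:
        m = _TRIPOS_RE.match(lines[i])
        if not (m and m.group(1) == "MOLECULE"):
            i += 1
            continue
        if i + 1 >= n:
            raise ParseError(f"{path}:{i + 1}: MOLECULE record without a name line")
        name = lines[i + 1].strip()
        mol_id, pose_index = name, None
        if "|" in name:  # GOLD solution naming: <id>|<...>|<solution #>
            parts = name.split("|")
            mol_id = parts[0]
            try:
                pose_index = int(parts[-1])
            except ValueError:
                pose_index = None
        i += 2
        fitness = None
        contributions: dict[int, np.ndarray] = {}
        while i < n:
            mm = _TRIPOS_RE.match(lines[i])
            if mm and mm.group(1) == "MOLECULE":
                break
            tag = _TAG_RE.match(lines[i].strip())
            if tag and tag.group("tag") == "Gold.PLP.Fitness":
                if i + 1 >= n:
                    raise ParseError(f"{path}:{i + 1}: fitness tag without a value line")
                try:
                    fitness = float(lines[i + 1].strip())
                except ValueError:
                    raise ParseError(f"{path}:{i + 2}: bad fitness value") from None
                i += 2
                continue
            if tag and tag.group("tag") == "Gold.Protein.ScoreContributions":
                i += 1
                if i >= n:
                    raise ParseError(f"{path}:{i}: contributions tag without a header")
                header = lines[i].split()
                if len(header) != 5 + N_TERMS:
                    raise ParseError(
                        f"{path}:{i + 1}: unsupported contributions header "
                        f"({len(header)} columns; expected {5 + N_TERMS})"
                    )
                i += 1
                while i < n and lines[i].strip() and not lines[i].startswith(("@", ">")):
                    row = lines[i].split()
                    if len(row) != 5 + N_TERMS:
                        raise ParseError(f"{path}:{i + 1}: bad contributions row")
                    atom = ProteinAtom(int(row[0]), row[1], int(row[2]), row[3], row[4])
                    prior = protein.get(atom.atom_id)
                    if prior is None:
                        protein[atom.atom_id] = atom
                    elif prior != atom:
                        raise ConsistencyError(
                            f"{path}:{i + 1}: atom {atom.atom_id} descriptor disagrees across poses"
                        )
                    contributions[atom.atom_id] = np.array([float(v) for v in row[5:]])
                    i += 1
                continue
            if tag:
                # other Gold.* annotation: skip the tag and its value block
                i += 1
                while i < n and lines[i].strip() and not lines[i].startswith(("@", ">")):
                    i += 1
                continue
            i += 1
        if fitness is None:
            raise ParseError(f"{path}: molecule {name!r} has no Gold.PLP.Fitness tag")
        if pose_index is None:
            pose_index = pose_counter.get(mol_id, 0)
        pose_counter[mol_id] = pose_index + 1
        poses.append(PoseRecord(mol_id, pose_index, fitness, contributions))
    if not poses:
        raise EmptyInputError(f"{path}: no MOLECULE blocks found")
    return poses, protein


# ---------------------------------------------------------------------------
# public API


def read_per_atom_scores(
    path: str | Path,
    dialect: str = "fixture_table",
    protein: Mapping[int, ProteinAtom] | None = None,
) -> tuple[list[PoseRecord], dict[int, ProteinAtom]]:
    """Read a docking output file with per-atom score contributions.

    Parameters
    ----------
    path : path
        Input file.
    dialect : {"fixture_table", "gold_mol2"}
        On-disk dialect (see module docstring).
    protein : mapping, optional
        Pre-declared protein atom table.  When given, pose rows referencing
        unknown atom ids raise :class:`ConsistencyError`; otherwise the
        table is accumulated from the file (first occurrence wins, later
        disagreement is an error — a docking run has one rigid receptor).

    Returns
    -------
    (poses, protein) : list of PoseRecord, dict of atom_id -> ProteinAtom
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "fixture_table":
        return _parse_fixture(path, dict(protein) if protein else None)
    if dialect == "gold_mol2":
        if protein is not None:
            raise ParseError("gold_mol2 dialect accumulates its own protein table")
        return _parse_gold_mol2(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def select_best_pose(poses: Sequence[PoseRecord]) -> PoseRecord:
    """The pose with the highest total ChemPLP fitness.

    Ties are broken deterministically toward the lowest pose index.  All
    poses must belong to one molecule.
    """
    if len(poses) == 0:
        raise EmptyInputError("select_best_pose: empty pose collection")
    ids = {p.molecule_id for p in poses}
    if len(ids) > 1:
        raise ConsistencyError(f"select_best_pose: mixed molecule ids {sorted(ids)}")
    best = poses[0]
    for p in poses[1:]:
        if p.total_score > best.total_score or (
            p.total_score == best.total_score and p.pose_index < best.pose_index
        ):
            best = p
    if math.isnan(best.total_score):
        raise ConsistencyError("select_best_pose: NaN total_score")
    return best


def group_poses(poses: Iterable[PoseRecord]) -> dict[str, list[PoseRecord]]:
    """Group a flat pose list by molecule id, preserving file order."""
    out: dict[str, list[PoseRecord]] = {}
    for p in poses:
        out.setdefault(p.molecule_id, []).append(p)
    return out


def best_poses(poses: Iterable[PoseRecord]) -> dict[str, PoseRecord]:
    """Best pose per molecule (highest fitness, lowest-index tie-break)."""
    return {mid: select_best_pose(ps) for mid, ps in group_poses(poses).items()}
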
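"""Canonical vocabularies and the dense fingerprint layout.

The fingerprint key space is the Cartesian product residue x interaction
term x atom class.  With the default vocabularies (20 standard amino acids,
8 ChemPLP interaction terms, 5 atom classes) that is 800 keys.  The dense
layout enumerates the product residue-major, term middle, atom-class minor,
and is identified by a short hash so sparse maps and dense vectors can be
checked for compatibility.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterator

from .errors import LayoutError, VocabularyError

#: The eight ChemPLP per-atom interaction terms, in canonical order.  The
#: first three are the ChemScore-derived terms whose sign is inverted during
#: fingerprint construction; the last five are the piecewise-linear-potential
#: (PLP) surface terms.
INTERACTION_TERMS: tuple[str, ...] = (
    "ChemScore.PLP.Hbond",
    "ChemScore.PLP.CHO",
    "ChemScore.PLP.Metal",
    "PLP.S(bond)",
    "PLP.S(metal)",
    "PLP.S(buried)",
    "PLP.S(nonpolar)",
    "PLP.S(repulsive)",
)

#: Short labels used in column names (RES_TERM_CLASS) and reports.
TERM_LABELS: tuple[str, ...] = (
    "Hbond",
    "CHO",
    "Metal",
    "Sbond",
    "Smetal",
    "Sburied",
    "Snonpolar",
    "Srepulsive",
)

N_TERMS = len(INTERACTION_TERMS)

#: Number of leading terms whose sign is inverted during standardization.
N_INVERTED_TERMS = 3

#: The 20 standard amino acids (alphabetical three-letter codes).
STANDARD_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Default protein atom classes.  The scoring function distinguishes
#: hydrogen-bond donors, acceptors, ambivalent donor/acceptor atoms,
#: nonpolar atoms and metals.
DEFAULT_ATOM_CLASSES: tuple[str, ...] = (
    "DONOR", "ACCEPTOR", "DONACC", "NONPOLAR", "METAL",
)

#: Bucket label for nonstandard residues when the relaxed policy is enabled.
OTHER_RESIDUE = "OTHER"


@dataclass(frozen=True)
class PadifLayout:
    """Dense enumeration of the (residue, term, atom class) key space.

    Parameters
    ----------
    residues : tuple of str
        Residue vocabulary (default: the 20 standard amino acids).
    atom_classes : tuple of str
        Atom-class vocabulary (default: 5 classes).

    The interaction-term axis is fixed to :data:`INTERACTION_TERMS`.
    """

    residues: tuple[str, ...] = STANDARD_RESIDUES
    atom_classes: tuple[str, ...] = DEFAULT_ATOM_CLASSES
    layout_id: str = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise VocabularyError("duplicate residue labels in layout")
        if len(set(self.atom_classes)) != len(self.atom_classes):
            raise VocabularyError("duplicate atom-class labels in layout")
        digest = hashlib.sha1(
            ("|".join(self.residues) + "#" + "|".join(self.atom_classes)).encode()
        ).hexdigest()[:12]
        object.__setattr__(self, "layout_id", digest)

    @property
    def terms(self) -> tuple[str, ...]:
        return INTERACTION_TERMS

    @property
    def size(self) -> int:
        return len(self.residues) * N_TERMS * len(self.atom_classes)

    def index(self, residue: str, term: str, atom_class: str) -> int:
        """Dense index of a key: residue-major, term middle, class minor."""
        try:
            r = self.residues.index(residue)
        except ValueError:
            raise VocabularyError(f"residue {residue!r} not in layout") from None
        try:
            t = INTERACTION_TERMS.index(term)
        except ValueError:
            raise LayoutError(f"unknown interaction term {term!r}") from None
        try:
            c = self.atom_classes.index(atom_class)
        except ValueError:
            raise VocabularyError(f"atom class {atom_class!r} not in layout") from None
        return (r * N_TERMS + t) * len(self.atom_classes) + c

    def keys(self) -> Iterator[tuple[str, str, str]]:
        """All keys in dense order."""
        for res in self.residues:
            for term in INTERACTION_TERMS:
                for cls in self.atom_classes:
                    yield (res, term, cls)

    def column_names(self) -> list[str]:
        """``RES_TERM_CLASS`` column names in dense order."""
        return [
            f"{res}_{TERM_LABELS[INTERACTION_TERMS.index(term)]}_{cls}"
            for res, term, cls in self.keys()
        ]

    def with_other_residue(self) -> "PadifLayout":
        """Layout extended with the OTHER bucket for nonstandard residues."""
        if OTHER_RESIDUE in self.residues:
            return self
        return PadifLayout(self.residues + (OTHER_RESIDUE,), self.atom_classes)


DEFAULT_LAYOUT = PadifLayout()
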
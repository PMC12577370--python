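"""Classification and screening-power metrics.

Implements the four quality metrics of the workflow:

* F1 = TP / (TP + (FP + FN)/2) — guides hyperparameter selection.
* Balanced accuracy = (TP/P + TN/N) / 2 — robust to class imbalance.
* Enrichment factor EF_x% = (N_active,x% / N_total,x%) / (N_actives / N_total),
  the improvement over random selection in the top x% of a score-ranked
  list.  The top-fraction size is ceil(x/100 * N_total) so the selection is
  never empty.
* Normalized enrichment factor NEF_x% = EF_x% / EF(max)_x%, where
  EF(max)_x% = (min(N_total,x%, N_actives) / N_total,x%) / (N_actives / N_total)
  is the saturation bound reached when every top slot that can hold an
  active does.  NEF lies in [0, 1].

Ranking ties are resolved by an explicit policy: ``pessimistic`` (default)
places tied actives below tied decoys, giving a conservative enrichment
estimate; ``optimistic`` is the reverse.

Undefined metrics (zero denominators, rankings with no actives) are
reported as missing (``None``), never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .padif import StdPADIF
from .vocab import DEFAULT_LAYOUT, INTERACTION_TERMS, PadifLayout, TERM_LABELS

__all__ = [
    "ConfusionCounts",
    "confusion",
    "f1",
    "balanced_accuracy",
    "rank_order",
    "enrichment_factor",
    "ef_max",
    "nef",
    "RankingMetrics",
    "ranking_metrics",
    "interaction_profile",
]

TIE_POLICIES = ("pessimistic", "optimistic")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-table counts (positives = actives)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.p + self.n


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Count TP/FP/TN/FN for binary labels (1 = active)."""
    y = np.asarray(labels)
    yhat = np.asarray(predictions)
    if y.size == 0:
        raise ConsistencyError("confusion: empty input")
    if y.shape != yhat.shape:
        raise ConsistencyError(f"confusion: length mismatch {y.shape} vs {yhat.shape}")
    if not set(np.unique(y)) <= {0, 1} or not set(np.unique(yhat)) <= {0, 1}:
        raise ConsistencyError("confusion: labels and predictions must be binary 0/1")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    return ConfusionCounts(tp, fp, tn, fn)


def f1(c: ConfusionCounts) -> float | None:
    """F1 score; None (missing) when TP, FP and FN are all zero."""
    denom = c.tp + 0.5 * (c.fp + c.fn)
    if denom == 0:
        return None
    return c.tp / denom


def balanced_accuracy(c: ConfusionCounts) -> float | None:
    """Mean of sensitivity and specificity; None when a class is absent."""
    if c.p == 0 or c.n == 0:
        return None
    return 0.5 * (c.tp / c.p + c.tn / c.n)


def rank_order(
    scores: Sequence[float], labels: Sequence[int], tie_policy: str = "pessimistic"
) -> np.ndarray:
    """Indices ordering records best-first under the declared tie policy."""
    if tie_policy not in TIE_POLICIES:
        raise ParameterError(f"unknown tie policy {tie_policy!r}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ConsistencyError("rank_order: length mismatch")
    # pessimistic: at equal score decoys (0) come first; optimistic: actives.
    tie_key = y if tie_policy == "pessimistic" else -y
    return np.lexsort((np.arange(s.size), tie_key, -s))


def _check_fraction(x: float) -> None:
    if not 0 < x <= 100:
        raise ParameterError(f"fraction x must be in (0, 100], got {x}")


def enrichment_factor(
    labels: Sequence[int],
    scores: Sequence[float],
    x: float,
    tie_policy: str = "pessimistic",
) -> float | None:
    """EF at the top x% of the score-ranked list; None with no actives."""
    _check_fraction(x)
    y = np.asarray(labels)
    n_total = y.size
    n_actives = int(np.sum(y == 1))
    if n_total == 0 or n_actives == 0:
        return None
    order = rank_order(scores, y, tie_policy)
    n_top = math.ceil(x / 100 * n_total)
    hits = int(np.sum(y[order[:n_top]] == 1))
    return (hits / n_top) / (n_actives / n_total)


def ef_max(n_total: int, n_actives: int, x: float) -> float:
    """Largest EF attainable at fraction x with the given composition."""
    _check_fraction(x)
    n_top = math.ceil(x / 100 * n_total)
    return (min(n_top, n_actives) / n_top) / (n_actives / n_total)


def nef(
    labels: Sequence[int],
    scores: Sequence[float],
    x: float,
    tie_policy: str = "pessimistic",
) -> float | None:
    """Normalized EF in [0, 1]; 1 means a saturated top fraction."""
    ef = enrichment_factor(labels, scores, x, tie_policy)
    if ef is None:
        return None
    y = np.asarray(labels)
    return ef / ef_max(y.size, int(np.sum(y == 1)), x)


@dataclass(frozen=True)
class RankingMetrics:
    """EF and NEF at one fraction, with the normalization recorded."""

    fraction: float
    ef: float | None
    ef_max: float
    nef: float | None
    tie_policy: str


def ranking_metrics(
    labels: Sequence[int],
    scores: Sequence[float],
    fractions: Iterable[float] = (1.0, 20.0),
    tie_policy: str = "pessimistic",
) -> list[RankingMetrics]:
    """EF/NEF at each requested fraction for one scored, labeled list."""
    y = np.asarray(labels)
    n_act = int(np.sum(y == 1))
    out = []
    for x in fractions:
        ef = enrichment_factor(y, scores, x, tie_policy)
        emax = ef_max(y.size, n_act, x) if n_act else float("nan")
        out.append(
            RankingMetrics(x, ef, emax, None if ef is None else ef / emax, tie_policy)
        )
    return out


def interaction_profile(
    padifs: Sequence[StdPADIF],
    group_labels: Sequence[str],
    layout: PadifLayout = DEFAULT_LAYOUT,
) -> pd.DataFrame:
    """Mean interaction term per atom class, per group, residues marginalized.

    For each molecule and each (term, atom class) pair the residue axis is
    collapsed by averaging the keys present in the sparse fingerprint; the
    group profile is the mean over its molecules.  Pairs no molecule of a
    group touches are missing (NaN); an empty group yields an all-missing
    row.

    Returns a DataFrame indexed by group label with a (term, atom class)
    column MultiIndex — the per-target interaction-frequency summary used
    to compare decoy strategies.
    """
    if len(padifs) != len(group_labels):
        raise ConsistencyError("interaction_profile: length mismatch")
    cols = pd.MultiIndex.from_product(
        [TERM_LABELS, layout.atom_classes], names=["term", "atom_class"]
    )
    term_label = dict(zip(INTERACTION_TERMS, TERM_LABELS))
    per_mol = []
    for std in padifs:
        acc: dict[tuple[str, str], list[float]] = {}
        for (res, term, cls), v in std.keys.items():
            acc.setdefault((term_label[term], cls), []).append(v)
        per_mol.append({k: float(np.mean(vs)) for k, vs in acc.items()})
    frame = pd.DataFrame(per_mol, index=range(len(per_mol))).reindex(columns=cols)
    profile = frame.groupby(np.asarray(group_labels)).mean()
    profile = profile.reindex(sorted(set(group_labels)))
    profile.columns = cols
    profile.index.name = "group"
    return profile
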
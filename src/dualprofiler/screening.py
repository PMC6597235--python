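"""Dock-score ranking, dual-target consensus, ΔG→pKd and enrichment.

Dock scores are pose-ranking energies where more negative is better. The
dual-target selection intersects each target's top-k ranked compounds
(k = 20 in the study configuration). Binding free energies convert to
dissociation constants through ΔG = −RT·ln Kd, i.e.
pKd = −ΔG / (ln10·R·T) with R = 1.9872×10⁻³ kcal/(mol·K).

The enrichment factor at a fraction f of a ranked database of N compounds
containing H actives is

    EF = (hits_sample / n_sample) / (H / N),   n_sample = ⌊f·N⌋,

so a uniformly random ranking gives EF = 1 in expectation and a perfect
ranking gives EF = min(N/n_sample, N/H).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ConsensusResult",
    "EnrichmentResult",
    "rank_compounds",
    "consensus_topk",
    "energy_to_pkd",
    "enrichment_factor",
    "enrichment_curve",
]

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass
class ConsensusResult:
    k: int
    rankings: dict[str, list]
    intersection: list = field(default_factory=list)


@dataclass
class EnrichmentResult:
    fraction_level: float
    hits_sample: int
    n_sample: int
    hits_database: int
    n_database: int
    ef: float
    curve: list[tuple[float, float]] = field(default_factory=list)


def rank_compounds(table: pd.DataFrame, target_id: str) -> list:
    """Compounds for one target ordered best-first (ascending dock score).

    Ties break deterministically by ascending compound id. The table needs
    columns ``compound_id``, ``target_id`` and ``dock_score``.
    """
    rows = table[table["target_id"] == target_id]
    if rows.empty:
        raise ValueError(f"no rows for target {target_id!r}")
    if rows["compound_id"].duplicated().any():
        raise ValueError(f"duplicate compound ids for target {target_id!r}")
    ordered = rows.sort_values(["dock_score", "compound_id"], kind="mergesort")
    return ordered["compound_id"].tolist()


def consensus_topk(rankings: dict[str, list], k: int) -> ConsensusResult:
    """Intersection of each target's top-k lists, ordered by mean rank."""
    if len(rankings) < 2:
        raise ValueError("consensus needs rankings for at least two targets")
    if k < 1:
        raise ValueError("k must be >= 1")
    smallest = min(len(r) for r in rankings.values())
    if k > smallest:
        warnings.warn(f"k={k} exceeds smallest ranking ({smallest}); clamping")
        k = smallest
    top_sets = [set(r[:k]) for r in rankings.values()]
    common = set.intersection(*top_sets)
    mean_rank = {
        c: np.mean([r.index(c) for r in rankings.values()]) for c in common
    }
    ordered = sorted(common, key=lambda c: (mean_rank[c], str(c)))
    return ConsensusResult(k=k, rankings=rankings, intersection=ordered)


def energy_to_pkd(dg: float, temperature: float = 298.0) -> float:
    """pKd from a binding free energy in kcal/mol (rounded to 2 decimals)."""
    if dg > 0:
        warnings.warn("positive binding free energy gives a negative pKd")
    pkd = -dg / (math.log(10.0) * GAS_CONSTANT_KCAL * temperature)
    return round(pkd, 2)


def _as_bool_array(ranked_labels) -> np.ndarray:
    arr = np.asarray(ranked_labels)
    if arr.dtype.kind in "US":
        return arr == "active"
    return arr.astype(bool)


def enrichment_curve(ranked_labels) -> list[tuple[float, float]]:
    """Cumulative actives-found curve over a ranked active/decoy list.

    At each rank i the point is (i/N, actives in top i / total actives);
    the curve is non-decreasing and ends at (1, 1).
    """
    labels = _as_bool_array(ranked_labels)
    n = len(labels)
    if n == 0:
        raise ValueError("ranked label list is empty")
    total = labels.sum()
    if total == 0:
        raise ValueError("no actives in the ranked list")
    cum = np.cumsum(labels)
    return [(float((i + 1) / n), float(cum[i] / total)) for i in range(n)]


def enrichment_factor(ranked_labels, fraction: float) -> EnrichmentResult:
    """Enrichment factor at a subset level of the ranked database.

    ``ranked_labels`` is best-first, either booleans (True = active) or the
    strings ``"active"``/``"decoy"``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    labels = _as_bool_array(ranked_labels)
    n_db = len(labels)
    hits_db = int(labels.sum())
    if hits_db == 0:
        raise ValueError("enrichment undefined with zero actives in the database")
    n_sample = max(1, math.floor(fraction * n_db))
    hits_sample = int(labels[:n_sample].sum())
    ef = (hits_sample / n_sample) / (hits_db / n_db)
    return EnrichmentResult(
        fraction_level=fraction,
        hits_sample=hits_sample,
        n_sample=n_sample,
        hits_database=hits_db,
        n_database=n_db,
        ef=ef,
        curve=enrichment_curve(labels),
    )
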
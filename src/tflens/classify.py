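"""Lineage classification of TFs from trimmed-mean internal Z scores.

A TF with trimmed-mean scores (Z_ad, Z_NE) and threshold θ (default 0.2) is

* ``SHARED``        iff Z_ad > θ and Z_NE > θ   (moderate-to-high in both)
* ``AD``            iff Z_ad - Z_NE > θ and Z_NE < θ
* ``NE``            iff Z_ad < θ and Z_NE - Z_ad > θ
* ``UNCLASSIFIED``  otherwise (including exact boundary ties).

For θ > 0 the three named predicates are pairwise mutually exclusive, so the
four categories partition the scored TFs. θ = 0.2 corresponds to roughly 20
normalized reads, the usual low-abundance filtering scale for bulk RNA-seq;
it is configurable per run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "SHARED", "AD", "NE", "UNCLASSIFIED",
    "DEFAULT_THETA",
    "TFClassification",
    "ConsolidatedSets",
    "classify_tf",
    "classify_all",
    "consolidate",
    "rank_within_lineage",
]

SHARED, AD, NE, UNCLASSIFIED = "SHARED", "AD", "NE", "UNCLASSIFIED"
CATEGORIES = (SHARED, AD, NE, UNCLASSIFIED)
DEFAULT_THETA = 0.2


def classify_tf(z_ad: float, z_ne: float, theta: float = DEFAULT_THETA) -> str:
    """Category of a single TF from its two lineage scores (strict inequalities)."""
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if not (math.isfinite(z_ad) and math.isfinite(z_ne)):
        raise ValueError(f"non-finite scores ({z_ad}, {z_ne})")
    if z_ad > theta and z_ne > theta:
        return SHARED
    if z_ad - z_ne > theta and z_ne < theta:
        return AD
    if z_ad < theta and z_ne - z_ad > theta:
        return NE
    return UNCLASSIFIED


@dataclass
class TFClassification:
    """Per-TF category assignment for one cohort."""

    table: pd.DataFrame  # index tf; columns Z_ad, Z_NE, category
    theta: float
    cohort_id: str = "cohort"

    def members(self, category: str) -> list[str]:
        return self.table.index[self.table["category"] == category].tolist()

    def counts(self) -> dict[str, int]:
        return {c: int((self.table["category"] == c).sum()) for c in CATEGORIES}


def classify_all(
    scores: pd.DataFrame,
    theta: float = DEFAULT_THETA,
    cohort_id: str = "cohort",
) -> TFClassification:
    """Vectorised application of the grouping criteria to a GroupScoreTable."""
    if scores.empty:
        raise ValueError("empty score table")
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    z_ad = scores["Z_ad"].to_numpy(dtype=float)
    z_ne = scores["Z_NE"].to_numpy(dtype=float)
    if not (np.isfinite(z_ad).all() and np.isfinite(z_ne).all()):
        raise ValueError("non-finite lineage scores")
    category = np.full(len(scores), UNCLASSIFIED, dtype=object)
    category[(z_ad < theta) & (z_ne - z_ad > theta)] = NE
    category[(z_ad - z_ne > theta) & (z_ne < theta)] = AD
    category[(z_ad > theta) & (z_ne > theta)] = SHARED
    table = pd.DataFrame(
        {"Z_ad": z_ad, "Z_NE": z_ne, "category": category}, index=scores.index
    )
    table.index.name = "tf"
    cls = TFClassification(table, theta=theta, cohort_id=cohort_id)
    logger.info("cohort %s classification: %s", cohort_id, cls.counts())
    return cls


@dataclass
class ConsolidatedSets:
    """Cross-cohort intersection of the three lineage TF sets."""

    sets: dict[str, list[str]]  # SHARED/AD/NE -> ordered TF list
    cohort_ids: list[str]
    per_cohort_sizes: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_gene_sets(self, prefix: str = "") -> list[GeneSet]:
        out = []
        for cat in (SHARED, AD, NE):
            members = self.sets.get(cat, [])
            if members:
                out.append(GeneSet(name=f"{prefix}{cat}_TFS",
                                   description=",".join(self.cohort_ids),
                                   members=members))
        return out


def consolidate(classifications: Sequence[TFClassification]) -> ConsolidatedSets:
    """Intersect each lineage set across >= 2 cohorts.

    TFs missing from any cohort's table are dropped from consolidation (and
    logged). Output lists are sorted alphabetically (deterministic; use
    :func:`rank_within_lineage` for score-ordered lists).
    """
    if len(classifications) < 2:
        raise ValueError(
            "consolidation needs at least two cohorts; with a single cohort "
            "use its classification directly"
        )
    universe = set(classifications[0].table.index)
    for cls in classifications[1:]:
        universe &= set(cls.table.index)
    dropped = set().union(*(set(c.table.index) for c in classifications)) - universe
    if dropped:
        logger.warning("consolidate: %d TFs absent from some cohort dropped", len(dropped))
    sets: dict[str, list[str]] = {}
    for cat in (SHARED, AD, NE):
        common = universe.copy()
        for cls in classifications:
            common &= set(cls.members(cat))
        sets[cat] = sorted(common)
    return ConsolidatedSets(
        sets=sets,
        cohort_ids=[c.cohort_id for c in classifications],
        per_cohort_sizes={
            c.cohort_id: {cat: len(c.members(cat)) for cat in (SHARED, AD, NE)}
            for c in classifications
        },
    )


def rank_within_lineage(
    cls: TFClassification | ConsolidatedSets,
    tables: Sequence[pd.DataFrame] | pd.DataFrame,
) -> dict[str, list[tuple[str, float]]]:
    """Order each lineage set by its defining score, descending.

    AD by Z_ad, NE by Z_NE, SHARED by min(Z_ad, Z_NE); with several cohorts
    the per-cohort trimmed-mean scores are averaged first. Ties break
    alphabetically. Returns category -> ordered (tf, score) list.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if isinstance(cls, TFClassification):
        member_lists = {cat: cls.members(cat) for cat in (SHARED, AD, NE)}
    else:
        member_lists = {cat: list(cls.sets.get(cat, [])) for cat in (SHARED, AD, NE)}

    def mean_score(tf: str, col: str) -> float:
        vals = []
        for i, tbl in enumerate(tables):
            if tf not in tbl.index:
                raise ValueError(f"TF {tf!r} missing a score in cohort table {i}")
            vals.append(float(tbl.loc[tf, col]))
        return float(np.mean(vals))

    ranked: dict[str, list[tuple[str, float]]] = {}
    for cat, members in member_lists.items():
        scored: list[tuple[str, float]] = []
        for tf in members:
            if cat == AD:
                s = mean_score(tf, "Z_ad")
            elif cat == NE:
                s = mean_score(tf, "Z_NE")
            else:
                s = min(mean_score(tf, "Z_ad"), mean_score(tf, "Z_NE"))
            scored.append((tf, s))
        scored.sort(key=lambda t: (-t[1], t[0]))
        ranked[cat] = scored
    return ranked
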
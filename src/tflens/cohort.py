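"""Marker-panel pre-selection of clean lineage samples.

Before TF scoring, cohorts are screened for unambiguous AR+/NE- adenocarcinoma
and AR-/NE+ neuroendocrine samples using two small marker panels scored on the
internal Z matrix (so selection inherits the per-sample scale invariance of
the score itself). Double-positive and double-negative samples are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .io import normalize_symbol
from .zscore import ADENO, EXCLUDED, NEPC, InternalZMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerPanel",
    "LineageLabels",
    "DEFAULT_AR_PANEL",
    "DEFAULT_NE_PANEL",
    "panel_score",
    "assign_lineage",
]


@dataclass
class MarkerPanel:
    """A named panel of lineage marker genes (e.g. the AR axis)."""

    name: str
    members: list[str]

    def __post_init__(self) -> None:
        normed = [normalize_symbol(m) for m in self.members]
        seen: set[str] = set()
        self.members = [m for m in normed if not (m in seen or seen.add(m))]
        if not self.members:
            raise ValueError(f"marker panel {self.name!r} is empty")


#: AR-pathway and NE-phenotype indicator genes (AR / PSA, CHGA / CD56);
#: overridable per run.
DEFAULT_AR_PANEL = MarkerPanel("AR_axis", ["AR", "KLK3"])
DEFAULT_NE_PANEL = MarkerPanel("NE_axis", ["CHGA", "NCAM1"])


@dataclass
class LineageLabels:
    """Sample -> {ADENO, NEPC, EXCLUDED} assignment with selection parameters."""

    mapping: dict[str, str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s: g for s, g in self.mapping.items() if g not in (ADENO, NEPC, EXCLUDED)}
        if bad:
            raise ValueError(f"unknown lineage labels: {bad}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.mapping, name="group")

    def counts(self) -> dict[str, int]:
        s = self.as_series()
        return {g: int((s == g).sum()) for g in (ADENO, NEPC, EXCLUDED)}

    def __getitem__(self, sample: str) -> str:
        return self.mapping[sample]


def panel_score(zmat: InternalZMatrix, panel: MarkerPanel) -> pd.Series:
    """Per-sample mean internal Z over the panel genes present in the matrix.

    Absent panel genes are reported in a warning; at least one must be present.
    """
    present = [g for g in panel.members if g in zmat.z.index]
    absent = [g for g in panel.members if g not in zmat.z.index]
    if not present:
        raise ValueError(f"no gene of panel {panel.name!r} present in the matrix")
    if absent:
        logger.warning("panel %s: %d/%d genes absent: %s",
                       panel.name, len(absent), len(panel.members), absent)
    scores = zmat.z.loc[present].mean(axis=0)
    scores.name = panel.name
    return scores


def assign_lineage(
    ar_scores: Mapping[str, float] | pd.Series,
    ne_scores: Mapping[str, float] | pd.Series,
    threshold: float = 0.0,
) -> LineageLabels:
    """Classify samples as ADENO (AR+/NE-), NEPC (AR-/NE+) or EXCLUDED.

    ADENO iff ar >= threshold and ne < threshold; NEPC iff ne >= threshold and
    ar < threshold; double-positive and double-negative samples are EXCLUDED.
    """
    ar = pd.Series(dict(ar_scores)) if not isinstance(ar_scores, pd.Series) else ar_scores
    ne = pd.Series(dict(ne_scores)) if not isinstance(ne_scores, pd.Series) else ne_scores
    if set(ar.index) != set(ne.index):
        only_ar = sorted(set(ar.index) - set(ne.index))
        only_ne = sorted(set(ne.index) - set(ar.index))
        raise ValueError(
            f"score vectors cover different samples (AR-only: {only_ar}, "
            f"NE-only: {only_ne})"
        )
    mapping: dict[str, str] = {}
    for sample in ar.index:
        a, n = float(ar[sample]), float(ne[sample])
        if a >= threshold and n < threshold:
            mapping[sample] = ADENO
        elif n >= threshold and a < threshold:
            mapping[sample] = NEPC
        else:
            mapping[sample] = EXCLUDED
    labels = LineageLabels(mapping, params={"threshold": threshold})
    logger.info("lineage selection: %s", labels.counts())
    return labels
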
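"""Longitudinal internal-Z analysis of a transdifferentiation series.

An ordered series of expression profiles (e.g. a patient-derived xenograft
followed from its adenocarcinoma baseline through post-castration dormancy to
neuroendocrine relapse) is scored per timepoint: internal Z per sample, then
a trimmed mean over a timepoint's replicates (a single-graft timepoint keeps
its value). Lineage-set trajectories segment the series into ADENO-like,
dormant and NE-like phases, and the dormancy screen flags TFs whose score at
the dormant timepoint clears an absolute floor and exceeds both terminal
stages by a margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, TFCatalog, subset_by_catalog
from .zscore import DEFAULT_TRIM, compute_internal_z, trimmed_mean

logger = logging.getLogger(__name__)

__all__ = [
    "ADENO_LIKE", "DORMANT", "NE_LIKE",
    "TimeSeriesScores",
    "PhaseSegmentation",
    "DormancyScreenResult",
    "SeriesModel",
    "SeriesResults",
    "series_scores",
    "set_trajectory",
    "assign_phases",
    "screen_dormant",
]

ADENO_LIKE, DORMANT, NE_LIKE = "ADENO_LIKE", "DORMANT", "NE_LIKE"


@dataclass
class TimeSeriesScores:
    """TF x timepoint internal-Z scores for an ordered series."""

    scores: pd.DataFrame  # index tf, columns ordered timepoint ids
    replicates: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scores.shape[1] < 3:
            raise ValueError("a series needs at least 3 timepoints")
        if self.scores.isna().to_numpy().any():
            raise ValueError("every TF must be scored at every timepoint")

    @property
    def timepoints(self) -> list[str]:
        return list(self.scores.columns)


def series_scores(
    series: Sequence[ExpressionMatrix],
    timepoint_ids: Sequence[str],
    catalog: TFCatalog | None = None,
    log2_transform: bool = True,
    trim_total: float = DEFAULT_TRIM,
) -> TimeSeriesScores:
    """Score an ordered series of matrices (one matrix per timepoint).

    All matrices are cut to the shared (catalog-subset) gene universe; genes
    absent anywhere are dropped and reported. A timepoint's score per TF is
    the trimmed mean over its sample columns (the value itself when n = 1).
    """
    if len(series) < 3:
        raise ValueError("a series needs at least 3 timepoints")
    if len(series) != len(timepoint_ids):
        raise ValueError("one timepoint id per matrix required")
    if len(set(timepoint_ids)) != len(timepoint_ids):
        raise ValueError("timepoint ids must be unique")
    for tp, m in zip(timepoint_ids, series):
        if m.shape[1] < 1:
            raise ValueError(f"timepoint {tp!r} has no samples")

    subsets = []
    for m in series:
        sub, _ = subset_by_catalog(m, catalog) if catalog is not None else (m, [])
        subsets.append(sub)
    shared = set(subsets[0].gene_ids)
    for sub in subsets[1:]:
        shared &= set(sub.gene_ids)
    if not shared:
        raise ValueError("no gene shared across all timepoints")
    order = [g for g in subsets[0].gene_ids if g in shared]
    dropped = sorted(set().union(*(set(s.gene_ids) for s in subsets)) - shared)
    if dropped:
        logger.warning("series: %d TFs absent from some timepoint dropped", len(dropped))

    cols: dict[str, np.ndarray] = {}
    replicates: dict[str, int] = {}
    for tp, sub in zip(timepoint_ids, subsets):
        cut = ExpressionMatrix(
            sub.values.loc[order],
            unit_tag=sub.unit_tag,
            log_transformed=sub.log_transformed,
        )
        zmat = compute_internal_z(cut, log2_transform=log2_transform)
        block = zmat.z.to_numpy()
        replicates[tp] = block.shape[1]
        if block.shape[1] == 1:
            cols[tp] = block[:, 0]
        else:
            cols[tp] = np.apply_along_axis(trimmed_mean, 1, block, trim_total)
    scores = pd.DataFrame(cols, index=order)
    scores.index.name = "tf"
    return TimeSeriesScores(
        scores,
        replicates=replicates,
        provenance={
            "log2_transform": log2_transform,
            "trim_total": trim_total,
            "dropped": dropped,
        },
    )


def set_trajectory(tf_set: GeneSet | Sequence[str], ts: TimeSeriesScores) -> pd.Series:
    """Unweighted mean score of a TF set at each timepoint.

    Coverage (members found / total) is logged; the intersection with the
    scored TFs must be non-empty.
    """
    members = tf_set.members if isinstance(tf_set, GeneSet) else list(tf_set)
    present = [m for m in members if m in ts.scores.index]
    if not present:
        raise ValueError("TF set has no member among the scored TFs")
    if len(present) < len(members):
        logger.warning(
            "set trajectory: coverage %d/%d members", len(present), len(members)
        )
    traj = ts.scores.loc[present].mean(axis=0)
    traj.name = getattr(tf_set, "name", "set")
    return traj


@dataclass
class PhaseSegmentation:
    """Per-timepoint phase labels with the trajectories that produced them."""

    phases: dict[str, str]  # timepoint -> phase
    ad_trajectory: pd.Series
    ne_trajectory: pd.Series
    threshold: float

    def transitions(self) -> list[tuple[str, str, str, str]]:
        """(from_tp, to_tp, from_phase, to_phase) for each phase change."""
        tps = list(self.phases)
        out = []
        for a, b in zip(tps, tps[1:]):
            if self.phases[a] != self.phases[b]:
                out.append((a, b, self.phases[a], self.phases[b]))
        return out


def assign_phases(
    ad_traj: pd.Series,
    ne_traj: pd.Series,
    threshold: float = 0.2,
) -> PhaseSegmentation:
    """Label each timepoint ADENO_LIKE, DORMANT or NE_LIKE.

    ADENO_LIKE iff the AD-set trajectory is >= threshold and the NE-set one
    below; NE_LIKE for the mirror; DORMANT when both programs sit below the
    threshold. Both programs high at once is not a state the three-phase
    model admits and raises, naming the timepoint.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if list(ad_traj.index) != list(ne_traj.index):
        raise ValueError("trajectories must share identical timepoints")
    phases: dict[str, str] = {}
    for tp in ad_traj.index:
        ad, ne = float(ad_traj[tp]), float(ne_traj[tp])
        if ad >= threshold and ne >= threshold:
            raise ValueError(
                f"timepoint {tp!r}: both lineage programs above threshold "
                f"(ad={ad:.3f}, ne={ne:.3f})"
            )
        if ad >= threshold:
            phases[tp] = ADENO_LIKE
        elif ne >= threshold:
            phases[tp] = NE_LIKE
        else:
            phases[tp] = DORMANT
    return PhaseSegmentation(phases, ad_traj, ne_traj, threshold)


@dataclass
class DormancyScreenResult:
    """TFs with elevated internal Z at the dormant timepoint.

    ``table`` is ordered by descending dormant-timepoint score and restricted
    to the flagged TFs; ``margins`` holds the score advantage over each
    terminal timepoint.
    """

    flagged: list[str]
    table: pd.DataFrame
    params: dict

    def __len__(self) -> int:
        return len(self.flagged)


def screen_dormant(
    ts: TimeSeriesScores,
    dormant_tp: str,
    terminal_tps: Sequence[str],
    delta: float = 0.2,
    floor: float = 0.2,
) -> DormancyScreenResult:
    """Flag TFs scoring high at the dormant timepoint relative to terminals.

    A TF is flagged iff its dormant-timepoint score exceeds ``floor`` and
    exceeds every terminal timepoint's score by more than ``delta``. Flagged
    TFs are ranked by descending dormant score.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if dormant_tp in terminal_tps:
        raise ValueError(f"dormant timepoint {dormant_tp!r} listed as terminal")
    for tp in (dormant_tp, *terminal_tps):
        if tp not in ts.scores.columns:
            raise ValueError(f"timepoint {tp!r} not in the scored series")
    z_dorm = ts.scores[dormant_tp]
    keep = z_dorm > floor
    margins = pd.DataFrame(index=ts.scores.index)
    for tp in terminal_tps:
        margins[f"margin_vs_{tp}"] = z_dorm - ts.scores[tp]
        keep &= margins[f"margin_vs_{tp}"] > delta
    flagged_idx = ts.scores.index[keep]
    table = pd.concat(
        [z_dorm.rename("Z_dormant"), margins], axis=1
    ).loc[flagged_idx].sort_values("Z_dormant", ascending=False)
    return DormancyScreenResult(
        flagged=list(table.index),
        table=table,
        params={
            "dormant_tp": dormant_tp,
            "terminal_tps": list(terminal_tps),
            "delta": delta,
            "floor": floor,
        },
    )


class SeriesModel:
    """Model object for an ordered transdifferentiation series.

    Wraps :func:`series_scores` / :func:`assign_phases` / :func:`screen_dormant`
    in the Model -> fit() -> Results shape.
    """

    def __init__(
        self,
        series: Sequence[ExpressionMatrix],
        timepoint_ids: Sequence[str],
        catalog: TFCatalog | None = None,
        log2_transform: bool = True,
        trim_total: float = DEFAULT_TRIM,
    ) -> None:
        self.series = list(series)
        self.timepoint_ids = list(timepoint_ids)
        self.catalog = catalog
        self.log2_transform = log2_transform
        self.trim_total = trim_total

    def fit(self) -> "SeriesResults":
        ts = series_scores(
            self.series,
            self.timepoint_ids,
            catalog=self.catalog,
            log2_transform=self.log2_transform,
            trim_total=self.trim_total,
        )
        return SeriesResults(model=self, scores=ts)


@dataclass
class SeriesResults:
    """Fitted series: TF x timepoint scores plus derived analyses."""

    model: SeriesModel
    scores: TimeSeriesScores

    def set_trajectory(self, tf_set: GeneSet | Sequence[str]) -> pd.Series:
        return set_trajectory(tf_set, self.scores)

    def assign_phases(
        self,
        ad_set: GeneSet | Sequence[str],
        ne_set: GeneSet | Sequence[str],
        threshold: float = 0.2,
    ) -> PhaseSegmentation:
        return assign_phases(
            self.set_trajectory(ad_set), self.set_trajectory(ne_set), threshold
        )

    def screen_dormant(
        self,
        dormant_tp: str,
        terminal_tps: Sequence[str],
        delta: float = 0.2,
        floor: float = 0.2,
    ) -> DormancyScreenResult:
        return screen_dormant(self.scores, dormant_tp, terminal_tps, delta, floor)

    def summary(self) -> str:
        ts = self.scores
        lines = [
            f"Series of {len(ts.timepoints)} timepoints, {ts.scores.shape[0]} TFs",
            "replicates per timepoint: "
            + ", ".join(f"{tp}={n}" for tp, n in ts.replicates.items()),
        ]
        return "\n".join(lines)
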
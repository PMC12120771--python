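"""Model/Results front end for the internal Z-score lineage analysis.

:class:`LineageTFModel` bundles an expression cohort with the scoring
parameters; :meth:`~LineageTFModel.fit` runs sample pre-selection (unless
labels are supplied), per-sample internal Z standardisation, trimmed-mean
lineage scoring and threshold classification, returning a
:class:`LineageTFResults` that carries the score table, the classification
and a ``summary()``. Cross-cohort consolidation lives on the results class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .classify import (
    AD,
    NE,
    SHARED,
    ConsolidatedSets,
    TFClassification,
    classify_all,
    consolidate,
    rank_within_lineage,
)
from .cohort import (
    DEFAULT_AR_PANEL,
    DEFAULT_NE_PANEL,
    LineageLabels,
    MarkerPanel,
    assign_lineage,
    panel_score,
)
from .io import ExpressionMatrix, TFCatalog, subset_by_catalog
from .zscore import (
    DEFAULT_TRIM,
    InternalZMatrix,
    compute_internal_z,
    group_scores,
)

__all__ = ["LineageTFModel", "LineageTFResults"]


class LineageTFModel:
    """Internal Z-score lineage-TF model for one expression cohort.

    Parameters
    ----------
    matrix
        Gene x sample expression matrix (pre-normalized units).
    catalog
        TF catalog; the matrix is cut to it before scoring. ``None`` scores
        every gene.
    labels
        Known sample -> {ADENO, NEPC, EXCLUDED} labels. When omitted, samples
        are selected with the marker panels (AR axis vs NE axis) at
        ``selection_threshold``.
    log2_transform
        Apply log2(x+1) before standardising (default). Turn off for
        matrices already on a log scale.
    trim_total
        Total trimmed fraction for the per-group trimmed mean (0.2 = 10%
        from each end).
    theta
        Classification threshold on the trimmed-mean internal Z (0.2 by
        default, the low-abundance scale of ~20 normalized reads).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        catalog: TFCatalog | None = None,
        labels: LineageLabels | Mapping[str, str] | None = None,
        ar_panel: MarkerPanel = DEFAULT_AR_PANEL,
        ne_panel: MarkerPanel = DEFAULT_NE_PANEL,
        selection_threshold: float = 0.0,
        log2_transform: bool = True,
        trim_total: float = DEFAULT_TRIM,
        theta: float = 0.2,
        cohort_id: str = "cohort",
    ) -> None:
        self.matrix = matrix
        self.catalog = catalog
        if labels is not None and not isinstance(labels, LineageLabels):
            labels = LineageLabels(dict(labels))
        self.labels = labels
        self.ar_panel = ar_panel
        self.ne_panel = ne_panel
        self.selection_threshold = selection_threshold
        self.log2_transform = log2_transform
        self.trim_total = trim_total
        self.theta = theta
        self.cohort_id = cohort_id

    @classmethod
    def from_files(
        cls,
        matrix_path: str,
        catalog_path: str | None = None,
        labels_path: str | None = None,
        labels_dialect: str = "two_column",
        **kwargs,
    ) -> "LineageTFModel":
        """Build a model straight from TSV/catalog/label files."""
        from . import io as _io

        matrix, _ = _io.read_expression_matrix(matrix_path)
        catalog = _io.read_catalog(catalog_path) if catalog_path else None
        labels = None
        if labels_path:
            labels = _io.read_labels(
                labels_path, dialect=labels_dialect, sample_ids=matrix.sample_ids
            )
        return cls(matrix, catalog=catalog, labels=labels, **kwargs)

    def fit(self) -> "LineageTFResults":
        subset, missing = (
            subset_by_catalog(self.matrix, self.catalog)
            if self.catalog is not None
            else (self.matrix, [])
        )
        zmat = compute_internal_z(subset, log2_transform=self.log2_transform)
        if self.labels is None:
            ar = panel_score(zmat, self.ar_panel)
            ne = panel_score(zmat, self.ne_panel)
            labels = assign_lineage(ar, ne, self.selection_threshold)
        else:
            labels = self.labels
        scores = group_scores(zmat, labels.as_series(), trim_total=self.trim_total)
        classification = classify_all(scores, theta=self.theta, cohort_id=self.cohort_id)
        return LineageTFResults(
            model=self,
            internal_z=zmat,
            labels=labels,
            scores=scores,
            classification=classification,
            missing_catalog_symbols=missing,
        )


@dataclass
class LineageTFResults:
    """Fitted lineage-TF analysis for one cohort."""

    model: LineageTFModel
    internal_z: InternalZMatrix
    labels: LineageLabels
    scores: pd.DataFrame
    classification: TFClassification
    missing_catalog_symbols: list[str] = field(default_factory=list)

    # -- convenience views --------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        """Score table joined with the category assignment."""
        return self.scores.join(self.classification.table["category"])

    def members(self, category: str) -> list[str]:
        return self.classification.members(category)

    def ranked(self) -> dict[str, list[tuple[str, float]]]:
        """Lineage sets ordered by their defining trimmed-mean score."""
        return rank_within_lineage(self.classification, self.scores)

    @staticmethod
    def consolidate(results: Sequence["LineageTFResults"]) -> ConsolidatedSets:
        """Intersect the lineage sets of >= 2 fitted cohorts."""
        return consolidate([r.classification for r in results])

    def summary(self) -> str:
        counts = self.classification.counts()
        sel = self.labels.counts()
        m = self.model
        lines = [
            f"Lineage-TF internal Z analysis | cohort={m.cohort_id}",
            f"samples: ADENO={sel['ADENO']}  NEPC={sel['NEPC']}  "
            f"EXCLUDED={sel['EXCLUDED']}",
            f"TFs scored: {len(self.scores)}"
            + (f" ({len(self.missing_catalog_symbols)} catalog symbols absent)"
               if self.missing_catalog_symbols else ""),
            f"parameters: log2={m.log2_transform}  trim={m.trim_total}  "
            f"theta={m.theta}",
            f"categories: SHARED={counts[SHARED]}  AD={counts[AD]}  "
            f"NE={counts[NE]}  UNCLASSIFIED={counts['UNCLASSIFIED']}",
        ]
        top = self.ranked()
        for cat in (AD, NE, SHARED):
            head = ", ".join(f"{tf} ({s:.2f})" for tf, s in top[cat][:5])
            lines.append(f"top {cat}: {head}" if head else f"top {cat}: (none)")
        return "\n".join(lines)
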
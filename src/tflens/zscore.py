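"""Internal Z-score computation and trimmed-mean lineage scores.

The internal Z-score standardises each TF's expression against the mean and
standard deviation of *all catalog TFs within the same sample*:

    z_i = (x_i - x̄) / s,   x̄ = mean over TFs,  s = sd over TFs (n-1 denominator)

Because every statistic is computed within one sample column, the score is
invariant to any positive rescaling of that sample — cohorts measured on
different scales or platforms become comparable without cross-sample
normalisation.

Per-TF lineage scores are trimmed means of the internal Z-scores over the
samples of a lineage group, with spreadsheet TRIMMEAN semantics: for a trim
fraction ``t`` (default 0.2), ``k = floor(n*t/2)`` values are dropped from
each end of the sorted values and the remaining ``S = n - 2k`` averaged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InternalZMatrix",
    "column_stats",
    "compute_internal_z",
    "trimmed_mean",
    "trim_counts",
    "group_scores",
]

DEFAULT_TRIM = 0.2  #: total trimmed fraction (10% from each end)

#: lineage group labels used throughout
ADENO, NEPC, EXCLUDED = "ADENO", "NEPC", "EXCLUDED"


@dataclass
class InternalZMatrix:
    """Per-sample standardized TF scores (dimensionless).

    Every column has mean 0 and sample standard deviation 1 (n-1 denominator)
    over the scored genes, to within 1e-9.
    """

    z: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def validate(self, tol: float = 1e-9) -> None:
        arr = self.z.to_numpy()
        means = arr.mean(axis=0)
        sds = arr.std(axis=0, ddof=1)
        if np.abs(means).max() > tol:
            raise AssertionError(f"column mean off zero by {np.abs(means).max():.3g}")
        if np.abs(sds - 1.0).max() > tol:
            raise AssertionError(f"column sd off one by {np.abs(sds - 1).max():.3g}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


def column_stats(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean and sd (n-1 denominator) across genes.

    Returns a DataFrame indexed by sample with columns ``mean``, ``sd`` and a
    boolean ``degenerate`` flag marking zero-variance columns.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if df.shape[0] < 2:
        raise ValueError("need at least 2 gene rows for column statistics")
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=1)
    return pd.DataFrame({"mean": means, "sd": sds, "degenerate": sds == 0.0})


def compute_internal_z(
    matrix: ExpressionMatrix,
    log2_transform: bool = True,
    drop_degenerate: bool = False,
) -> InternalZMatrix:
    """Standardise each sample column to internal Z-scores.

    Parameters
    ----------
    matrix
        Catalog-subset expression matrix (genes x samples).
    log2_transform
        Apply ``x -> log2(x + 1)`` before standardising. Skipped automatically
        for matrices flagged as already log-transformed.
    drop_degenerate
        Drop zero-variance sample columns with a warning instead of raising.
    """
    df = matrix.values
    if log2_transform:
        if matrix.log_transformed:
            raise ValueError("matrix is already log-transformed; pass log2_transform=False")
        if (df.to_numpy() < 0).any():
            raise ValueError("log2 transform requires non-negative values")
        df = np.log2(df + 1.0)
    stats = column_stats(df)
    degenerate = stats.index[stats["degenerate"]].tolist()
    if degenerate:
        if not drop_degenerate:
            raise ValueError(
                f"zero-variance sample columns {degenerate}; "
                "pass drop_degenerate=True to remove them"
            )
        logger.warning("dropping %d zero-variance columns: %s", len(degenerate), degenerate)
        df = df.drop(columns=degenerate)
        stats = stats.drop(index=degenerate)
    z = (df - stats["mean"]) / stats["sd"]
    return InternalZMatrix(
        z,
        provenance={
            "log2_transform": bool(log2_transform),
            "unit_tag": matrix.unit_tag,
            "n_genes": int(z.shape[0]),
            "dropped_columns": degenerate,
        },
    )


def trim_counts(n: int, trim_total: float = DEFAULT_TRIM) -> tuple[int, int]:
    """Number trimmed per end (k) and retained (S) for group size ``n``.

    Spreadsheet TRIMMEAN rule: the total excluded count is ``n * trim_total``
    rounded down to the nearest even integer, split equally between the ends,
    i.e. ``k = floor(n * trim_total / 2)`` per end.
    """
    if n < 1:
        raise ValueError("empty group")
    if not 0.0 <= trim_total < 1.0:
        raise ValueError(f"trim_total must be in [0, 1), got {trim_total}")
    k = math.floor(n * trim_total / 2.0)
    return k, n - 2 * k


def trimmed_mean(values: Sequence[float] | np.ndarray, trim_total: float = DEFAULT_TRIM) -> float:
    """Mean after dropping ``floor(n*trim_total/2)`` values from each end.

    Equivalent to the spreadsheet TRIMMEAN(values, trim_total). A single value
    is returned unchanged for any trim below 1 (k = 0).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size == 0:
        raise ValueError("trimmed_mean of empty input")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in trimmed_mean input")
    k, _ = trim_counts(arr.size, trim_total)
    kept = np.sort(arr)[k: arr.size - k]
    # fsum: correctly rounded sum, independent of accumulation order
    return math.fsum(kept) / kept.size


def _trimmed_mean_rows(block: np.ndarray, trim_total: float) -> np.ndarray:
    """Row-wise trimmed mean of a 2-D block (genes x group samples)."""
    n = block.shape[1]
    k, _ = trim_counts(n, trim_total)
    ordered = np.sort(block, axis=1)[:, k: n - k]
    return ordered.mean(axis=1)


def group_scores(
    zmat: InternalZMatrix,
    labels: Mapping[str, str] | pd.Series,
    trim_total: float = DEFAULT_TRIM,
) -> pd.DataFrame:
    """Per-TF trimmed-mean internal Z within each lineage group.

    ``labels`` maps sample ids to ADENO / NEPC / EXCLUDED; EXCLUDED samples
    are ignored entirely. Returns a DataFrame indexed by TF with columns
    ``Z_ad``, ``Z_NE``, ``n_ad``, ``n_NE``, ``k_ad``, ``k_NE``, ``S_ad``,
    ``S_NE``.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    missing = [s for s in zmat.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    cols: dict[str, list[str]] = {ADENO: [], NEPC: []}
    for s in zmat.sample_ids:
        grp = labels[s]
        if grp in cols:
            cols[grp].append(s)
        elif grp != EXCLUDED:
            raise ValueError(f"unknown group {grp!r} for sample {s!r}")
    for grp, members in cols.items():
        if not members:
            raise ValueError(f"group {grp} has no samples after exclusions")
    out = pd.DataFrame(index=zmat.z.index)
    for grp, col_z, col_n, col_k, col_s in (
        (ADENO, "Z_ad", "n_ad", "k_ad", "S_ad"),
        (NEPC, "Z_NE", "n_NE", "k_NE", "S_NE"),
    ):
        block = zmat.z[cols[grp]].to_numpy()
        n = block.shape[1]
        k, S = trim_counts(n, trim_total)
        out[col_z] = _trimmed_mean_rows(block, trim_total)
        out[col_n], out[col_k], out[col_s] = n, k, S
    out.index.name = "tf"
    return out
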
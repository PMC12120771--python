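"""Self-contained two-class gene set enrichment analysis.

Implements the canonical weighted Kolmogorov-Smirnov formulation: genes are
ranked by a two-class metric (signal-to-noise by default), a running sum
increments at set members by ``|score|^p`` (normalised over the set) and
decrements at non-members by ``1/(N - N_hit)``; the enrichment score (ES) is
the signed extremum of the running sum. Significance comes from phenotype
(label-shuffling) permutations: the normalised enrichment score (NES) divides
ES by the mean magnitude of same-sign permutation scores, the nominal p-value
is the same-sign permutation tail fraction, and the FDR q-value uses the
pooled-NES procedure. The conventional significance rule for a set is
FDR q < 0.25.

Results are statsmodels-shaped: build a :class:`TwoClassGSEA` model from a
matrix, labels and gene sets, call :meth:`~TwoClassGSEA.fit`, and read the
table or ``summary()`` off the returned :class:`GSEAResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "GseaResult",
    "GSEAResults",
    "TwoClassGSEA",
    "rank_metric",
    "enrichment_score",
    "gsea",
]

SIGNIFICANCE_Q = 0.25  #: conventional FDR q cutoff for calling a set enriched


@dataclass
class RankedList:
    """Genes ordered by a two-class metric, descending; ties alphabetical."""

    scores: pd.Series  # index gene, values metric score, descending order
    metric: str
    phenotypes: tuple[str, str]  # (positive class, negative class)

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)


def _metric_scores(
    values: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    metric: str,
) -> np.ndarray:
    """Vectorised two-class metric over a genes x samples array."""
    xa, xb = values[:, mask_a], values[:, mask_b]
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    if metric == "difference_of_means":
        return mu_a - mu_b
    if metric != "signal_to_noise":
        raise ValueError(f"unknown metric {metric!r}")
    sd_a = xa.std(axis=1, ddof=1)
    sd_b = xb.std(axis=1, ddof=1)
    # GSEA-desktop floor: sd at least 20% of |mean|, and 0.2 when both vanish
    sd_a = np.maximum(sd_a, 0.2 * np.abs(mu_a))
    sd_b = np.maximum(sd_b, 0.2 * np.abs(mu_b))
    denom = sd_a + sd_b
    num = mu_a - mu_b
    out = np.zeros_like(num)
    np.divide(num, denom, out=out, where=denom > 0)
    return out


def _order(genes: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Indices sorting descending by score, alphabetical within ties."""
    return np.lexsort((genes, -scores))


def rank_metric(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    phenotypes: tuple[str, str],
    metric: str = "signal_to_noise",
) -> RankedList:
    """Rank all genes of ``matrix`` by a two-class metric.

    ``phenotypes = (A, B)`` names the positive and negative class in
    ``labels``; samples labelled otherwise are ignored. Signal-to-noise is
    ``(mu_A - mu_B)/(sigma_A + sigma_B)`` with the GSEA-desktop variance
    floor and needs >= 2 samples per class.
    """
    pos, neg = phenotypes
    samples = list(matrix.sample_ids)
    grp = np.array([labels.get(s) for s in samples], dtype=object)
    mask_a, mask_b = grp == pos, grp == neg
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"phenotype with no samples: {pos}={n_a}, {neg}={n_b}")
    if metric == "signal_to_noise" and min(n_a, n_b) < 2:
        raise ValueError(
            "signal_to_noise needs >= 2 samples per phenotype; "
            "use metric='difference_of_means'"
        )
    values = matrix.values.to_numpy(dtype=float)
    scores = _metric_scores(values, mask_a, mask_b, metric)
    genes = np.asarray(matrix.gene_ids, dtype=object)
    order = _order(genes, scores)
    series = pd.Series(scores[order], index=genes[order], name=metric)
    return RankedList(series, metric=metric, phenotypes=phenotypes)


def enrichment_score(
    ranked: RankedList | pd.Series,
    gene_set: GeneSet | Sequence[str],
    p_weight: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS enrichment score of a gene set against a ranked list.

    Returns ``(ES, running_sum, leading_edge)``. The running sum is over the
    full ranked universe; the leading edge contains the set members at or
    before (after, for negative ES) the extremum.
    """
    scores = ranked.scores if isinstance(ranked, RankedList) else ranked
    members = gene_set.members if isinstance(gene_set, GeneSet) else list(gene_set)
    genes = np.asarray(scores.index, dtype=object)
    vals = scores.to_numpy(dtype=float)
    hit = np.isin(genes, np.asarray(list(members), dtype=object))
    n, n_hit = len(genes), int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranked universe")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked universe")
    running = _running_sum(vals, hit, p_weight)
    idx = int(np.argmax(np.abs(running)))
    es = float(running[idx])
    if es >= 0:
        leading = [g for g, h in zip(genes[: idx + 1], hit[: idx + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[idx:], hit[idx:]) if h]
    return es, running, leading


def _running_sum(vals: np.ndarray, hit: np.ndarray, p_weight: float) -> np.ndarray:
    n = vals.size
    n_hit = int(hit.sum())
    weights = np.abs(vals[hit]) ** p_weight
    total = weights.sum()
    steps = np.full(n, -1.0 / (n - n_hit))
    if total > 0:
        steps[hit] = weights / total
    else:  # all member scores zero: fall back to equal hit weights
        steps[hit] = 1.0 / n_hit
    return np.cumsum(steps)


def _es_batch(vals: np.ndarray, hits: list[np.ndarray], p_weight: float) -> np.ndarray:
    """ES of several pre-located gene sets against one ranked score vector."""
    out = np.empty(len(hits))
    for i, hit in enumerate(hits):
        running = _running_sum(vals, hit, p_weight)
        out[i] = running[np.argmax(np.abs(running))]
    return out


@dataclass
class GseaResult:
    """Enrichment of one gene set against one two-class comparison."""

    name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    size: int
    leading_edge: list[str]
    n_permutations: int
    seed: int | None

    @property
    def significant(self) -> bool:
        return self.fdr_q < SIGNIFICANCE_Q


@dataclass
class GSEAResults:
    """Fitted GSEA: one :class:`GseaResult` per input set plus provenance."""

    results: list[GseaResult]
    phenotypes: tuple[str, str]
    metric: str
    perm_type: str
    n_permutations: int
    seed: int | None
    ranked: RankedList | None = field(default=None, repr=False)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set": [r.name for r in self.results],
                "size": [r.size for r in self.results],
                "ES": [r.es for r in self.results],
                "NES": [r.nes for r in self.results],
                "p": [r.p_value for r in self.results],
                "FDR_q": [r.fdr_q for r in self.results],
                "leading_edge_size": [len(r.leading_edge) for r in self.results],
                "significant_q<0.25": [r.significant for r in self.results],
            }
        ).set_index("set")

    def summary(self) -> str:
        pos, neg = self.phenotypes
        head = (
            f"Two-class GSEA: {pos} vs {neg} | metric={self.metric} | "
            f"{self.n_permutations} {self.perm_type} permutations | seed={self.seed}"
        )
        return head + "\n" + self.table.to_string(float_format=lambda x: f"{x: .4f}")


class TwoClassGSEA:
    """Model object: expression matrix + phenotype labels + gene sets.

    Parameters
    ----------
    matrix
        Whole-transcriptome expression matrix (no catalog cut is applied:
        ranking uses all genes).
    labels
        Sample -> phenotype mapping; samples outside ``phenotypes`` ignored.
    gene_sets
        The sets to score (e.g. the consolidated AD/NE/shared TF sets).
    phenotypes
        (positive, negative) class pair; positive enrichment means
        concordance with the first class.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        labels: Mapping[str, str],
        gene_sets: Sequence[GeneSet],
        phenotypes: tuple[str, str],
        metric: str = "signal_to_noise",
        p_weight: float = 1.0,
    ) -> None:
        if not gene_sets:
            raise ValueError("no gene sets supplied")
        self.matrix = matrix
        self.labels = dict(labels)
        self.gene_sets = list(gene_sets)
        self.phenotypes = phenotypes
        self.metric = metric
        self.p_weight = p_weight

    def fit(
        self,
        n_permutations: int = 1000,
        perm_type: str = "phenotype",
        seed: int | None = None,
    ) -> GSEAResults:
        """Run the enrichment analysis; deterministic given ``seed``."""
        return gsea(
            self.matrix,
            self.labels,
            self.gene_sets,
            phenotypes=self.phenotypes,
            metric=self.metric,
            p_weight=self.p_weight,
            n_permutations=n_permutations,
            perm_type=perm_type,
            seed=seed,
        )


def gsea(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    gene_sets: Sequence[GeneSet],
    phenotypes: tuple[str, str],
    metric: str = "signal_to_noise",
    p_weight: float = 1.0,
    n_permutations: int = 1000,
    perm_type: str = "phenotype",
    seed: int | None = None,
) -> GSEAResults:
    """Two-class GSEA over several gene sets with permutation significance.

    Phenotype permutation shuffles class labels among the compared samples,
    preserving group sizes. When the number of distinct label splits equals
    ``n_permutations`` the splits are enumerated exhaustively (exact null);
    when it is smaller, the analysis falls back to gene-set permutation with
    a warning. Nominal p is the same-sign tail fraction of permutation ES;
    NES divides each ES by the mean |ES| of same-sign permutations of its own
    set; FDR q follows the pooled-NES procedure.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    rng = np.random.default_rng(seed)
    pos, neg = phenotypes
    samples = list(matrix.sample_ids)
    grp = np.array([labels.get(s) for s in samples], dtype=object)
    used = np.flatnonzero((grp == pos) | (grp == neg))
    values = matrix.values.to_numpy(dtype=float)[:, used]
    grp_used = grp[used]
    mask_a = grp_used == pos
    n_used, n_a = mask_a.size, int(mask_a.sum())
    if metric == "signal_to_noise" and min(n_a, n_used - n_a) < 2:
        raise ValueError(
            "signal_to_noise needs >= 2 samples per phenotype; "
            "use metric='difference_of_means'"
        )

    genes = np.asarray(matrix.gene_ids, dtype=object)
    obs_scores = _metric_scores(values, mask_a, ~mask_a, metric)
    obs_order = _order(genes, obs_scores)
    member_arrays = [np.asarray(gs.members, dtype=object) for gs in gene_sets]
    base_hits = [np.isin(genes, m) for m in member_arrays]
    for gs, hit in zip(gene_sets, base_hits):
        n_hit = int(hit.sum())
        if n_hit == 0:
            raise ValueError(f"gene set {gs.name!r} has no member in the matrix")
        if n_hit == len(genes):
            raise ValueError(f"gene set {gs.name!r} covers the whole matrix")

    # observed ES and leading edges
    ranked = RankedList(
        pd.Series(obs_scores[obs_order], index=genes[obs_order], name=metric),
        metric=metric,
        phenotypes=phenotypes,
    )
    obs_es = np.empty(len(gene_sets))
    leading: list[list[str]] = []
    for i, gs in enumerate(gene_sets):
        es, _, lead = enrichment_score(ranked, gs, p_weight)
        obs_es[i] = es
        leading.append(lead)

    # permutation null
    if perm_type == "phenotype":
        n_distinct = comb(n_used, n_a)
        if n_distinct < n_permutations:
            logger.warning(
                "only %d distinct label splits for %d requested permutations; "
                "falling back to gene_set permutation",
                n_distinct,
                n_permutations,
            )
            perm_type = "gene_set"
    if perm_type == "phenotype":
        null_es = _phenotype_null(
            values, genes, base_hits, metric, p_weight,
            n_a, n_permutations, comb(n_used, n_a), rng,
        )
    elif perm_type == "gene_set":
        null_es = _gene_set_null(
            obs_scores, obs_order, genes, base_hits, p_weight, n_permutations, rng
        )
    else:
        raise ValueError(f"unknown perm_type {perm_type!r}")

    nes, p_values, null_nes = _normalize(obs_es, null_es)
    fdr_q = _pooled_fdr(nes, null_nes)

    results = [
        GseaResult(
            name=gs.name,
            es=float(obs_es[i]),
            nes=float(nes[i]),
            p_value=float(p_values[i]),
            fdr_q=float(fdr_q[i]),
            size=int(base_hits[i].sum()),
            leading_edge=leading[i],
            n_permutations=null_es.shape[1],
            seed=seed,
        )
        for i, gs in enumerate(gene_sets)
    ]
    return GSEAResults(
        results=results,
        phenotypes=phenotypes,
        metric=metric,
        perm_type=perm_type,
        n_permutations=null_es.shape[1],
        seed=seed,
        ranked=ranked,
    )


def _phenotype_null(
    values: np.ndarray,
    genes: np.ndarray,
    base_hits: list[np.ndarray],
    metric: str,
    p_weight: float,
    n_a: int,
    n_permutations: int,
    n_distinct: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES matrix (sets x permutations) from label shuffles."""
    n_used = values.shape[1]
    if n_distinct == n_permutations:  # exact null: enumerate all splits
        splits = [np.array(c) for c in combinations(range(n_used), n_a)]
    else:
        splits = [rng.permutation(n_used)[:n_a] for _ in range(n_permutations)]
    null = np.empty((len(base_hits), len(splits)))
    for j, idx_a in enumerate(splits):
        mask = np.zeros(n_used, dtype=bool)
        mask[idx_a] = True
        scores = _metric_scores(values, mask, ~mask, metric)
        order = _order(genes, scores)
        vals = scores[order]
        hits = [h[order] for h in base_hits]
        null[:, j] = _es_batch(vals, hits, p_weight)
    return null


def _gene_set_null(
    obs_scores: np.ndarray,
    obs_order: np.ndarray,
    genes: np.ndarray,
    base_hits: list[np.ndarray],
    p_weight: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES from random same-size gene sets on the observed ranking."""
    vals = obs_scores[obs_order]
    n = len(genes)
    null = np.empty((len(base_hits), n_permutations))
    for i, hit in enumerate(base_hits):
        size = int(hit.sum())
        for j in range(n_permutations):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=size, replace=False)] = True
            running = _running_sum(vals, mask, p_weight)
            null[i, j] = running[np.argmax(np.abs(running))]
    return null


def _normalize(
    obs_es: np.ndarray, null_es: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NES, nominal p and the sign-matched normalised null NES pool."""
    n_sets, n_perm = null_es.shape
    nes = np.zeros(n_sets)
    p_values = np.ones(n_sets)
    null_nes = np.zeros_like(null_es)
    for i in range(n_sets):
        nulls = null_es[i]
        pos, neg = nulls[nulls >= 0], nulls[nulls < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        # each permutation ES normalised by its own sign's mean magnitude
        with np.errstate(invalid="ignore"):
            null_nes[i] = np.where(
                nulls >= 0,
                nulls / mean_pos if pos.size else 0.0,
                nulls / mean_neg if neg.size else 0.0,
            )
        es = obs_es[i]
        if es >= 0:
            same = pos
            nes[i] = es / mean_pos if pos.size else 0.0
        else:
            same = neg
            nes[i] = -abs(es) / mean_neg if neg.size else 0.0
        if same.size:
            p_values[i] = float((np.abs(same) >= abs(es)).sum()) / same.size
        else:
            p_values[i] = 1.0 / (n_perm + 1)
    return nes, p_values, null_nes


def _pooled_fdr(nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Pooled-NES FDR q: null tail fraction over observed tail fraction."""
    pool = null_nes.ravel()
    pool = pool[np.isfinite(pool)]
    q = np.ones_like(nes)
    n_pool_pos = (pool >= 0).sum()
    n_pool_neg = (pool < 0).sum()
    n_obs_pos = (nes >= 0).sum()
    n_obs_neg = (nes < 0).sum()
    for i, v in enumerate(nes):
        if v >= 0:
            if n_pool_pos == 0 or n_obs_pos == 0:
                q[i] = 1.0
                continue
            null_frac = (pool >= v).sum() / n_pool_pos
            obs_frac = (nes >= v).sum() / n_obs_pos
        else:
            if n_pool_neg == 0 or n_obs_neg == 0:
                q[i] = 1.0
                continue
            null_frac = (pool <= v).sum() / n_pool_neg
            obs_frac = (nes <= v).sum() / n_obs_neg
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    return q
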
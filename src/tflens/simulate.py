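"""Synthetic two-lineage cohorts and transdifferentiation series.

The cohort generator emulates the data the scoring method consumes: a
log-normal expression matrix with planted lineage-specific, shared and
background TFs, marker-panel genes for sample pre-selection, and independent
per-sample scale factors that mimic library-size / platform differences (the
nuisance the internal Z-score is designed to remove).

Generative model (log2 scale, per gene g and sample j):

    log2 x_gj = b_g + e_gj + noise,   noise ~ N(0, sigma)

with baseline ``b_g ~ N(mu_baseline, 1)`` and planted effects ``e_gj``:
lineage TFs are *on* (+delta) in their own lineage and *off* (-delta) in the
other, shared TFs +delta everywhere, background TFs 0. Emitted values are
linear scale, multiplied per sample by ``exp(N(0, sigma_scale))``.

The series generator plants canonical profile shapes anchored at the catalog
baseline mean: adenocarcinoma TFs high only at baseline, NE TFs high only at
relapse, dormant TFs high only at the dormant timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import DEFAULT_AR_PANEL, DEFAULT_NE_PANEL, LineageLabels
from .io import ExpressionMatrix, TFCatalog
from .zscore import ADENO, NEPC

__all__ = [
    "CohortParams",
    "SeriesParams",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_time_series",
    "simulate_two_class",
]


@dataclass(frozen=True)
class CohortParams:
    """Generation parameters for a two-lineage cohort.

    Sizes and noise levels are deliberately desk-scale: 300 genes, a 30+20
    cohort, a 2-log2-unit planted effect over sigma = 0.5 gene-level noise
    and sigma_scale = 0.3 per-sample scale jitter.
    """

    n_genes: int = 300
    n_ad: int = 30
    n_ne: int = 20
    delta: float = 2.0          # planted effect, log2 units
    sigma: float = 0.5          # gene-level noise sd, log2 units
    sigma_scale: float = 0.3    # per-sample log scale-factor sd
    mu_baseline: float = 5.0    # mean log2 baseline (~32 normalized reads)
    n_ad_tfs: int = 20          # planted AD set size, marker genes included
    n_ne_tfs: int = 20          # planted NE set size, marker genes included
    n_shared_tfs: int = 30


@dataclass(frozen=True)
class SeriesParams:
    """Generation parameters for a four-timepoint transdifferentiation series.

    Besides the AD / NE / dormant groups, a transient castration-response
    group peaks at the second timepoint, so that every timepoint carries one
    elevated planted group and the per-column standardisation statistics stay
    comparable along the series. The default noise is technical-scale
    (single-graft profiles of one tumor line); raise ``sigma`` to study the
    screen's robustness rather than its correctness.
    """

    n_genes: int = 300
    timepoints: tuple[str, ...] = ("T0", "T1", "T2", "T3")
    replicates: int = 1
    delta: float = 2.0          # lineage-TF on/off separation, log2 units
    delta_dormant: float = 1.0  # dormant-TF on-level above baseline mean, log2
    sigma: float = 0.02         # technical-scale noise sd, log2 units
    sigma_scale: float = 0.3
    mu_baseline: float = 5.0
    n_ad_tfs: int = 20
    n_ne_tfs: int = 20
    n_dormant: int = 20
    n_transient: int = 20       # castration-response TFs peaking early


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated instance."""

    ad_tfs: list[str] = field(default_factory=list)
    ne_tfs: list[str] = field(default_factory=list)
    shared_tfs: list[str] = field(default_factory=list)
    dormant_tfs: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        sets = [set(self.ad_tfs), set(self.ne_tfs),
                set(self.shared_tfs), set(self.dormant_tfs)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("planted TF sets overlap")


def _gene_names(params: CohortParams | SeriesParams, with_dormant: bool) -> dict[str, list[str]]:
    """Deterministic gene naming so replicate cohorts share planted identity.

    Marker-panel genes are members of the planted lineage sets: they are
    lineage-specific by construction, and the classifier is expected to find
    them.
    """
    ad = list(DEFAULT_AR_PANEL.members) + [
        f"ADTF{i:03d}" for i in range(params.n_ad_tfs - len(DEFAULT_AR_PANEL.members))
    ]
    ne = list(DEFAULT_NE_PANEL.members) + [
        f"NETF{i:03d}" for i in range(params.n_ne_tfs - len(DEFAULT_NE_PANEL.members))
    ]
    shared = [f"SHTF{i:03d}" for i in range(getattr(params, "n_shared_tfs", 0))]
    dormant = [f"DORM{i:03d}" for i in range(getattr(params, "n_dormant", 0))] if with_dormant else []
    transient = [f"TRAN{i:03d}" for i in range(getattr(params, "n_transient", 0))] if with_dormant else []
    planted = len(ad) + len(ne) + len(shared) + len(dormant) + len(transient)
    if params.n_genes < planted + 20:
        raise ValueError(
            f"n_genes={params.n_genes} too small for {planted} planted TFs "
            "(need at least 20 background genes)"
        )
    background = [f"BG{i:04d}" for i in range(params.n_genes - planted)]
    return {"ad": ad, "ne": ne, "shared": shared, "dormant": dormant,
            "transient": transient, "background": background}


def simulate_cohort(
    params: CohortParams | None = None,
    seed: int = 1,
) -> tuple[ExpressionMatrix, LineageLabels, SyntheticTruth]:
    """Simulate a two-lineage cohort with planted lineage-specific TFs.

    Returns the linear-scale expression matrix, the true lineage labels and
    the planted truth. Identical seed -> bit-identical output. Replicate
    cohorts (same planted memberships, independent baselines and noise) are
    produced by calling again with a different seed and the same params.
    """
    params = params or CohortParams()
    if params.n_ad < 4 or params.n_ne < 4:
        raise ValueError("need at least 4 samples per lineage")
    if params.sigma < 0 or params.sigma_scale < 0 or params.delta < 0:
        raise ValueError("delta, sigma and sigma_scale must be non-negative")
    names = _gene_names(params, with_dormant=False)
    genes = names["ad"] + names["ne"] + names["shared"] + names["background"]
    n_genes = len(genes)
    samples = [f"AD{i:02d}" for i in range(params.n_ad)] + [
        f"NE{i:02d}" for i in range(params.n_ne)
    ]
    is_ad_sample = np.array([s.startswith("AD") for s in samples])

    rng = np.random.default_rng(seed)
    baseline = params.mu_baseline + rng.standard_normal(n_genes)
    effect = np.zeros((n_genes, len(samples)))
    idx = {g: i for i, g in enumerate(genes)}
    for g in names["ad"]:
        effect[idx[g], is_ad_sample] += params.delta
        effect[idx[g], ~is_ad_sample] -= params.delta
    for g in names["ne"]:
        effect[idx[g], ~is_ad_sample] += params.delta
        effect[idx[g], is_ad_sample] -= params.delta
    for g in names["shared"]:
        effect[idx[g], :] += params.delta
    log2x = baseline[:, None] + effect + params.sigma * rng.standard_normal(
        (n_genes, len(samples))
    )
    scale = np.exp(params.sigma_scale * rng.standard_normal(len(samples)))
    values = np.power(2.0, log2x) * scale[None, :]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        unit_tag="simulated normalized counts",
    )
    labels = LineageLabels(
        {s: (ADENO if ad else NEPC) for s, ad in zip(samples, is_ad_sample)},
        params={"source": "simulated ground truth"},
    )
    truth = SyntheticTruth(
        ad_tfs=names["ad"],
        ne_tfs=names["ne"],
        shared_tfs=names["shared"],
        params=asdict(params),
        seed=seed,
    )
    return matrix, labels, truth


def simulate_time_series(
    params: SeriesParams | None = None,
    seed: int = 7,
) -> tuple[list[ExpressionMatrix], SyntheticTruth]:
    """Simulate an ordered transdifferentiation series with planted dormant TFs.

    Planted profile shapes (log2 scale, anchored at the baseline mean mu_b):
    AD TFs sit at mu_b + delta/2 at the first timepoint and mu_b - delta/2
    elsewhere; NE TFs are mirrored at the last timepoint; transient
    castration-response TFs peak at the second timepoint; dormant TFs rise to
    mu_b + delta_dormant/2 at the dormant timepoint (index 2) from a
    suppressed mu_b - delta/2 level. Background genes keep their random
    baseline.
    """
    params = params or SeriesParams()
    if params.delta <= 0 or params.delta_dormant <= 0:
        raise ValueError("planted margins must be positive")
    if params.replicates < 1:
        raise ValueError("need at least one sample per timepoint")
    if len(params.timepoints) < 3:
        raise ValueError("a series needs at least 3 timepoints")
    names = _gene_names(params, with_dormant=True)
    genes = (names["ad"] + names["ne"] + names["dormant"] + names["transient"]
             + names["background"])
    n_genes = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    tps = list(params.timepoints)
    dormant_tp_index = 2 if len(tps) > 3 else 1

    rng = np.random.default_rng(seed)
    baseline = params.mu_baseline + rng.standard_normal(n_genes)
    # planted genes are anchored at the catalog mean so their on/off levels
    # are controlled in z units rather than riding on a random baseline
    for group in ("ad", "ne", "dormant", "transient"):
        for g in names[group]:
            baseline[idx[g]] = params.mu_baseline

    level = np.tile(baseline[:, None], (1, len(tps)))
    half = params.delta / 2.0
    for g in names["ad"]:
        level[idx[g], :] -= half
        level[idx[g], 0] += params.delta
    for g in names["ne"]:
        level[idx[g], :] -= half
        level[idx[g], len(tps) - 1] += params.delta
    for g in names["transient"]:
        level[idx[g], :] -= half
        level[idx[g], 1] += params.delta
    for g in names["dormant"]:
        level[idx[g], :] -= half
        level[idx[g], dormant_tp_index] += half + params.delta_dormant / 2.0

    matrices: list[ExpressionMatrix] = []
    for t, tp in enumerate(tps):
        cols = {}
        for r in range(params.replicates):
            noise = params.sigma * rng.standard_normal(n_genes)
            scale = np.exp(params.sigma_scale * rng.standard_normal())
            name = tp if params.replicates == 1 else f"{tp}_r{r}"
            cols[name] = np.power(2.0, level[:, t] + noise) * scale
        matrices.append(
            ExpressionMatrix(
                pd.DataFrame(cols, index=genes),
                unit_tag="simulated normalized counts",
            )
        )
    truth = SyntheticTruth(
        ad_tfs=names["ad"],
        ne_tfs=names["ne"],
        dormant_tfs=names["dormant"],
        params={**asdict(params), "dormant_tp": tps[dormant_tp_index],
                "transient_tfs": names["transient"]},
        seed=seed,
    )
    return matrices, truth


def simulate_two_class(
    n_genes: int = 200,
    n_shifted: int = 40,
    n_a: int = 10,
    n_b: int = 10,
    shift: float = 1.0,
    sigma: float = 0.5,
    mu_baseline: float = 5.0,
    seed: int = 1,
) -> tuple[ExpressionMatrix, dict[str, str], list[str]]:
    """Two-phenotype matrix with ``n_shifted`` genes up-shifted in class A.

    Returns (matrix, sample->class labels, shifted gene names); the natural
    fixture for exercising the GSEA validator.
    """
    if not 0 < n_shifted < n_genes:
        raise ValueError("n_shifted must be strictly between 0 and n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"UP{i:03d}" for i in range(n_shifted)] + [
        f"BG{i:04d}" for i in range(n_genes - n_shifted)
    ]
    samples = [f"A{i:02d}" for i in range(n_a)] + [f"B{i:02d}" for i in range(n_b)]
    baseline = mu_baseline + rng.standard_normal(n_genes)
    log2x = baseline[:, None] + sigma * rng.standard_normal((n_genes, len(samples)))
    log2x[:n_shifted, :n_a] += shift
    matrix = ExpressionMatrix(
        pd.DataFrame(np.power(2.0, log2x), index=genes, columns=samples),
        unit_tag="simulated normalized counts",
    )
    labels = {s: ("A" if s.startswith("A") else "B") for s in samples}
    return matrix, labels, genes[:n_shifted]


def catalog_from_truth(matrix: ExpressionMatrix) -> TFCatalog:
    """Catalog covering every gene of a simulated matrix (the TF universe)."""
    return TFCatalog(list(matrix.gene_ids), source_label="simulated catalog")
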
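from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from tflens import (
    ExpressionMatrix,
    GeneSet,
    TwoClassGSEA,
    enrichment_score,
    gsea,
    rank_metric,
    simulate_two_class,
)
from tflens.gsea import RankedList


def snr_oracle(xa, xb):
    """Scalar signal-to-noise with the GSEA-desktop variance floor."""
    ma, mb = np.mean(xa), np.mean(xb)
    sa = max(np.std(xa, ddof=1), 0.2 * abs(ma))
    sb = max(np.std(xb, ddof=1), 0.2 * abs(mb))
    if sa + sb == 0:
        return 0.0
    return (ma - mb) / (sa + sb)


def es_oracle(scores: pd.Series, members, p_weight):
    """Exhaustive running-sum reference over every prefix position."""
    genes = list(scores.index)
    hits = [g in set(members) for g in genes]
    n, n_hit = len(genes), sum(hits)
    weights = [abs(scores[g]) ** p_weight if h else 0.0 for g, h in zip(genes, hits)]
    total = sum(weights)
    best, running = 0.0, 0.0
    for i, g in enumerate(genes):
        if hits[i]:
            running += (weights[i] / total) if total > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def toy_matrix(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestRankMetric:
    def test_sign_and_ordering(self):
        m = toy_matrix(
            [[5.0, 6.0, 1.0, 2.0], [1.0, 2.0, 5.0, 6.0], [3.0, 3.1, 3.0, 3.1]],
            ["UP_IN_A", "UP_IN_B", "FLAT"],
            ["a1", "a2", "b1", "b2"],
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        ranked = rank_metric(m, labels, ("A", "B"))
        assert ranked.scores["UP_IN_A"] > 0 > ranked.scores["UP_IN_B"]
        assert ranked.genes[0] == "UP_IN_A" and ranked.genes[-1] == "UP_IN_B"

    def test_all_tied_scores_order_alphabetically(self):
        m = toy_matrix(
            [[1.0, 2.0, 1.0, 2.0]] * 3, ["C", "A", "B"], ["a1", "a2", "b1", "b2"]
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        ranked = rank_metric(m, labels, ("A", "B"))
        assert np.allclose(ranked.scores, 0.0)
        assert ranked.genes == ["A", "B", "C"]

    def test_matches_floored_formula_oracle(self, rng):
        values = rng.lognormal(size=(20, 6))
        genes = [f"G{i:02d}" for i in range(20)]
        samples = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        m = toy_matrix(values, genes, samples)
        labels = {s: s[0].upper() for s in samples}
        ranked = rank_metric(m, labels, ("A", "B"))
        for i, g in enumerate(genes):
            assert ranked.scores[g] == pytest.approx(
                snr_oracle(values[i, :3], values[i, 3:]), abs=1e-12
            )

    def test_small_groups_need_difference_of_means(self):
        m = toy_matrix([[1.0, 2.0]], ["G"], ["a", "b"])
        labels = {"a": "A", "b": "B"}
        with pytest.raises(ValueError, match="difference_of_means"):
            rank_metric(m, labels, ("A", "B"))
        ranked = rank_metric(m, labels, ("A", "B"), metric="difference_of_means")
        assert ranked.scores["G"] == pytest.approx(-1.0)


class TestEnrichmentScore:
    def _ranked(self, scores: dict) -> RankedList:
        s = pd.Series(scores).sort_values(ascending=False)
        return RankedList(s, metric="test", phenotypes=("A", "B"))

    def test_single_top_gene_unweighted_es_is_one(self):
        ranked = self._ranked({f"G{i}": 10 - i for i in range(10)})
        es, _, lead = enrichment_score(ranked, ["G0"], p_weight=0.0)
        assert es == pytest.approx(1.0)
        assert lead == ["G0"]

    def test_single_bottom_gene_es_is_minus_one(self):
        ranked = self._ranked({f"G{i}": 10 - i for i in range(10)})
        es, _, _ = enrichment_score(ranked, ["G9"], p_weight=0.0)
        assert es == pytest.approx(-1.0)

    @pytest.mark.parametrize("p_weight", [0.0, 1.0])
    def test_matches_running_sum_oracle(self, rng, p_weight):
        for n in (10, 25, 50):
            scores = pd.Series(
                rng.normal(size=n), index=[f"G{i:03d}" for i in range(n)]
            ).sort_values(ascending=False)
            ranked = RankedList(scores, metric="t", phenotypes=("A", "B"))
            members = list(rng.choice(scores.index, size=max(3, n // 5), replace=False))
            es, running, _ = enrichment_score(ranked, members, p_weight)
            assert es == pytest.approx(es_oracle(scores, members, p_weight), abs=1e-12)
            assert np.abs(running).max() <= 1.0 + 1e-12

    def test_reversed_list_negates_unweighted_es(self, rng):
        scores = pd.Series(rng.normal(size=20), index=[f"G{i}" for i in range(20)])
        fwd = RankedList(scores.sort_values(ascending=False), "t", ("A", "B"))
        rev = RankedList(-scores.sort_values(ascending=True), "t", ("A", "B"))
        members = [f"G{i}" for i in (2, 5, 11)]
        es_f, _, _ = enrichment_score(fwd, members, 0.0)
        es_r, _, _ = enrichment_score(rev, members, 0.0)
        assert es_f == pytest.approx(-es_r, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        ranked = self._ranked({"A": 2.0, "B": 1.0})
        with pytest.raises(ValueError):
            enrichment_score(ranked, ["NOPE"])
        with pytest.raises(ValueError):
            enrichment_score(ranked, ["A", "B"])


class TestGsea:
    def test_planted_set_significant(self):
        m, labels, up = simulate_two_class(seed=1)
        res = TwoClassGSEA(m, labels, [GeneSet("UP", "planted", up)], ("A", "B")).fit(
            n_permutations=1000, seed=17
        )
        r = res.results[0]
        assert r.es > 0
        assert r.fdr_q < 0.25
        assert r.significant

    def test_seed_determinism(self):
        m, labels, up = simulate_two_class(seed=3, n_genes=60, n_shifted=10, n_a=5, n_b=5)
        sets = [GeneSet("UP", "p", up)]
        a = gsea(m, labels, sets, ("A", "B"), n_permutations=100, seed=5)
        b = gsea(m, labels, sets, ("A", "B"), n_permutations=100, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_label_reversal_negates_es(self):
        m, labels, up = simulate_two_class(seed=2, n_genes=50, n_shifted=8, n_a=5, n_b=5)
        sets = [GeneSet("UP", "p", up)]
        fwd = gsea(m, labels, sets, ("A", "B"), n_permutations=50, seed=1)
        rev = gsea(m, labels, sets, ("B", "A"), n_permutations=50, seed=1)
        assert fwd.results[0].es == pytest.approx(-rev.results[0].es, abs=1e-12)

    def test_exhaustive_p_matches_enumeration_oracle(self, rng):
        # 4 + 4 samples: all 70 distinct label splits enumerated
        n_genes = 30
        values = rng.lognormal(size=(n_genes, 8))
        values[:6, :4] *= 2.5
        genes = [f"G{i:02d}" for i in range(n_genes)]
        samples = [f"s{i}" for i in range(8)]
        m = toy_matrix(values, genes, samples)
        labels = {s: ("A" if i < 4 else "B") for i, s in enumerate(samples)}
        members = genes[:6]
        res = gsea(m, labels, [GeneSet("SET", "p", members)], ("A", "B"),
                   n_permutations=70, seed=0)
        assert res.perm_type == "phenotype" and res.n_permutations == 70

        # independent oracle: enumerate splits, recompute metric + ES by hand
        null = []
        for combo in combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(combo)] = True
            scores = pd.Series(
                [snr_oracle(values[i, mask], values[i, ~mask]) for i in range(n_genes)],
                index=genes,
            )
            ordered = scores.iloc[np.lexsort((np.array(genes, object), -scores.to_numpy()))]
            null.append(es_oracle(ordered, members, 1.0))
        # self-contained oracle: observed ES is the first enumerated split
        obs = null[0]
        assert obs == pytest.approx(res.results[0].es, abs=1e-12)
        same = [e for e in null if (e >= 0) == (obs >= 0)]
        expected_p = sum(abs(e) >= abs(obs) for e in same) / len(same)
        assert res.results[0].p_value == pytest.approx(expected_p, abs=1e-12)

    def test_random_sets_are_usually_null(self, rng):
        m, labels, _ = simulate_two_class(seed=9, n_genes=100, n_shifted=1,
                                          shift=0.0, n_a=6, n_b=6)
        calm = 0
        reps = 50
        for i in range(reps):
            members = list(rng.choice(m.gene_ids, size=10, replace=False))
            res = gsea(m, labels, [GeneSet("R", "r", members)], ("A", "B"),
                       n_permutations=100, seed=1000 + i)
            if res.results[0].p_value >= 0.05:
                calm += 1
        assert calm >= 0.9 * reps

    def test_fallback_to_gene_set_permutation(self, caplog):
        m, labels, up = simulate_two_class(seed=4, n_genes=40, n_shifted=8,
                                           n_a=3, n_b=3)
        res = gsea(m, labels, [GeneSet("UP", "p", up)], ("A", "B"),
                   n_permutations=100, seed=2)  # only C(6,3)=20 distinct splits
        assert res.perm_type == "gene_set"

    def test_too_few_permutations_rejected(self):
        m, labels, up = simulate_two_class(seed=5, n_genes=30, n_shifted=5)
        with pytest.raises(ValueError, match="10"):
            gsea(m, labels, [GeneSet("UP", "p", up)], ("A", "B"), n_permutations=5)
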
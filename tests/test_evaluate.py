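"""Enrichment-recall curves, average enrichment, gene bootstrap, tagging diagnostics."""

import numpy as np
import pandas as pd
import pytest

from peaktag.core import EvaluationLinkSet, GeneSet, MultiomeDataset, PeakSet
from peaktag.evaluate import (
    average_enrichment,
    bootstrap_compare,
    diagnostic_correlation,
    enrichment_recall,
    tagging_diagnostics,
)


def links_from(table):
    return EvaluationLinkSet(pd.DataFrame(table, columns=["peak_id", "gene_id", "label"]))


def brute_force_curve(scores, labels):
    """Hand enumeration of enrichment/recall at every unique threshold."""
    uni = len(scores)
    n_true = sum(labels)
    rows = []
    for c in sorted(set(scores), reverse=True):
        pred = [i for i, s in enumerate(scores) if s >= c]
        tp = sum(labels[i] for i in pred)
        recall = tp / n_true
        enrich = (tp / n_true) / (len(pred) / uni)
        rows.append((c, recall, enrich))
    return rows


@pytest.fixture
def toy_links():
    # 10 candidate links for 3 genes, 3 true
    rows = [
        ("p0", "g1", "true"), ("p1", "g1", "false"), ("p2", "g1", "false"),
        ("p0", "g2", "false"), ("p1", "g2", "true"), ("p2", "g2", "false"),
        ("p3", "g2", "false"), ("p0", "g3", "true"), ("p1", "g3", "false"),
        ("p2", "g3", "false"),
    ]
    return links_from(rows)


@pytest.fixture
def toy_scores():
    return pd.DataFrame(
        {
            "peak_id": ["p0", "p1", "p2", "p0", "p1", "p2", "p3", "p0", "p1", "p2"],
            "gene_id": ["g1"] * 3 + ["g2"] * 4 + ["g3"] * 3,
            "score": [0.9, 0.5, 0.1, 0.3, 0.8, 0.2, 0.05, 0.7, 0.6, 0.4],
        }
    )


class TestEnrichmentRecall:
    def test_matches_hand_computation_at_every_threshold(self, toy_links, toy_scores):
        curve = enrichment_recall(toy_scores, toy_links)
        labels = [1, 0, 0, 0, 1, 0, 0, 1, 0, 0]
        expected = brute_force_curve(list(toy_scores["score"]), labels)
        assert len(curve.points) == len(expected)
        for (_, row), (c, rec, enr) in zip(curve.points.iterrows(), expected):
            assert row["threshold"] == pytest.approx(c)
            assert row["recall"] == pytest.approx(rec)
            assert row["enrichment"] == pytest.approx(enr)

    def test_perfect_classifier_first_threshold(self):
        # 20 links, 4 true, perfect separation: first enrichment = 1/f = 5
        rows, scores = [], []
        for i in range(20):
            true = i < 4
            rows.append((f"p{i}", "g0", "true" if true else "false"))
            scores.append({"peak_id": f"p{i}", "gene_id": "g0", "score": 1.0 if true else 0.0})
        curve = enrichment_recall(pd.DataFrame(scores), links_from(rows))
        assert curve.points["enrichment"].iloc[0] == pytest.approx(5.0)

    def test_all_called_enrichment_one_at_full_recall(self, toy_links, toy_scores):
        curve = enrichment_recall(toy_scores, toy_links)
        last = curve.points.iloc[-1]
        assert last["recall"] == 1.0
        assert last["enrichment"] == pytest.approx(1.0)

    def test_untested_pairs_dropped_in_crispr_mode(self, toy_scores):
        rows = [
            ("p0", "g1", "true"), ("p1", "g1", "false"),
            ("p0", "g2", "false"), ("p1", "g2", "true"),
        ]  # everything else untested
        curve = enrichment_recall(toy_scores, links_from(rows), restrict_to_tested=True)
        assert curve.n_universe == 4

    def test_genes_without_true_links_excluded(self, toy_scores):
        rows = [("p0", "g1", "true"), ("p1", "g1", "false")]
        curve = enrichment_recall(toy_scores, links_from(rows))
        assert curve.n_universe == 3  # only g1's candidate links

    def test_zero_true_links_fatal(self, toy_scores):
        with pytest.raises(ValueError, match="no true links"):
            enrichment_recall(toy_scores, links_from([("p0", "g1", "false")]))


class TestAverageEnrichment:
    def test_constant_enrichment_closed_form(self, toy_links, toy_scores):
        curve = enrichment_recall(toy_scores, toy_links)
        avg = average_enrichment({"m": curve})
        pts = curve.at_true_link_points()
        expected = float(np.mean(pts["enrichment"] * (1 - pts["recall"])))
        assert avg["average_enrichment"].iloc[0] == pytest.approx(expected)

    def test_common_recall_truncation(self, toy_links, toy_scores):
        good = enrichment_recall(toy_scores, toy_links)
        # a method that never recovers the last true link: drop the lowest-scored rows
        partial_scores = toy_scores.copy()
        partial_scores.loc[partial_scores["peak_id"] == "p0", "score"] = -1.0  # demote true links
        partial = enrichment_recall(partial_scores, toy_links)
        avg = average_enrichment({"good": good, "partial": partial})
        assert (avg["common_recall"] <= 1.0).all()
        n_r = avg.set_index("method")["n_R"]
        assert n_r["good"] == n_r["partial"]

    def test_invariant_to_monotone_transform(self, toy_links, toy_scores):
        a = enrichment_recall(toy_scores, toy_links)
        t2 = toy_scores.assign(score=np.exp(3 * toy_scores["score"]) + 5)
        b = enrichment_recall(t2, toy_links)
        av = average_enrichment({"a": a, "b": b}).set_index("method")["average_enrichment"]
        assert av["a"] == pytest.approx(av["b"], abs=1e-12)

    def test_random_scores_match_permutation_oracle(self, rng):
        # independent oracle: average enrichment recomputed from the ranks of
        # the true links in the descending score order; and at a fixed
        # prediction size the expected enrichment under permutation is exactly
        # 1 (hypergeometric mean)
        n_links, n_true = 200, 30
        rows = [(f"p{i}", f"g{i % 10}", "true" if i < n_true else "false") for i in range(n_links)]
        links = links_from(rows)
        is_true = np.array([r[2] == "true" for r in rows])
        base = pd.DataFrame({"peak_id": [r[0] for r in rows], "gene_id": [r[1] for r in rows]})
        fixed_k = 100
        enr_at_k = []
        for _ in range(100):
            s = rng.random(n_links)  # unique scores, no ties
            t = base.assign(score=s)
            curve = enrichment_recall(t, links)
            got = average_enrichment({"m": curve})["average_enrichment"].iloc[0]
            order = np.argsort(-s)
            ranks = np.flatnonzero(is_true[order]) + 1  # rank of i-th true link
            expected = np.mean(
                [
                    (i / n_true) / (ranks[i - 1] / n_links) * (1 - i / n_true)
                    for i in range(1, n_true + 1)
                ]
            )
            assert got == pytest.approx(expected, abs=1e-9)
            tp = is_true[order][:fixed_k].sum()
            enr_at_k.append((tp / n_true) / (fixed_k / n_links))
        enr_at_k = np.asarray(enr_at_k)
        se = enr_at_k.std(ddof=1) / np.sqrt(len(enr_at_k))
        assert abs(enr_at_k.mean() - 1.0) < 2 * se + 0.02


class TestBootstrap:
    def test_method_against_itself_null(self, toy_links, toy_scores):
        out = bootstrap_compare({"a": toy_scores, "b": toy_scores.copy()}, toy_links, n_boot=200, seed=1)
        row = out["pairwise"].iloc[0]
        assert row["difference"] == 0.0
        assert row["p"] == 1.0
        assert row["se"] == 0.0

    def test_deterministic_given_seed(self, toy_links, toy_scores):
        a = bootstrap_compare({"m": toy_scores}, toy_links, n_boot=100, seed=5)
        b = bootstrap_compare({"m": toy_scores}, toy_links, n_boot=100, seed=5)
        pd.testing.assert_frame_equal(a["per_method"], b["per_method"])

    def test_noised_null_scores_degrade_average_enrichment(self, rng):
        # method B separates true/false; A is B with extra noise on the null
        # links -> B should win in most bootstrap replicates
        n_genes, per_gene = 25, 8
        rows, recs = [], []
        for g in range(n_genes):
            for p in range(per_gene):
                true = p == 0
                rows.append((f"p{p}", f"g{g}", "true" if true else "false"))
                base = 2.0 if true else rng.normal()
                recs.append({"peak_id": f"p{p}", "gene_id": f"g{g}", "score": base})
        links = links_from(rows)
        b_table = pd.DataFrame(recs)
        a_table = b_table.copy()
        nulls = ~a_table["peak_id"].eq("p0")
        a_table.loc[nulls, "score"] += rng.normal(scale=2.0, size=int(nulls.sum()))
        out = bootstrap_compare({"a": a_table, "b": b_table}, links, n_boot=200, seed=2)
        per = out["per_method"].set_index("method")["average_enrichment"]
        assert per["b"] >= per["a"]
        row = out["pairwise"].iloc[0]
        assert row["difference"] == pytest.approx(per["a"] - per["b"])


class TestTaggingDiagnostics:
    @staticmethod
    def build_dataset(rng, lam=None, n_units=200):
        """One causal peak per gene; negatives = lam * causal + noise.

        ``lam=None`` draws a wide range of tagging strengths per negative peak
        (as real CRISPR-negative peaks span weak to strong taggers); a fixed
        lam makes every negative an equally strong tagger.
        """
        n_genes = 6
        n_neg = 4
        peaks, genes, atac, rna, rows = [], [], [], [], []
        for g in range(n_genes):
            causal = rng.normal(size=n_units)
            expr = causal + 0.5 * rng.normal(size=n_units)
            rna.append(expr)
            genes.append((f"g{g}", "chr1", 3_000_000 + g * 100_000))
            atac.append(causal)
            peaks.append((f"pos{g}", "chr1", 10_000 + g * 50_000))
            rows.append((f"pos{g}", f"g{g}", "true"))
            for k in range(n_neg):
                lam_k = rng.uniform(0.05, 0.95) if lam is None else lam
                tag = lam_k * causal + np.sqrt(1 - lam_k**2) * rng.normal(size=n_units)
                atac.append(tag)
                peaks.append((f"neg{g}_{k}", "chr1", 20_000 + g * 50_000 + k * 2_000))
                rows.append((f"neg{g}_{k}", f"g{g}", "false"))
        pk = PeakSet(
            [p[0] for p in peaks], [p[1] for p in peaks],
            [p[2] for p in peaks], [p[2] + 500 for p in peaks],
        )
        gn = GeneSet([g[0] for g in genes], [g[1] for g in genes], [g[2] for g in genes], ["+"] * n_genes)
        ds = MultiomeDataset(np.column_stack(atac), np.column_stack(rna), pk, gn)
        return ds, links_from(rows)

    def test_identical_negative_equals_positive_correlations(self, rng):
        ds, links = self.build_dataset(rng, lam=1.0)
        pairs = tagging_diagnostics(ds, links)
        np.testing.assert_allclose(pairs["r_with_positive"], 1.0, atol=1e-9)
        # r(neg, gene) == r(pos, gene) when neg == pos
        merged = pairs.merge(
            pd.DataFrame({"gene_id": ds.genes.ids}), on="gene_id"
        )
        assert len(merged) == len(pairs)

    def test_generative_tagging_model_high_pair_correlation(self, rng):
        ds, links = self.build_dataset(rng)
        pairs = tagging_diagnostics(ds, links, r_threshold=0.45)
        assert len(pairs) > 0
        assert diagnostic_correlation(pairs) > 0.8

    def test_no_negative_peaks_empty(self, rng):
        ds, links = self.build_dataset(rng)
        only_true = EvaluationLinkSet(links.table[links.table["label"] == "true"].reset_index(drop=True))
        out = tagging_diagnostics(ds, only_true)
        assert out.empty

    def test_gene_level_mirror(self, rng):
        ds, links = self.build_dataset(rng)
        # swap roles: label gene-level positives for each causal peak
        out = tagging_diagnostics(ds, links, level="peak")
        assert set(out.columns) == {"peak_id", "positive_gene", "negative_gene", "r_with_positive", "r_with_focal"}
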
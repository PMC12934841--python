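"""Stratified scores, regression/enrichment estimation, jackknife, meta-analysis."""

import numpy as np
import pandas as pd
import pytest

from peaktag.core import GeneSet, PeakSet
from peaktag.scasc import (
    CategoryAnnotation,
    builtin_categories,
    fit_stratified_regression,
    kmeans_blocks,
    meta_analyze,
    read_categories,
    stratified_scores,
    write_categories,
)
from peaktag.scores import co_accessibility_scores
from peaktag.synth import stratified_model_sim
from test_scores import pearson_loop


def three_overlapping_categories(rng, peak_ids):
    n = len(peak_ids)
    m = pd.DataFrame(
        {
            "catA": (rng.random(n) < 0.4).astype(float),
            "catB": (rng.random(n) < 0.5).astype(float),
            "frac": rng.random(n).round(3),  # probabilistic category
        },
        index=peak_ids,
    )
    return CategoryAnnotation(peak_ids, m)


class TestStratifiedScores:
    def test_all_category_equals_plain_score(self, small_dataset, rng):
        cats = three_overlapping_categories(rng, small_dataset.peaks.ids)
        b = 0.01
        table = stratified_scores(small_dataset, cats, bias_x=b)
        plain = co_accessibility_scores(small_dataset, b)
        np.testing.assert_allclose(table["x::all"], plain["score"], atol=1e-10)

    def test_empty_category_is_pure_bias_column(self, small_dataset):
        ids = small_dataset.peaks.ids
        cats = CategoryAnnotation(ids, pd.DataFrame({"empty": np.zeros(len(ids))}, index=ids))
        b = 0.02
        table = stratified_scores(small_dataset, cats, bias_x=b)
        plain = co_accessibility_scores(small_dataset, 0.0)
        np.testing.assert_allclose(table["x::empty"], -b * plain["n_cis_partners"], atol=1e-12)

    def test_matches_brute_force_triple_loop(self, small_dataset, rng):
        cats = three_overlapping_categories(rng, small_dataset.peaks.ids)
        b = 0.013
        table = stratified_scores(small_dataset, cats, bias_x=b)
        A = small_dataset.atac
        pc, pch = small_dataset.peaks.centers, small_dataset.peaks.chroms
        member = cats.membership
        for cat in cats.category_names:
            I = member[cat].to_numpy()
            for j in range(len(pc)):
                expected = 0.0
                for k in range(len(pc)):
                    if pch[k] == pch[j] and abs(int(pc[k]) - int(pc[j])) < 1_000_000:
                        expected += I[k] * pearson_loop(A[:, j], A[:, k]) ** 2 - b
                assert table[f"x::{cat}"].iloc[j] == pytest.approx(expected, abs=1e-10)

    def test_partition_consistent_option_sums_to_plain_score(self, small_dataset):
        ids = small_dataset.peaks.ids
        half = np.zeros(len(ids))
        half[: len(ids) // 2] = 1.0
        m = pd.DataFrame({"left": half, "right": 1.0 - half}, index=ids)
        cats = CategoryAnnotation(ids, m)
        b = 0.015
        table = stratified_scores(small_dataset, cats, bias_x=b, partition_consistent=True)
        np.testing.assert_allclose(
            table["x::left"] + table["x::right"], table["x::all"], atol=1e-10
        )

    def test_genome_wide_refused_by_default(self, small_dataset, rng):
        cats = three_overlapping_categories(rng, small_dataset.peaks.ids)
        with pytest.raises(ValueError, match="genome-wide"):
            stratified_scores(small_dataset, cats, genome_wide=True)
        table = stratified_scores(small_dataset, cats, genome_wide=True, allow_genome_wide=True)
        assert np.isfinite(table.filter(like="x::").to_numpy()).all()

    def test_missing_elements_fatal_with_ids(self, small_dataset):
        ids = small_dataset.peaks.ids[:-2]
        cats = CategoryAnnotation(ids, pd.DataFrame({"c": np.ones(len(ids))}, index=ids))
        with pytest.raises(ValueError, match="missing from category"):
            stratified_scores(small_dataset, cats)


class TestRegression:
    def test_enrichment_of_all_is_exactly_one(self):
        table, member, _ = stratified_model_sim(n_elements=500, seed=4)
        cats = CategoryAnnotation(member.index.to_numpy(), member)
        res = fit_stratified_regression(table, cats)
        assert res.enrichment["all"] == pytest.approx(1.0, abs=1e-9)

    def test_single_enriched_category_converges_to_inverse_fraction(self):
        table, member, expected = stratified_model_sim(n_elements=20_000, seed=1)
        cats = CategoryAnnotation(member.index.to_numpy(), member)
        res = fit_stratified_regression(table, cats)
        est = res.enrichment["category"]
        assert abs(est - expected) / expected < 0.05
        # closed form: all causal variance in the category at fraction f -> 1/f
        f = member["category"].mean()
        assert expected == pytest.approx(1.0 / f)

    def test_uniform_causal_variance_gives_unit_enrichments(self):
        table, member, expected = stratified_model_sim(
            n_elements=20_000, tau_all=0.3, tau_category=0.0, seed=2
        )
        cats = CategoryAnnotation(member.index.to_numpy(), member)
        res = fit_stratified_regression(table, cats)
        assert expected == pytest.approx(1.0)
        assert abs(res.enrichment["category"] - 1.0) < 0.05

    def test_equivariant_under_element_permutation(self):
        table, member, _ = stratified_model_sim(n_elements=800, seed=5)
        cats = CategoryAnnotation(member.index.to_numpy(), member)
        res = fit_stratified_regression(table, cats)
        perm = np.random.default_rng(0).permutation(len(table))
        res_p = fit_stratified_regression(table.iloc[perm].reset_index(drop=True), cats)
        pd.testing.assert_series_equal(res.tau, res_p.tau, atol=1e-8, rtol=1e-6)
        pd.testing.assert_series_equal(res.enrichment, res_p.enrichment, atol=1e-8, rtol=1e-6)

    def test_collinear_categories_fatal_naming_them(self):
        table, member, _ = stratified_model_sim(n_elements=400, seed=6)
        member = member.copy()
        member["dup"] = member["category"]
        table = table.copy()
        table["x::dup"] = table["x::category"]
        cats = CategoryAnnotation(member.index.to_numpy(), member)
        with pytest.raises(np.linalg.LinAlgError, match="category|dup"):
            fit_stratified_regression(table, cats)

    def test_summary_renders(self):
        table, member, _ = stratified_model_sim(n_elements=500, seed=7)
        cats = CategoryAnnotation(member.index.to_numpy(), member)
        res = fit_stratified_regression(table, cats)
        res.jackknife()
        text = res.summary()
        assert "category" in text and "enrichment" in text


class TestJackknife:
    def test_duplicated_blocks_zero_se(self):
        table, member, _ = stratified_model_sim(n_elements=600, n_blocks=1, seed=8)
        # two identical copies labelled as two blocks
        double = pd.concat([table, table], ignore_index=True)
        double["element_id"] = [f"e{i}" for i in range(len(double))]
        double["block"] = ["b0"] * len(table) + ["b1"] * len(table)
        m2 = pd.concat([member, member], ignore_index=True)
        m2.index = double["element_id"]
        cats = CategoryAnnotation(double["element_id"].to_numpy(), m2)
        res = fit_stratified_regression(double, cats)
        jk = res.jackknife()
        np.testing.assert_allclose(jk["se"], 0.0, atol=1e-8)

    def test_single_block_fatal(self):
        table, member, _ = stratified_model_sim(n_elements=300, n_blocks=1, seed=9)
        cats = CategoryAnnotation(member.index.to_numpy(), member)
        res = fit_stratified_regression(table, cats)
        with pytest.raises(ValueError, match=">= 2"):
            res.jackknife()

    def test_calibrated_against_fresh_replicates(self):
        # jackknife SE should track the spread of the estimator across
        # independent replicates of the same study
        ests, ses = [], []
        for s in range(60):
            table, member, _ = stratified_model_sim(n_elements=3000, seed=900 + s)
            cats = CategoryAnnotation(member.index.to_numpy(), member)
            res = fit_stratified_regression(table, cats)
            jk = res.jackknife()
            row = jk[jk["category"] == "category"].iloc[0]
            ests.append(row["enrichment"])
            ses.append(row["se"])
        ratio = np.mean(ses) / np.std(ests, ddof=1)
        assert 0.6 < ratio < 1.6

    def test_category_confined_to_one_block_flagged_unstable(self):
        table, member, _ = stratified_model_sim(n_elements=400, n_blocks=4, seed=10)
        member = member.copy()
        confined = np.zeros(len(member))
        confined[table["block"] == "block0"] = 1.0
        member["confined"] = confined
        table = table.copy()
        table["x::confined"] = table["x::category"] * confined[np.arange(len(confined))]
        cats = CategoryAnnotation(member.index.to_numpy(), member)
        res = fit_stratified_regression(table, cats)
        with pytest.warns(UserWarning, match="unstable"):
            jk = res.jackknife()
        assert jk.loc[jk["category"] == "confined", "unstable"].iloc[0]


class TestMetaAnalysis:
    @staticmethod
    def frame(e, se):
        return pd.DataFrame({"category": ["c1"], "enrichment": [e], "se": [se]})

    def test_identical_inputs_return_input(self):
        a = self.frame(1.5, 0.2)
        pooled = meta_analyze([a, a.copy()])
        assert pooled["enrichment"].iloc[0] == pytest.approx(1.5)
        assert pooled["tau2_meta"].iloc[0] == pytest.approx(0.0)
        assert pooled["se"].iloc[0] <= 0.2 + 1e-12

    def test_dersimonian_laird_closed_form(self):
        pooled = meta_analyze([self.frame(1.0, 0.1), self.frame(3.0, 0.1)])
        # independent closed form: w=100 each -> fixed=2, Q=200, C=100,
        # tau2=(200-1)/100=1.99, equal weights -> pooled still 2
        assert pooled["enrichment"].iloc[0] == pytest.approx(2.0, abs=1e-10)
        assert pooled["tau2_meta"].iloc[0] == pytest.approx(1.99, abs=1e-10)
        expected_se = np.sqrt(1.0 / (2.0 / (0.01 + 1.99)))
        assert pooled["se"].iloc[0] == pytest.approx(expected_se, abs=1e-10)

    def test_single_input_passthrough_with_warning(self):
        with pytest.warns(UserWarning, match="single input"):
            pooled = meta_analyze([self.frame(2.5, 0.4)])
        assert pooled["enrichment"].iloc[0] == 2.5

    def test_fixed_effect_limit_se_bound(self):
        pooled = meta_analyze([self.frame(1.2, 0.3), self.frame(1.2, 0.1)])
        assert pooled["tau2_meta"].iloc[0] == 0.0
        assert pooled["se"].iloc[0] <= 0.3


class TestBuiltinCategories:
    def setup_method(self):
        rng = np.random.default_rng(3)
        starts = np.sort(rng.choice(np.arange(2, 200) * 2500, size=50, replace=False))
        self.peaks = PeakSet([f"p{i}" for i in range(50)], ["chr1"] * 50, starts, starts + 400)
        tss = np.sort(rng.choice(np.arange(1, 480) * 1000 + 137, size=12, replace=False))
        self.genes = GeneSet([f"g{i}" for i in range(12)], ["chr1"] * 12, tss, ["+"] * 12)

    def test_window_edge_excluded_half_open(self):
        peaks = PeakSet(["edge"], ["chr1"], [11_000], [11_300])
        genes = GeneSet(["g"], ["chr1"], [1000], ["+"])  # window [0, 11000)
        cats = builtin_categories(peaks, genes, tss_windows=(10_000,))
        assert cats.membership["TSS±10kb"].iloc[0] == 0.0

    def test_constraint_fraction_inside_region_is_one(self):
        peaks = PeakSet(["in", "half"], ["chr1", "chr1"], [100, 1000], [200, 1200])
        genes = GeneSet(["g"], ["chr1"], [900_000], ["+"])
        constrained = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1100]})
        cats = builtin_categories(peaks, genes, constraint_intervals=constrained)
        assert cats.membership["Constraint"].loc["in"] == 1.0
        assert cats.membership["Constraint"].loc["half"] == pytest.approx(0.5)

    def test_closest_to_tss_matches_brute_force(self):
        cats = builtin_categories(self.peaks, self.genes)
        got = set(np.flatnonzero(cats.membership["Closest to TSS"].to_numpy()))
        expected = set()
        for t in self.genes.tss:
            d = np.abs(self.peaks.centers - t)
            expected.add(int(np.argmin(d)))
        assert got == expected

    def test_binary_feature_category_any_overlap(self):
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [self.peaks.starts[5] - 50], "end": [self.peaks.starts[5] + 10]})
        cats = builtin_categories(self.peaks, self.genes, feature_intervals={"mark": iv})
        vals = cats.membership["mark"]
        assert vals.iloc[5] == 1.0
        assert vals.sum() == 1.0

    def test_gene_level_closest_to_peak(self):
        cats = builtin_categories(self.peaks, self.genes, level="gene")
        got = set(np.flatnonzero(cats.membership["Closest to peak"].to_numpy()))
        expected = set()
        for c in self.peaks.centers:
            expected.add(int(np.argmin(np.abs(self.genes.tss - c))))
        assert got == expected
        assert "Peak±10kb" in cats.membership

    def test_empty_category_warns_but_kept(self):
        iv = pd.DataFrame({"chrom": ["chrZ"], "start": [0], "end": [100]})
        with pytest.warns(UserWarning, match="empty"):
            cats = builtin_categories(self.peaks, self.genes, feature_intervals={"never": iv})
        assert "never" in cats.membership


class TestCategoryIO:
    def test_round_trip(self, tmp_path, rng):
        ids = [f"p{i}" for i in range(20)]
        m = pd.DataFrame({"a": (rng.random(20) < 0.5).astype(float), "frac": rng.random(20).round(4)})
        cats = CategoryAnnotation(np.array(ids, dtype=object), m, blocks=["chr1"] * 10 + ["chr2"] * 10)
        path = tmp_path / "cats.tsv"
        write_categories(cats, str(path))
        back = read_categories(str(path))
        pd.testing.assert_frame_equal(back.membership, cats.membership)
        np.testing.assert_array_equal(back.blocks, cats.blocks)

    def test_kmeans_blocks_deterministic(self, rng):
        X = rng.normal(size=(30, 25))
        b1 = kmeans_blocks(X, n_blocks=4, seed=2)
        b2 = kmeans_blocks(X, n_blocks=4, seed=2)
        np.testing.assert_array_equal(b1, b2)
        assert len(np.unique(b1)) == 4
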
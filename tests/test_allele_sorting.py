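"""Per-SNP FST, outlier flags, ancestry categories and enrichment tests."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hybridtrace as ht
from hybridtrace import allele_sorting as aso
from hybridtrace.genotype_io import MISSING


def make_gm(calls, groups):
    calls = np.asarray(calls, dtype=np.int8)
    sites = pd.DataFrame(
        {"scaffold": "s1", "pos": np.arange(1, len(calls) + 1), "ref": "A", "alt": "T"}
    )
    samples = [f"x{i}" for i in range(calls.shape[1])]
    gm = ht.GenotypeMatrix(sites, samples, calls)
    pm = ht.PopulationMap(dict(zip(samples, groups)))
    return gm, pm


def fisher_two_sided_enumeration(a, b, c, d):
    """Exhaustive hypergeometric two-sided Fisher p for a 2x2 table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    def pr(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom
    p_obs = pr(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pr(x) for x in range(lo, hi + 1) if pr(x) <= p_obs * (1 + 1e-9))


class TestGlobalFst:
    def test_fixed_difference_gives_one(self):
        calls = np.zeros((1, 10), dtype=np.int8)
        calls[0, 5:] = 2
        gm, pm = make_gm(calls, ["s1"] * 5 + ["s2"] * 5)
        fst = aso.global_fst(gm, pm, ["s1", "s2"])
        assert fst.theta[0] == pytest.approx(1.0)

    def test_identical_frequencies_near_zero_overall(self):
        """Species sampled from one frequency: multi-locus theta ~ 0."""
        rng = np.random.default_rng(5)
        p = rng.uniform(0.2, 0.8, 500)
        calls = rng.binomial(2, p[:, None], size=(500, 20)).astype(np.int8)
        gm, pm = make_gm(calls, ["s1"] * 10 + ["s2"] * 10)
        fst = aso.global_fst(gm, pm, ["s1", "s2"])
        assert fst.overall_theta == pytest.approx(0.0, abs=0.02)

    def test_matches_textbook_component_arithmetic(self):
        """2 species x 5 diploids: compare against a scalar transcription of
        the Weir-Cockerham (1984) a/b/c components."""
        g1 = [0, 1, 1, 2, 2]
        g2 = [0, 0, 0, 1, 2]
        gm, pm = make_gm([g1 + g2], ["s1"] * 5 + ["s2"] * 5)
        fst = aso.global_fst(gm, pm, ["s1", "s2"])

        r = 2
        n1 = n2 = 5.0
        p1 = sum(g1) / (2 * n1)
        p2 = sum(g2) / (2 * n2)
        h1 = sum(1 for g in g1 if g == 1) / n1
        h2 = sum(1 for g in g2 if g == 1) / n2
        n_bar = (n1 + n2) / r
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        assert fst.theta[0] == pytest.approx(a / (a + b + c))

    def test_monomorphic_site_undefined(self):
        gm, pm = make_gm([[0] * 10], ["s1"] * 5 + ["s2"] * 5)
        fst = aso.global_fst(gm, pm, ["s1", "s2"])
        assert np.isnan(fst.theta[0])

    def test_negative_estimates_not_clamped(self):
        rng = np.random.default_rng(0)
        calls = rng.binomial(2, 0.5, size=(300, 12)).astype(np.int8)
        gm, pm = make_gm(calls, ["s1"] * 6 + ["s2"] * 6)
        fst = aso.global_fst(gm, pm, ["s1", "s2"])
        assert (fst.theta < 0).any()


class TestFlagOutliers:
    def island_fst(self, seed=0, n_sites=4000):
        gm, pm, _ = ht.simulate_sorting_dataset(
            n_sites=n_sites, frac_fixed=0.0, bdm_sorting=False, seed=seed,
            n_control_pairs=0,
        )
        lv = [g for g in pm.group_names if g.startswith("lv_")]
        return aso.global_fst(gm, pm, lv)

    def test_neutral_data_flags_about_five_percent(self):
        fst = self.island_fst()
        out, p = aso.flag_outliers(fst, aso.IslandNullConfig(seed=3, n_sim=20_000))
        ok = np.isfinite(fst.theta)
        assert 0.02 <= out[ok].mean() <= 0.09

    def test_extreme_snp_flagged(self):
        fst = self.island_fst(seed=1, n_sites=500)
        fst.theta[0] = 1.0
        fst.heterozygosity[0] = 0.3
        out, p = aso.flag_outliers(fst, aso.IslandNullConfig(seed=4, n_sim=5_000))
        assert out[0]

    def test_degenerate_threshold_flags_everything(self):
        fst = self.island_fst(seed=2, n_sites=300)
        out, p = aso.flag_outliers(fst, aso.IslandNullConfig(seed=5, n_sim=2_000),
                                   p_threshold=1.1)
        assert out[np.isfinite(fst.theta)].all()

    def test_quantile_mode_flags_top_fraction(self):
        fst = self.island_fst(seed=3, n_sites=2000)
        out, p = aso.flag_outliers(fst, method="quantile", p_threshold=0.05)
        frac = out[np.isfinite(fst.theta)].mean()
        assert 0.03 <= frac <= 0.06


class TestClassifyCategories:
    def build(self, congo, nile, lv=(0, 1, 2)):
        """Rows: one SNP; LV group of 3, congo of 3, nile of 3 diploids."""
        calls = np.array([list(lv) + list(congo) + list(nile)], dtype=np.int8)
        groups = ["lv"] * 3 + ["congo"] * 3 + ["nile"] * 3
        gm, pm = make_gm(calls, groups)
        return aso.classify_categories(gm, pm, ["lv"], "congo", "nile")

    def test_divergently_fixed_is_category_4(self):
        df = self.build(congo=(0, 0, 0), nile=(2, 2, 2))
        assert df["category"][0] == "4"

    def test_congolese_polymorphic_is_category_2(self):
        df = self.build(congo=(0, 1, 2), nile=(2, 2, 2))
        assert df["category"][0] == "2"

    def test_congo_fixed_nile_polymorphic_is_category_3(self):
        df = self.build(congo=(0, 0, 0), nile=(0, 1, 2))
        assert df["category"][0] == "3"

    def test_one_parental_allele_only_is_category_1(self):
        df = self.build(congo=(0, 0, 0), nile=(0, 0, 0))
        assert df["category"][0] == "1"

    def test_lv_monomorphic_excluded(self):
        df = self.build(congo=(0, 1, 2), nile=(0, 0, 0), lv=(2, 2, 2))
        assert df["category"][0] == "excluded"

    def test_insufficient_parental_calls_excluded(self):
        df = self.build(congo=(0, 0, MISSING), nile=(2, 2, 2))
        assert df["category"][0] == "excluded"

    def test_categories_partition_classified_snps(self):
        gm, pm, _ = ht.simulate_sorting_dataset(n_sites=3000, seed=6)
        lv = [g for g in pm.group_names if g.startswith("lv_")]
        df = aso.classify_categories(gm, pm, lv, "congolese", "upper_nile")
        masks = [(df["category"] == c).to_numpy() for c in "1234"]
        stacked = np.vstack(masks).sum(axis=0)
        classified = (df["category"] != "excluded").to_numpy()
        assert (stacked[classified] == 1).all()
        assert (stacked[~classified] == 0).all()


class TestSelectControlSet:
    def test_worked_example_0164_included(self):
        """pC=0.1, pN=0.5 with 0.84/0.16 weights: weighted frequency 0.164."""
        flags, wmaf = aso.select_control_set(
            np.array([0.1]), np.array([0.5]), np.array([False])
        )
        assert wmaf[0] == pytest.approx(0.164)
        assert flags[0]

    def test_divergently_fixed_excluded_despite_weight(self):
        """pC=0, pN=1 weights to 0.16 but is excluded as divergently fixed."""
        flags, wmaf = aso.select_control_set(
            np.array([0.0]), np.array([1.0]), np.array([True])
        )
        assert wmaf[0] == pytest.approx(0.16)
        assert not flags[0]

    def test_half_half_outside_window(self):
        flags, wmaf = aso.select_control_set(
            np.array([0.5]), np.array([0.5]), np.array([False])
        )
        assert wmaf[0] == pytest.approx(0.5) and not flags[0]

    def test_folding_to_minor_allele(self):
        flags, wmaf = aso.select_control_set(
            np.array([0.9]), np.array([0.5]), np.array([False])
        )
        assert wmaf[0] == pytest.approx(1 - (0.9 * 0.84 + 0.5 * 0.16))
        assert flags[0]


class TestEnrichment:
    def run(self, cat_out, cat_n, ref_out, ref_n):
        n = cat_n + ref_n
        masks = {
            "4": np.arange(n) < cat_n,
            aso.CONTROL_LABEL: np.arange(n) >= cat_n,
        }
        outliers = np.zeros(n, dtype=bool)
        outliers[:cat_out] = True
        outliers[cat_n:cat_n + ref_out] = True
        res = aso.enrichment(masks, outliers)
        return res.table.set_index("category").loc["4", "p_vs_reference"]

    def test_balanced_table_p_one(self):
        assert self.run(1, 2, 1, 2) == pytest.approx(1.0)

    def test_perfect_association_matches_enumeration(self):
        p = self.run(10, 10, 0, 10)
        assert p == pytest.approx(fisher_two_sided_enumeration(10, 0, 0, 10))

    def test_equal_proportions_near_one(self):
        assert self.run(5, 50, 5, 50) > 0.99

    def test_fisher_matches_enumeration_for_small_margins(self):
        """scipy's two-sided Fisher equals the exhaustive-table oracle for
        every 2x2 table with margins <= 30 (sampled grid)."""
        for a in range(0, 13, 3):
            for b in range(0, 13, 4):
                for c in range(0, 13, 4):
                    for d in range(0, 13, 3):
                        if a + b == 0 or c + d == 0:
                            continue
                        _, p = stats.fisher_exact([[a, b], [c, d]])
                        assert p == pytest.approx(
                            fisher_two_sided_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
                        ), (a, b, c, d)


class TestWeightRobustness:
    def test_weight_016_reproduces_default(self):
        gm, pm, truth = ht.simulate_sorting_dataset(n_sites=3000, seed=8)
        lv = [g for g in pm.group_names if g.startswith("lv_")]
        fst = aso.global_fst(gm, pm, lv)
        out, _ = aso.flag_outliers(fst, method="quantile")
        df = aso.classify_categories(gm, pm, lv, "congolese", "upper_nile")
        cat4 = (df["category"] == "4").to_numpy()
        pc = df["congolese_freq"].to_numpy()
        pn = df["upper_nile_freq"].to_numpy()
        masks = {c: (df["category"] == c).to_numpy() for c in "1234"}
        default_flags, _ = aso.select_control_set(pc, pn, cat4)
        masks[aso.CONTROL_LABEL] = default_flags
        default = aso.enrichment(masks, out)

        sweep = aso.weight_robustness(masks, pc, pn, cat4, out,
                                      nile_weights=np.array([0.16, 0.30]))
        pd.testing.assert_frame_equal(sweep[0.16].table, default.table)
        assert not sweep[0.30].table.equals(default.table)


class TestControlFixation:
    def test_no_fixed_differences_p_one_with_warning(self):
        # pair fixed for the same allele everywhere; 2 cat-4 sites
        calls = np.array([[0, 0, 0, 0, 0, 0]] * 2, dtype=np.int8)
        gm, pm = make_gm(calls, ["a"] * 3 + ["b"] * 3)
        with pytest.warns(UserWarning, match="no fixed differences"):
            out = aso.control_fixation_test(
                gm, pm, [("a", "b")], np.array([True, True]), np.array([True, False])
            )
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_built_table_matches_enumeration(self):
        """20 cat-4 sites arranged to give the 2x2 table (3,7;2,8)."""
        rows = []
        outliers = []
        # outlier sites: 3 differentially fixed, 7 not
        for fixed in [True] * 3 + [False] * 7:
            rows.append([0, 0, 0] + ([2, 2, 2] if fixed else [0, 0, 0]))
            outliers.append(True)
        for fixed in [True] * 2 + [False] * 8:
            rows.append([0, 0, 0] + ([2, 2, 2] if fixed else [0, 0, 0]))
            outliers.append(False)
        gm, pm = make_gm(rows, ["a"] * 3 + ["b"] * 3)
        out = aso.control_fixation_test(
            gm, pm, [("a", "b")], np.ones(20, dtype=bool), np.array(outliers)
        )
        assert out["p"].iloc[0] == pytest.approx(fisher_two_sided_enumeration(3, 7, 2, 8))

    def test_ancestry_independent_fixation_not_enriched(self):
        """Control pairs outside the radiation: outlier status should not
        predict fixation, so p-values are not systematically small."""
        ps = []
        for seed in range(5):
            gm, pm, truth = ht.simulate_sorting_dataset(
                n_sites=4000, seed=40 + seed, bdm_sorting=True
            )
            lv = [g for g in pm.group_names if g.startswith("lv_")]
            fst = aso.global_fst(gm, pm, lv)
            out, _ = aso.flag_outliers(fst, method="quantile")
            df = aso.classify_categories(gm, pm, lv, "congolese", "upper_nile")
            cat4 = (df["category"] == "4").to_numpy()
            res = aso.control_fixation_test(
                gm, pm, [("control_1a", "control_1b"), ("control_2a", "control_2b")],
                cat4, out,
            )
            ps.extend(res["p"].tolist())
        assert np.median(ps) > 0.05
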
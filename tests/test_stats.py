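import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.formula.api as smf
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from reformulate import classifier, matching, stats, synth
from reformulate.stats import (
    StatsError,
    bh_adjust,
    chi_square,
    fit_fsanz_model,
    fit_reformulation_model,
    summarize_prices,
    wilcoxon_paired,
)


def exact_signrank_p_two_sided(diffs):
    """Independent oracle: enumerate all 2^n sign patterns of |diffs| ranks."""
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    w_all = [np.array(signs) @ ranks for signs in itertools.product([0, 1], repeat=n)]
    w_all = np.array(w_all)
    mu = ranks.sum() / 2
    p = np.mean(np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-12)
    return p


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        res = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.pvalue == 1.0

    def test_all_positive_n5_matches_enumeration(self):
        y1 = np.zeros(5)
        y2 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_paired(y1, y2)
        assert res.pvalue == pytest.approx(2 / 32)
        assert res.pvalue == pytest.approx(exact_signrank_p_two_sided(y2 - y1))

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration_random_small(self, seed):
        rng = np.random.default_rng(seed)
        diffs = rng.normal(size=7)
        res = wilcoxon_paired(np.zeros(7), diffs)
        assert res.pvalue == pytest.approx(exact_signrank_p_two_sided(diffs))

    def test_missing_pairs_dropped(self):
        res = wilcoxon_paired([1.0, np.nan, 3.0], [2.0, 5.0, 4.0])
        assert res.n_used == 2

    def test_unequal_lengths_error(self):
        with pytest.raises(StatsError):
            wilcoxon_paired([1.0], [1.0, 2.0])

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(300):
            d = rng.normal(size=40)
            pvals.append(wilcoxon_paired(np.zeros(40), d).pvalue)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


class TestChiSquare:
    def test_hand_computed_example(self):
        stat, df, p = chi_square([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(20 / 3, 1))

    def test_independence_gives_zero(self):
        stat, df, _ = chi_square([[10, 20], [30, 60]])  # proportional to margins
        assert stat == pytest.approx(0.0)

    def test_uniform_2x2(self):
        stat, df, p = chi_square([[5, 5], [5, 5]])
        assert stat == 0.0 and df == 1

    def test_zero_margin_error(self):
        with pytest.raises(StatsError):
            chi_square([[0, 0], [5, 5]])

    def test_matches_scipy_uncorrected(self):
        rng = np.random.default_rng(0)
        table = rng.integers(5, 50, size=(3, 4))
        stat, df, p = chi_square(table)
        ref = sps.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert df == ref.dof
        assert p == pytest.approx(ref.pvalue)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_stepup_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_error(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_adjusted_at_least_raw(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=20),
           st.randoms())
    def test_permutation_invariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj = bh_adjust(pvals)
        adj_perm = bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose([adj[i] for i in perm], adj_perm, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_statsmodels(self, seed):
        p = np.random.default_rng(seed).uniform(size=25)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


def _classified_pairs(n=800, seed=1, **kw):
    cfg = synth.SupplyConfig(n_products=n, seed=seed, **kw)
    db1, db2, truth = synth.generate_supply(cfg)
    pairs, _ = matching.match_products(db1, db2)
    classifier.classify_pairs(pairs, classifier.load_dv_table())
    return pairs


class TestReformulationModel:
    def test_recovers_injected_effect(self):
        beta = 0.30
        pairs = _classified_pairs(
            n=2500, seed=5, price_noise_sd=0.15,
            nutrient_baselines={**synth.DEFAULT_NUTRIENT_BASELINES, "sodium_mg": (800.0, 400.0)},
            reformulation_prevalence={"sodium_mg": 0.35},
            reformulation_magnitude={"sodium_mg": (20.0, 10.0)},
            price_effect_beta={("*", "sodium_mg", "large_decrease"): beta},
        )
        ests, info = fit_reformulation_model(pairs, "sodium_mg")
        by_term = {e.term.split(":")[1]: e for e in ests}
        est = by_term["large_decrease"]
        assert est.ci_low <= beta <= est.ci_high
        assert abs(est.beta - beta) < 0.1

    def test_single_retailer_equals_ols_oracle(self):
        pairs = _classified_pairs(n=600, seed=9, n_retailers=1)
        ests, info = fit_reformulation_model(pairs, "sodium_mg")
        assert info.fallback_ols
        frame = stats._pairs_frame(pairs, nutrient="sodium_mg")
        frame = frame[~frame.group.isin(info.dropped_groups)].reset_index(drop=True)
        frame["container_std"] = stats._standardize(frame["container_size"].astype(float))
        ref = smf.ols(
            "delta_price ~ C(group, Treatment('little_change'))"
            " + container_std + C(brand_type, Treatment('multinational'))",
            frame,
        ).fit()
        for est in ests:
            level = est.term.split(":")[1]
            name = f"C(group, Treatment('little_change'))[T.{level}]"
            assert est.beta == pytest.approx(ref.params[name], abs=1e-6)

    def test_small_groups_dropped(self):
        pairs = _classified_pairs(n=120, seed=3,
                                  reformulation_prevalence={"sodium_mg": 0.05})
        ests, info = fit_reformulation_model(pairs, "sodium_mg", min_group_n=50)
        assert ests == []
        assert info.skipped or info.dropped_groups

    def test_no_usable_pairs_returns_empty(self):
        ests, info = fit_reformulation_model([], "sodium_mg")
        assert ests == [] and info.skipped


class TestFsanzModel:
    def _pairs_with_coupling(self, slope, n=1200, seed=4, noise=0.05):
        rng = np.random.default_rng(seed)
        pairs = _classified_pairs(n=n, seed=seed, price_noise_sd=0.0, inflation_rate=0.0)
        for p in pairs:
            p.fsanz_score_change = int(rng.integers(-4, 5))
            p.delta_price = slope * p.fsanz_score_change + rng.normal(0, noise)
        return pairs

    def test_recovers_synthetic_slope(self):
        slope = 0.05
        ests, _ = fit_fsanz_model(self._pairs_with_coupling(slope), grouping="overall")
        est = ests[0]
        assert est.ci_low <= slope <= est.ci_high
        assert abs(est.beta - slope) < 0.02

    def test_zero_coupling_ci_covers_zero_mostly(self):
        hits = 0
        for seed in range(20):
            ests, _ = fit_fsanz_model(
                self._pairs_with_coupling(0.0, n=300, seed=seed), grouping="overall"
            )
            est = ests[0]
            hits += est.ci_low <= 0.0 <= est.ci_high
        assert hits >= 17  # ≥ 90 % nominal with slack at 20 replicates

    def test_constant_predictor_skipped(self):
        pairs = self._pairs_with_coupling(0.0, n=120, seed=2)
        for p in pairs:
            p.fsanz_score_change = 0
        ests, skipped = fit_fsanz_model(pairs, grouping="overall")
        assert ests == []
        assert skipped[0]["reason"] == "constant predictor"

    def test_low_n_cells_skipped_per_category(self):
        pairs = self._pairs_with_coupling(0.0, n=60, seed=3)
        ests, skipped = fit_fsanz_model(pairs, grouping="tra_category", min_cell_n=50)
        assert ests == []
        assert all(s["reason"] == "below minimum n" for s in skipped)


class TestInflationCancellation:
    def test_constant_shift_moves_no_exposure_coefficient(self):
        pairs = _classified_pairs(n=700, seed=6, price_noise_sd=0.1)
        base, _ = fit_reformulation_model(pairs, "sodium_mg")
        for p in pairs:
            if p.delta_price is not None:
                p.delta_price += 2.5
        shifted, _ = fit_reformulation_model(pairs, "sodium_mg")
        assert len(base) == len(shifted) > 0
        for a, b in zip(base, shifted):
            assert abs(a.beta - b.beta) <= 1e-8
            assert abs(a.ci_low - b.ci_low) <= 1e-8
            assert abs(a.ci_high - b.ci_high) <= 1e-8


class TestSummarizePrices:
    def test_identical_years_degenerate(self):
        pairs = _classified_pairs(n=100, seed=7, inflation_rate=0.0, price_noise_sd=0.0)
        table = summarize_prices(pairs, by="overall")
        row = table.iloc[0]
        assert row.degenerate
        assert row.mean_y1 == pytest.approx(row.mean_y2)
        assert row.median_y1 == pytest.approx(row.median_y2)

    def test_cell_means_match_recomputation(self):
        pairs = _classified_pairs(n=300, seed=8)
        table = summarize_prices(pairs, by="retailer").set_index("cell")
        for retailer in table.index:
            values = [p.price_per100_y1 for p in pairs
                      if p.record_y1.retailer_id == retailer
                      and p.price_per100_y1 is not None and p.price_per100_y2 is not None]
            assert table.loc[retailer, "n"] == len(values)
            assert table.loc[retailer, "mean_y1"] == pytest.approx(np.mean(values))

    def test_adjusted_p_at_least_raw(self):
        pairs = _classified_pairs(n=400, seed=9)
        table = summarize_prices(pairs, by="tra_category")
        assert (table.p_adj >= table.p_raw - 1e-15).all()

    def test_drifted_category_detected(self):
        pairs = _classified_pairs(n=1500, seed=10, inflation_rate=0.0, price_noise_sd=0.02)
        for p in pairs:  # +10 % drift in category A only
            if p.record_y1.tra_category == "A" and p.delta_price is not None:
                p.price_per100_y2 = p.price_per100_y1 * 1.10
        table = summarize_prices(pairs, by="tra_category").set_index("cell")
        assert table.loc["A", "p_adj"] < 0.05
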
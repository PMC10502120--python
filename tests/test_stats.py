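import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phaseflow import (
    GrowthParams,
    SLGEConfig,
    adf_stationarity,
    bh_adjust,
    clr_transform,
    compute_deltas,
    covariate_adjusted_regression,
    delta_abundance_stats,
    donor_mean_regression,
    fisher_combine,
    ptr_abundance_regression,
    simulate_slge,
)
from phaseflow.stats import TaxonSeries


def make_series(days, clr, log2ptr=None, taxon="t", donor="d"):
    clr = np.asarray(clr, dtype=float)
    if log2ptr is None:
        log2ptr = np.full_like(clr, np.nan)
    return TaxonSeries(taxon=taxon, donor=donor, days=np.asarray(days), clr=clr, log2ptr=log2ptr)


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        out = clr_transform(np.array([[5.0], [5.0], [5.0], [5.0]]), pseudocount=0.0)
        assert np.allclose(out, 0.0)

    def test_two_part_hand_computation(self):
        # ln2 - (ln2 + ln8)/2 = -ln2
        out = clr_transform(np.array([[2.0], [8.0]]), pseudocount=0.0)
        assert out[:, 0] == pytest.approx([-math.log(2), math.log(2)], abs=1e-12)

    @given(
        mat=arrays(
            float,
            (4, 3),
            elements=st.floats(0.1, 1e5, allow_nan=False),
        )
    )
    def test_columns_sum_to_zero(self, mat):
        out = clr_transform(mat, pseudocount=0.5)
        assert np.allclose(out.sum(axis=0), 0.0, atol=1e-10)

    def test_invariance_to_sample_scaling(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(1, 1000, size=(6, 4)).astype(float)
        assert np.allclose(
            clr_transform(mat, pseudocount=0.0),
            clr_transform(mat * 37.0, pseudocount=0.0),
            atol=1e-10,
        )

    def test_all_zero_sample_is_named(self):
        df = pd.DataFrame(
            {"s1": [1, 2], "bad_sample": [0, 0]}, index=["a", "b"]
        )
        with pytest.raises(ValueError, match="bad_sample"):
            clr_transform(df)

    def test_dataframe_round_trip_labels(self):
        df = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]}, index=["a", "b"])
        out = clr_transform(df)
        assert list(out.index) == ["a", "b"] and list(out.columns) == ["s1", "s2"]

    def test_zero_count_needs_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(np.array([[0.0], [5.0]]), pseudocount=0.0)


class TestDeltas:
    def test_consecutive_days(self):
        pairs = compute_deltas(make_series([1, 2, 3], [3, 5, 4]))
        assert pairs.tolist() == [[3.0, 2.0], [5.0, -1.0]]

    def test_wide_gap_is_dropped_not_interpolated(self):
        assert compute_deltas(make_series([1, 5], [0, 1])).size == 0

    def test_gap_of_two_days_is_retained(self):
        assert compute_deltas(make_series([1, 3], [0, 1])).tolist() == [[0.0, 1.0]]

    @given(st.integers(2, 30), st.integers(1))
    def test_never_more_pairs_than_consecutive_gaps(self, n, seed):
        rng = np.random.default_rng(seed)
        days = np.cumsum(rng.integers(1, 5, size=n))
        s = make_series(days, rng.normal(size=n))
        pairs = compute_deltas(s)
        assert len(pairs) == int(np.sum(np.diff(days) < 3)) <= n - 1


class TestDeltaAbundanceStats:
    def test_alternating_series_is_perfectly_negative(self):
        pairs = compute_deltas(make_series([1, 2, 3, 4, 5], [1, 2, 1, 2, 1]))
        res = delta_abundance_stats(pairs)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_iid_sampling_gives_minus_one_over_sqrt_two(self):
        # corr(x, x' - x) for iid x is -1/sqrt(2)
        rng = np.random.default_rng(7)
        x = rng.standard_normal(501)
        pairs = np.column_stack([x[:-1], np.diff(x)])
        res = delta_abundance_stats(pairs)
        assert res.pearson_r == pytest.approx(-1 / math.sqrt(2), abs=0.08)

    def test_stationary_slge_window_is_negative(self, params, boundaries):
        ens = simulate_slge(
            SLGEConfig(params=params, sigma=0.1, n_iter=1, seed=13)
        ).thin(100)
        rel = ens.times - ens.times[0]
        idx = np.nonzero(rel >= boundaries.s4)[0][:-1]
        x = ens.abundances[0, idx]
        pairs = np.column_stack([x, ens.abundances[0, idx + 1] - x])
        assert delta_abundance_stats(pairs).pearson_r < 0

    def test_degenerate_inputs_yield_none(self):
        assert delta_abundance_stats(np.empty((0, 2))) is None
        assert delta_abundance_stats([[1, 0.5], [1, -0.5]]) is None
        assert delta_abundance_stats([[1, 1], [1, 2], [1, 3]]) is None  # zero variance


class TestPtrRegression:
    def test_perfect_linear_association(self):
        v = np.arange(6, dtype=float)
        res = ptr_abundance_regression(make_series(np.arange(6), v, v))
        assert res.slope == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.p < 0.05
        assert res.n == 6

    def test_constant_ptr_is_degenerate(self):
        res = ptr_abundance_regression(
            make_series(np.arange(6), np.arange(6.0), np.full(6, 0.5))
        )
        assert res is None

    def test_five_points_is_ineligible(self):
        v = np.arange(5, dtype=float)
        assert ptr_abundance_regression(make_series(np.arange(5), v, v)) is None

    def test_missing_ptr_days_are_dropped(self):
        v = np.arange(8, dtype=float)
        ptr = v.copy()
        ptr[[0, 3]] = np.nan
        res = ptr_abundance_regression(make_series(np.arange(8), v, ptr))
        assert res.n == 6


class TestBhAdjust:
    @staticmethod
    def brute_force_bh(p):
        # step-up: p * m / rank, then cumulative min from the largest rank
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 51))
            assert np.allclose(bh_adjust(p), self.brute_force_bh(p), atol=1e-12)

    @given(arrays(float, st.integers(1, 30), elements=st.floats(0.0, 1.0)))
    def test_bounds_and_rank_monotonicity(self, p):
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestFisherCombine:
    def test_published_donor_pvalues_combine_to_0_005(self):
        assert round(fisher_combine([0.0318, 0.125, 0.155, 0.031]), 3) == 0.005

    def test_df4_closed_form(self):
        # for two inputs, p = e^{-X/2}(1 + X/2) with X = -2(ln p1 + ln p2)
        X = -2 * (math.log(0.5) + math.log(0.5))
        assert fisher_combine([0.5, 0.5]) == pytest.approx(
            math.exp(-X / 2) * (1 + X / 2), abs=1e-10
        )
        assert round(fisher_combine([0.5, 0.5]), 4) == 0.5966

    @given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
    def test_two_input_closed_form_property(self, p1, p2):
        X = -2 * (math.log(p1) + math.log(p2))
        assert fisher_combine([p1, p2]) == pytest.approx(
            math.exp(-X / 2) * (1 + X / 2), abs=1e-10
        )

    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


class TestAdfStationarity:
    def test_ar1_is_flagged_stationary(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.empty(300)
            x[0] = 0.0
            for i in range(1, 300):
                x[i] = 0.5 * x[i - 1] + rng.standard_normal()
            res = adf_stationarity(x)
            assert res.stationary == (res.p < 0.1)
            hits += res.stationary
        assert hits >= 95

    def test_random_walk_is_not_flagged(self):
        misses = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.cumsum(rng.standard_normal(300))
            misses += not adf_stationarity(x).stationary
        assert misses >= 90

    def test_degenerate_series_yield_none(self):
        assert adf_stationarity(np.arange(10.0)) is None
        assert adf_stationarity(np.full(50, 3.0)) is None
        x = np.random.default_rng(0).standard_normal(50)
        x[3] = np.nan
        assert adf_stationarity(x) is None


class TestDonorMeanRegression:
    @staticmethod
    def taxa_with_means(means_ptr, means_clr, n_days=10):
        days = np.arange(n_days)
        series = []
        rng = np.random.default_rng(1)
        for i, (mp, mc) in enumerate(zip(means_ptr, means_clr)):
            jitter = rng.normal(0, 0.01, n_days)
            jitter -= jitter.mean()
            series.append(
                make_series(days, mc + jitter, mp + jitter, taxon=f"t{i}")
            )
        return series

    def test_recovers_engineered_slope(self):
        mp = np.array([0.2, 0.5, 1.0, 1.5])
        series = self.taxa_with_means(mp, 2.0 * mp)
        res = donor_mean_regression(series)
        assert res.slope == pytest.approx(2.0, abs=1e-6)

    def test_shuffled_pairing_kills_the_association(self):
        rng = np.random.default_rng(5)
        mp = rng.normal(1.0, 0.3, 50)
        mc = rng.permutation(rng.normal(0.0, 1.0, 50))
        res = donor_mean_regression(self.taxa_with_means(mp, mc))
        assert abs(res.pearson_r) < 0.3
        assert res.p > 0.05

    def test_donor_pvalues_pipe_into_fisher(self):
        ps = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            mp = rng.normal(1.0, 0.3, 12)
            res = donor_mean_regression(self.taxa_with_means(mp, 0.5 * mp + rng.normal(0, 0.2, 12)))
            ps.append(res.p)
        combined = fisher_combine(ps)
        assert 0.0 < combined <= 1.0

    def test_too_few_taxa_yield_none(self):
        series = self.taxa_with_means([0.5, 1.0], [1.0, 2.0])
        assert donor_mean_regression(series) is None


class TestCovariateAdjustedRegression:
    @staticmethod
    def simpson_frame():
        # two groups, identical positive within-group slope, opposed group
        # means: the pooled naive slope is negative
        rng = np.random.default_rng(11)
        rows = []
        for group, (clr0, ptr0) in [("g1", (0.0, 2.0)), ("g2", (5.0, 0.0))]:
            clr = clr0 + rng.normal(0, 0.5, 60)
            ptr = ptr0 + 0.3 * (clr - clr0) + rng.normal(0, 0.05, 60)
            rows.append(pd.DataFrame({"clr": clr, "log2ptr": ptr, "group": group}))
        return pd.concat(rows, ignore_index=True)

    def test_adjustment_resolves_simpsons_paradox(self):
        df = self.simpson_frame()
        naive = np.polyfit(df.clr, df.log2ptr, 1)[0]
        beta, p = covariate_adjusted_regression(df)
        assert naive < 0 < beta
        assert beta == pytest.approx(0.3, abs=0.05)
        assert p < 1e-6

    def test_matches_normal_equations_oracle(self):
        df = self.simpson_frame()
        beta, _ = covariate_adjusted_regression(df)
        X = np.column_stack(
            [np.ones(len(df)), df.clr, (df.group == "g2").astype(float)]
        )
        coef, *_ = np.linalg.lstsq(X, df.log2ptr.to_numpy(), rcond=None)
        assert beta == pytest.approx(coef[1], abs=1e-8)

    def test_orthogonal_groups_match_simple_slope(self):
        rng = np.random.default_rng(3)
        clr = rng.normal(size=200)
        df = pd.DataFrame(
            {
                "clr": clr,
                "log2ptr": 0.7 * clr + rng.normal(0, 0.1, 200),
                "group": np.tile(["a", "b"], 100),  # balanced, independent of clr
            }
        )
        beta, _ = covariate_adjusted_regression(df)
        simple = np.polyfit(df.clr, df.log2ptr, 1)[0]
        assert beta == pytest.approx(simple, abs=0.02)

    def test_single_group_falls_back_with_warning(self):
        rng = np.random.default_rng(4)
        clr = rng.normal(size=30)
        df = pd.DataFrame({"clr": clr, "log2ptr": clr, "group": "only"})
        with pytest.warns(UserWarning, match="unadjusted"):
            beta, _ = covariate_adjusted_regression(df)
        assert beta == pytest.approx(1.0, abs=1e-8)


class TestTaxonSeries:
    def test_means_are_recomputed(self):
        s = make_series([0, 1, 2], [1.0, 2.0, 3.0], [0.5, np.nan, 1.5])
        assert s.mu == pytest.approx(2.0)
        assert s.mean_log2ptr == pytest.approx(1.0)

    def test_days_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            make_series([0, 2, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            TaxonSeries("t", "d", np.array([0, 1]), np.array([1.0]), np.array([1.0, 2.0]))
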
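"""Contingency statistics: tables, tests, odds ratios, pooling, meta-analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from immunesig import (
    ContingencyTable2x2,
    auto_test,
    chi_square,
    dichotomize_covariate,
    fisher_exact,
    make_table,
    mh_meta,
    odds_ratio,
    pool_tables,
    rates,
    univariate_screen,
)
from immunesig.reference import POOLED_NO_ANTIHER2, reference_model
from immunesig.simulate import SyntheticConfig, simulate_cohort
from immunesig.stats import percent


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = sps.hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p_k = sps.hypergeom.pmf(k, n, c1, r1)
        if p_k <= p_obs * (1 + 1e-10):
            total += p_k
    return min(total, 1.0)


class TestMakeTable:
    def test_tally(self):
        t = make_table(["Gp-R", "Gp-R", "Gp-NR"], [True, False, False])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 1)

    def test_unknown_outcomes_excluded(self, caplog):
        with caplog.at_level("INFO", logger="immunesig.stats"):
            t = make_table(["Gp-R", "Gp-NR", "Gp-R"], [True, pd.NA, False])
        assert t.n == 2
        assert "excluded 1" in caplog.text

    def test_totals_preserved(self):
        rng = np.random.default_rng(0)
        groups = np.where(rng.random(50) < 0.5, "Gp-R", "Gp-NR")
        outcomes = rng.random(50) < 0.3
        t = make_table(groups, outcomes)
        assert t.n == 50


class TestRates:
    def test_pooled_published_counts_render_40_and_12(self):
        r1, r2 = rates(ContingencyTable2x2(170, 254, 83, 596))
        assert percent(r1) == 40.0  # 40.09 rounded
        assert percent(r2) == 12.0

    def test_zero_numerator(self):
        r1, _ = rates(ContingencyTable2x2(0, 10, 5, 5))
        assert r1 == 0.0

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            rates(ContingencyTable2x2(0, 0, 5, 5))

    @pytest.mark.parametrize("fraction,decimals,expected", [
        (0.345, 0, 35.0),        # half-up at the boundary
        (13 / 112, 1, 11.6),
        (0.4009, 0, 40.0),
    ])
    def test_percent_rounds_half_up(self, fraction, decimals, expected):
        assert percent(fraction, decimals) == expected


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            cells = rng.integers(0, 11, size=4)
            if cells.sum() == 0:
                continue
            t = ContingencyTable2x2(*map(int, cells))
            assert t.n <= 40
            expected = fisher_enumeration_oracle(t.a, t.b, t.c, t.d)
            assert fisher_exact(t) == pytest.approx(expected, abs=1e-12)
            assert 0 < fisher_exact(t) <= 1


class TestChiSquare:
    def test_balanced_table_statistic_zero(self):
        stat, p = chi_square(ContingencyTable2x2(10, 10, 10, 10), continuity=False)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_uncorrected_statistic_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 40, size=4))
            t = ContingencyTable2x2(a, b, c, d)
            stat, _ = chi_square(t, continuity=False)
            n = t.n
            expected = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            assert stat == pytest.approx(expected, rel=1e-12)

    def test_continuity_correction_never_increases_statistic(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = ContingencyTable2x2(*(int(x) for x in rng.integers(1, 30, size=4)))
            assert chi_square(t, True)[0] <= chi_square(t, False)[0] + 1e-12

    def test_zero_margin_advises_fisher(self):
        with pytest.raises(ValueError, match="Fisher"):
            chi_square(ContingencyTable2x2(0, 0, 5, 5))


class TestAutoTest:
    def test_small_expected_cell_uses_fisher(self):
        _, name = auto_test(ContingencyTable2x2(1, 9, 2, 8))
        assert name == "fisher"

    def test_large_balanced_table_uses_chi_square(self):
        p, name = auto_test(ContingencyTable2x2(50, 50, 50, 50))
        assert name == "chi-square-yates"
        assert p == pytest.approx(1.0)

    def test_name_always_known(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            t = ContingencyTable2x2(*(int(x) for x in rng.integers(0, 25, size=4) + [1, 1, 1, 1]))
            _, name = auto_test(t)
            assert name in ("fisher", "chi-square-yates")


class TestOddsRatio:
    def test_published_pooled_counts_give_4_81(self):
        or_, _ = odds_ratio(POOLED_NO_ANTIHER2)
        assert or_ == pytest.approx(4.81, abs=0.005)

    def test_unit_table_ci_spans_one(self):
        or_, (lo, hi) = odds_ratio(ContingencyTable2x2(1, 1, 1, 1), haldane=False)
        assert or_ == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_row_swap_inverts(self):
        t = ContingencyTable2x2(20, 10, 5, 30)
        assert odds_ratio(t)[0] * odds_ratio(t.swap_rows())[0] == pytest.approx(1.0)

    def test_haldane_handles_zero_cell(self):
        t = ContingencyTable2x2(5, 5, 0, 10)
        or_, (lo, hi) = odds_ratio(t, haldane=True)
        assert math.isfinite(or_) and math.isfinite(hi)
        with pytest.raises(ValueError, match="zero cell"):
            odds_ratio(t, haldane=False)


class TestPooling:
    def test_identity_and_doubling(self):
        t = ContingencyTable2x2(3, 4, 5, 6, dataset="x")
        assert pool_tables([t]).to_array().tolist() == t.to_array().tolist()
        doubled = pool_tables([t, t])
        assert (doubled.a, doubled.b, doubled.c, doubled.d) == (6, 8, 10, 12)

    def test_associative_and_commutative(self):
        rng = np.random.default_rng(2)
        tables = [
            ContingencyTable2x2(*(int(x) for x in rng.integers(0, 20, 4) + 1))
            for _ in range(4)
        ]
        left = pool_tables([pool_tables(tables[:2]), pool_tables(tables[2:])])
        right = pool_tables(tables[::-1])
        assert left.to_array().tolist() == right.to_array().tolist()

    def test_per_dataset_tables_reproduce_pooled_published_rates(self):
        # split the published pooled counts into synthetic per-dataset tables
        parts = [
            ContingencyTable2x2(100, 154, 43, 296, dataset="d1"),
            ContingencyTable2x2(50, 80, 30, 200, dataset="d2"),
            ContingencyTable2x2(20, 20, 10, 100, dataset="d3"),
        ]
        pooled = pool_tables(parts)
        assert (pooled.a, pooled.b, pooled.c, pooled.d) == (170, 254, 83, 596)
        r1, r2 = rates(pooled)
        assert percent(r1) == 40.0
        assert percent(r2) == 12.0


class TestMeta:
    def test_identical_tables_pool_to_single_table_or(self):
        t = ContingencyTable2x2(30, 20, 10, 40)
        single = odds_ratio(t, haldane=False)[0]
        meta = mh_meta([t] * 4)
        assert meta.pooled_or == pytest.approx(single, rel=1e-9)

    def test_single_table_is_cross_product(self):
        t = ContingencyTable2x2(30, 20, 10, 40)
        meta = mh_meta([t])
        assert meta.pooled_or == pytest.approx(6.0, rel=1e-6)

    def test_pooled_or_between_study_extremes(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            tables = [
                ContingencyTable2x2(*(int(x) for x in rng.integers(1, 40, 4)))
                for _ in range(5)
            ]
            meta = mh_meta(tables)
            ors = [odds_ratio(t, haldane=False)[0] for t in tables]
            assert min(ors) - 1e-9 <= meta.pooled_or <= max(ors) + 1e-9

    def test_random_effects_available(self):
        tables = [
            ContingencyTable2x2(30, 20, 10, 40, dataset="a"),
            ContingencyTable2x2(25, 25, 15, 35, dataset="b"),
            ContingencyTable2x2(40, 15, 12, 38, dataset="c"),
        ]
        meta = mh_meta(tables, method="dl")
        assert meta.method == "dersimonian-laird"
        assert meta.pooled_ci[0] < meta.pooled_or < meta.pooled_ci[1]


class TestDichotomize:
    @pytest.mark.parametrize("value,cutoff,direction,expected", [
        (25.0, 20.0, ">", True),    # TILs 25 at >20 -> high
        (42.0, 42.0, ">=", True),   # HRD 42 at >=42 -> positive
        (19.9, 20.0, ">=", False),  # Ki67 19.9 at >=20 -> negative
        (20.0, 20.0, ">", False),
    ])
    def test_cutoff_directions(self, value, cutoff, direction, expected):
        out = dichotomize_covariate(pd.Series([value]), cutoff, direction)
        assert bool(out.iloc[0]) is expected

    def test_missing_preserved_and_all_missing_rejected(self):
        out = dichotomize_covariate(pd.Series([25.0, None]), 20.0, ">")
        assert out.isna().tolist() == [False, True]
        with pytest.raises(ValueError, match="missing"):
            dichotomize_covariate(pd.Series([None, None]), 20.0, ">")


@pytest.fixture(scope="module")
def screened():
    config = SyntheticConfig(n_samples=800, n_datasets=1, seed=77)
    matrix, clinical, _ = simulate_cohort(config)
    scores = reference_model().score(matrix)
    return univariate_screen(clinical, scores)


class TestUnivariateScreen:
    def test_signature_group_ranks_first_by_or(self, screened):
        assert screened.loc[0, "factor"] == "IRSN Gp-R"

    def test_rows_cover_evaluable_factors_only(self, screened):
        assert len(screened) >= 5
        assert screened["or"].is_monotonic_decreasing
        assert set(screened["test"]).issubset({"fisher", "chi-square-yates"})

    def test_single_level_factor_skipped(self, caplog):
        config = SyntheticConfig(n_samples=300, n_datasets=1, seed=78)
        matrix, clinical, _ = simulate_cohort(config)
        clinical.data["er"] = "positive"  # one level only
        scores = reference_model().score(matrix)
        with caplog.at_level("INFO", logger="immunesig.stats"):
            out = univariate_screen(clinical, scores)
        assert "ER-negative" not in set(out["factor"])
        assert "skipped" in caplog.text
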
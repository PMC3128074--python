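import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ontosex import diffexpr
from ontosex.core_io import FEMALE, MALE, UNBIASED, UNDETERMINED, BiasProfile
from ontosex.synthetic_data import ExpressionSimSpec, gen_expression
from tests.conftest import make_matrix

NAN = float("nan")


class TestLowess:
    def test_zero_log_ratios_stay_zero(self):
        rng = np.random.default_rng(0)
        female = rng.uniform(100, 10000, 200)
        out = diffexpr.lowess_normalize(female, female)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_constant_offset_absorbed(self):
        # oracle: a constant M = c is exactly the fitted constant
        rng = np.random.default_rng(1)
        female = rng.uniform(100, 10000, 200)
        male = female * 2.0  # M = 1 everywhere
        out = diffexpr.lowess_normalize(male, female)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_intensity_trend_is_reduced(self):
        # simulation oracle: linear dye trend in A plus noise shrinks
        rng = np.random.default_rng(2)
        a = rng.uniform(5, 15, 1000)
        m = 0.3 * (a - 10) + rng.normal(0, 0.05, 1000)
        female = 2 ** (a - m / 2)
        male = 2 ** (a + m / 2)
        out = diffexpr.lowess_normalize(male, female)
        assert np.mean(np.abs(out)) < np.mean(np.abs(m))

    def test_nonpositive_intensity_flagged_missing(self):
        out = diffexpr.lowess_normalize(
            np.array([-1.0] + [100.0] * 20), np.array([50.0] + [100.0] * 20)
        )
        assert math.isnan(out[0]) and not np.isnan(out[1:]).any()


class TestReplicateFilter:
    def test_two_of_three_everywhere_is_kept(self):
        row = ([0.1, 0.1, NAN]) * 5  # 10/15 = 66.7% >= 66%
        m = make_matrix({"g": row})
        assert diffexpr.filter_replicates(m) == {"g"}

    def test_one_of_three_everywhere_is_dropped(self):
        m = make_matrix({"g": [0.1, NAN, NAN] * 5})
        assert diffexpr.filter_replicates(m) == set()

    def test_fully_observed_kept(self, small_matrix):
        assert diffexpr.filter_replicates(small_matrix) == {"g1", "g2", "g3"}


class TestCrossGeneAnova:
    def test_single_signal_gene_among_nulls(self):
        rng = np.random.default_rng(3)
        rows = {f"n{i}": list(rng.normal(0, 0.1, 15)) for i in range(50)}
        rows["sig"] = list(np.repeat([3.0] * 5, 3) + rng.normal(0, 0.1, 15))
        p = diffexpr.cross_gene_anova(make_matrix(rows))
        assert p["sig"] < 0.001
        assert np.median([p[f"n{i}"] for i in range(50)]) > 0.2

    def test_identical_zero_replicates_give_p_one(self):
        p = diffexpr.cross_gene_anova(make_matrix({"g": [0.0] * 15}))
        assert p["g"] == 1.0

    def test_under_two_values_gives_missing_p(self):
        p = diffexpr.cross_gene_anova(make_matrix({"g": [0.5] + [NAN] * 14,
                                                   "h": [0.1, 0.2, 0.1] * 5}))
        assert math.isnan(p["g"])


class TestRecovery:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((0.7, 0.7, 0.7), True),       # mean 0.7 > 0.6, all same sign
            ((0.6, 0.6, 0.6), False),      # mean exactly 0.6: strict inequality
            ((1.2, -0.1, 1.6), True),      # mean 0.9, 2/3 = 66.7% positive
            ((1.9, -0.1, -0.1), False),    # mean 0.57 below threshold
            ((2.4, -0.2, -0.1), False),    # mean 0.7 but only 1/3 positive
        ],
    )
    def test_two_clause_rule(self, values, expected):
        row = list(values) + [NAN] * 12
        m = make_matrix({"g": row})
        recovered = diffexpr.recover_marginal(m, {"g"})
        assert (("g" in recovered) is expected)


class TestClassifyStageBias:
    @pytest.mark.parametrize(
        "ratio,call",
        [
            (0.9, MALE),
            (0.8, UNBIASED),   # strict inequality at the threshold
            (-0.81, FEMALE),
            (-0.8, UNBIASED),
            (0.0, UNBIASED),
            (NAN, UNDETERMINED),
        ],
    )
    def test_threshold_rules(self, ratio, call):
        assert diffexpr.classify_stage_bias(ratio) == call

    @given(st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_in_ratio(self, r):
        swap = {MALE: FEMALE, FEMALE: MALE, UNBIASED: UNBIASED}
        assert diffexpr.classify_stage_bias(-r) == swap[diffexpr.classify_stage_bias(r)]


class TestBiasProfiles:
    def test_stage_mean_and_call(self):
        row = [NAN] * 12 + [1.0, 1.2, 0.8]  # adult replicates
        m = make_matrix({"g": row})
        (p,) = diffexpr.build_bias_profiles(m, {"g"})
        assert p.mean_ratio["A"] == pytest.approx(1.0)
        assert p.call["A"] == MALE

    def test_all_missing_stage_is_undetermined(self):
        row = [0.1] * 9 + [NAN] * 3 + [0.1] * 3
        m = make_matrix({"g": row})
        (p,) = diffexpr.build_bias_profiles(m, {"g"})
        assert p.call["P"] == UNDETERMINED
        assert math.isnan(p.mean_ratio["P"])

    def test_non_admitted_genes_excluded(self, small_matrix):
        profiles = diffexpr.build_bias_profiles(small_matrix, {"g2"})
        assert [p.gene for p in profiles] == ["g2"]


class TestStageSummary:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(1884, 6142, 30.7), (1309, 1752, 74.7), (0, 100, 0.0), (1, 3, 33.3)],
    )
    def test_percentage_one_decimal_half_away_from_zero(self, k, n, expected):
        assert diffexpr.percentage(k, n) == expected

    def test_percentage_undefined_for_zero_n(self):
        with pytest.raises(ZeroDivisionError):
            diffexpr.percentage(1, 0)

    def test_tier2_counts_never_exceed_tier1(self):
        matrix, _ = gen_expression(ExpressionSimSpec(n_genes=400, seed=9))
        profiles = diffexpr.build_bias_profiles(matrix, set(matrix.genes))
        summary = diffexpr.stage_summary(profiles)
        for stage, grp in summary.groupby("stage"):
            t1 = grp[grp["tier"] == 0.8].iloc[0]
            t2 = grp[grp["tier"] == 1.6].iloc[0]
            assert t2["n_male_biased"] <= t1["n_male_biased"]
            assert t2["n_female_biased"] <= t1["n_female_biased"]
            assert t1["n_male_biased"] + t1["n_female_biased"] <= t1["n_total_admitted"]

    def test_raising_threshold_never_increases_biased_counts(self):
        matrix, _ = gen_expression(ExpressionSimSpec(n_genes=300, seed=10))
        profiles_08 = diffexpr.build_bias_profiles(matrix, set(matrix.genes), 0.8)
        profiles_12 = diffexpr.build_bias_profiles(matrix, set(matrix.genes), 1.2)
        n08 = sum(p.is_biased for p in profiles_08)
        n12 = sum(p.is_biased for p in profiles_12)
        assert n12 <= n08


def _profile(gene, calls):
    return BiasProfile(
        gene,
        {s: (1.0 if c == MALE else -1.0 if c == FEMALE else 0.0) for s, c in calls.items()},
        calls,
    )


class TestMaintainedBias:
    def test_larvae_and_adult_only(self):
        p = _profile("g", {"L1": MALE, "L2-3": UNBIASED, "L4": UNBIASED,
                           "P": UNBIASED, "A": MALE})
        part = diffexpr.maintained_bias([p])
        assert part == {frozenset({"larvae", "adult"}): {"g"}}

    def test_all_five_stages_is_all_three_pools(self):
        p = _profile("g", {s: FEMALE for s in ("L1", "L2-3", "L4", "P", "A")})
        part = diffexpr.maintained_bias([p])
        assert set(part) == {frozenset({"larvae", "pupae", "adult"})}

    def test_classes_partition_the_biased_set(self):
        matrix, _ = gen_expression(ExpressionSimSpec(n_genes=500, seed=11))
        profiles = diffexpr.build_bias_profiles(matrix, set(matrix.genes))
        part = diffexpr.maintained_bias(profiles)
        union = set().union(*part.values()) if part else set()
        assert union == {p.gene for p in profiles if p.is_biased}
        assert sum(len(v) for v in part.values()) == len(union)


class TestVarianceProfile:
    def test_constant_profile_has_zero_sd(self):
        p = _profile("g", {s: MALE for s in ("L1", "L2-3", "L4", "P", "A")})
        df = diffexpr.variance_profile([p])
        assert df.loc[0, "mean_ratio"] == 1.0 and df.loc[0, "sd_ratio"] == 0.0

    def test_hand_arithmetic_sample_sd(self):
        p = BiasProfile("g", dict(zip(("L1", "L2-3", "L4", "P", "A"),
                                      [0.0, 0.0, 0.0, 0.0, 2.0])), {})
        df = diffexpr.variance_profile([p])
        assert df.loc[0, "mean_ratio"] == pytest.approx(0.4)
        assert df.loc[0, "sd_ratio"] == pytest.approx(math.sqrt(0.8))

    def test_single_stage_sd_missing(self):
        p = BiasProfile("g", {"A": 1.0, "L1": NAN, "L2-3": NAN, "L4": NAN, "P": NAN}, {})
        df = diffexpr.variance_profile([p])
        assert math.isnan(df.loc[0, "sd_ratio"])


class TestSpearmanValidation:
    def test_monotone_and_reversed(self):
        a = np.arange(10.0)
        rho, _ = diffexpr.spearman_validation(a, a**3)
        assert rho == pytest.approx(1.0)
        rho, _ = diffexpr.spearman_validation(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_explicit_rank_oracle(self):
        a = np.array([1.0, 2.0, 2.0, 3.0])
        b = np.array([1.0, 3.0, 2.0, 4.0])
        # oracle: Pearson correlation of average ranks
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        rho, _ = diffexpr.spearman_validation(a, b)
        assert rho == pytest.approx(expected)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.spearman_validation(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def test_lowering_alpha_never_admits_more_genes():
    matrix, _ = gen_expression(ExpressionSimSpec(n_genes=300, seed=12))
    admitted = {}
    for alpha in (0.05, 0.01):
        res = diffexpr.screen_genes(matrix, alpha=alpha)
        admitted[alpha] = {r.gene for r in res if r.admitted}
    assert admitted[0.01] <= admitted[0.05]


def test_screen_result_invariants():
    matrix, _ = gen_expression(ExpressionSimSpec(n_genes=200, seed=13))
    for r in diffexpr.screen_genes(matrix):
        significant = r.passed_replicate_rule and (
            not math.isnan(r.anova_p) and r.anova_p <= 0.05
        )
        assert r.admitted == (significant or r.recovered)
        if r.recovered:
            assert not significant
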
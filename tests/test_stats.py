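"""Nonparametric comparisons, chi-square tables and feasibility accounting."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cpts.datasets import cpts_availability_tables
from cpts.errors import DegenerateTableError, InputError
from cpts.stats import (FeasibilityRecord, compare_groups, effect_size_label,
                        feasibility_tally, mann_whitney_exact_p,
                        mann_whitney_with_effect, median_iqr,
                        pearson_chi_square, two_sample_t)


def brute_force_mw_p(a, b):
    """Independent enumeration oracle over all group assignments."""
    pooled = sorted(a) + sorted(b)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    na = len(a)
    mu = na * len(b) / 2
    obs = sum(ranks[v] for v in a) - na * (na + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(pooled, na):
        u = sum(ranks[v] for v in combo) - na * (na + 1) / 2
        hits += abs(u - mu) >= abs(obs - mu) - 1e-12
        total += 1
    return hits / total


class TestMannWhitney:
    def test_identical_groups_zero_effect(self):
        res = mann_whitney_with_effect([1, 2, 3], [1, 2, 3])
        assert res.z == 0.0 and res.r == 0.0 and res.p == 1.0

    def test_separated_groups_match_enumeration(self):
        res = mann_whitney_with_effect([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert brute_force_mw_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert mann_whitney_exact_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_group_swap_invariance(self):
        a, b = [1.0, 5.0, 2.0, 8.0], [3.0, 9.0, 4.0]
        r1 = mann_whitney_with_effect(a, b)
        r2 = mann_whitney_with_effect(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert r1.r == pytest.approx(r2.r)

    def test_r_is_abs_z_over_sqrt_n(self):
        res = mann_whitney_with_effect([1, 2, 7, 9], [3, 4, 5])
        assert res.r == pytest.approx(abs(res.z) / math.sqrt(7))

    def test_uncorrected_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(size=7) + 0.5
        res = mann_whitney_with_effect(a, b, continuity=False)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_matches_scipy_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(2, 7)))
            b = rng.normal(size=int(rng.integers(2, 7)))
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue
            assert mann_whitney_exact_p(a, b) == pytest.approx(ref, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_with_effect([], [1.0])


class TestEffectSizeLabel:
    @pytest.mark.parametrize("r,label", [
        (0.51, "large"),       # published: "largely higher PTIs"
        (0.44, "moderate"),    # published: "moderately lower in footwear"
        (0.26, "small"),       # published: "slightly higher adherence"
        (0.0, "none"), (0.09999, "none"), (0.1, "small"),
        (0.3, "moderate"), (0.5, "large"), (3.0, "large"),
    ])
    def test_bands(self, r, label):
        assert effect_size_label(r) == label

    @given(r=st.floats(min_value=0.0, max_value=10.0, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_bands_partition_nonnegative_reals(self, r):
        assert effect_size_label(r) in {"none", "small", "moderate", "large"}

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            effect_size_label(-0.1)


class TestPearsonChiSquare:
    def test_sex_table_hand_oracle(self):
        """[[2,2],[3,6]]: chi2 = sum (O-E)^2/E = 0.3256..., p = 0.569."""
        chi2, df, p = pearson_chi_square([[2, 2], [3, 6]])
        # hand evaluation: E = [[20,32],[45,72]]/13
        e = np.outer([4, 9], [5, 8]) / 13
        hand = (((np.array([[2, 2], [3, 6]]) - e) ** 2) / e).sum()
        assert chi2 == pytest.approx(hand)
        assert chi2 == pytest.approx(0.325, abs=5e-4)
        assert p == pytest.approx(0.569, abs=5e-4)

    def test_independent_table(self):
        chi2, df, p = pearson_chi_square([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_three_by_two_df_and_p(self):
        chi2, df, p = pearson_chi_square([[1, 1], [0, 3], [4, 4]])
        assert df == 2
        assert p == pytest.approx(0.296, abs=5e-4)

    def test_all_zero_row_dropped(self):
        with_zero = pearson_chi_square([[1, 1], [0, 0], [0, 3], [4, 4]])
        without = pearson_chi_square([[1, 1], [0, 3], [4, 4]])
        assert with_zero == without

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi_square([[5, 3], [0, 0]])

    def test_non_integer_rejected(self):
        with pytest.raises(InputError):
            pearson_chi_square([[1.5, 2], [3, 4]])


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_separation(self):
        t, p = two_sample_t([0.0, 0.001], [1.0, 0.999])
        assert abs(t) > 100 and p < 1e-4

    def test_textbook_formula_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (2 / 3))
        t, p = two_sample_t(a, b)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), 4))


class TestMedianIqr:
    def test_odd_n_median(self):
        assert median_iqr([1, 2, 3, 4, 5])[0] == 3.0

    def test_single_value(self):
        assert median_iqr([7.0]) == (7.0, 7.0, 7.0)

    def test_haverage_convention(self):
        """(n+1)-weighted quartiles of {1,2,3,4}: p25 = 1.25, p75 = 3.75."""
        med, p25, p75 = median_iqr([1, 2, 3, 4])
        assert (p25, p75) == (1.25, 3.75)


class TestFeasibilityTally:
    def test_published_baseline_percentages(self):
        """AU baseline: 5 complete, 4 technical, 2 non-adherent, 2 combined
        of 13 enrolled -> 38%, 31%, 15%, 15%."""
        records = (
            [FeasibilityRecord(f"P{i}", "baseline", "complete") for i in range(5)]
            + [FeasibilityRecord(f"T{i}", "baseline", "technical") for i in range(4)]
            + [FeasibilityRecord(f"N{i}", "baseline", "non_adherent") for i in range(2)]
            + [FeasibilityRecord(f"C{i}", "baseline", "combination") for i in range(2)]
        )
        tally = feasibility_tally(records).set_index("status")
        pct = tally["percent"].round().astype(int)
        assert pct["complete"] == 38
        assert pct["technical"] == 31
        assert pct["non_adherent"] == 15
        assert pct["combination"] == 15
        assert tally["count"].sum() == 13

    def test_all_complete(self):
        records = [FeasibilityRecord(f"P{i}", "week4", "complete")
                   for i in range(6)]
        tally = feasibility_tally(records).set_index("status")
        assert tally.loc["complete", "percent"] == 100.0
        assert tally.drop("complete")["count"].sum() == 0

    def test_counts_conserved_per_stage(self):
        rng = np.random.default_rng(1)
        statuses = ["complete", "technical", "refusal", "dropout",
                    "non_adherent", "combination"]
        records = [FeasibilityRecord(f"P{i}", stage,
                                     statuses[rng.integers(len(statuses))])
                   for i in range(9) for stage in ("baseline", "week8")]
        tally = feasibility_tally(records)
        for stage, grp in tally.groupby("stage"):
            assert grp["count"].sum() == 9
            assert grp["percent"].sum() == pytest.approx(100.0)

    def test_unknown_status_rejected(self):
        with pytest.raises(InputError):
            FeasibilityRecord("P1", "baseline", "lost_socks")


class TestCompareGroups:
    def test_nan_handling_and_row(self):
        cmp = compare_groups("pti", [1.0, 2.0, np.nan], [3.0, 4.0, 5.0])
        assert cmp.n_a == 2 and cmp.n_b == 3
        row = cmp.as_row()
        assert row["variable"] == "pti" and row["r"] is not None

    def test_published_contingency_tables_available(self):
        tables = cpts_availability_tables()
        assert set(tables) >= {"sex", "offloading_device", "ulcer_site"}
        sex = tables["sex"]
        assert sex["available"].sum() == 5
        assert sex["not_available"].sum() == 8
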
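"""Potency/efficacy shifts and the exact Wilcoxon rank-sum test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu, rankdata

from gpcrstates.fixture_factory import make_mutant_table
from gpcrstates.mutation_stats import (
    MutantRecord, compare_groups, delta_from_wt, load_mutant_table,
    wilcoxon_rank_sum_exact,
)
from gpcrstates.fixture_factory import write_mutant_table


def brute_force_two_sided(a, b):
    """Independent enumeration over all group assignments of the pooled
    mid-ranks; doubles the smaller tail and caps at 1."""
    pooled = list(a) + list(b)
    ranks = rankdata(pooled)
    n, N = len(a), len(pooled)
    w_obs = ranks[:n].sum()
    le = ge = total = 0
    for comb in itertools.combinations(range(N), n):
        w = ranks[list(comb)].sum()
        total += 1
        le += w <= w_obs + 1e-9
        ge += w >= w_obs - 1e-9
    return min(1.0, 2.0 * min(le, ge) / total)


def rec(mutant, group, gprot, log_ec50, emax=100.0, replicate=1):
    return MutantRecord(mutant=mutant, group=group, g_protein=gprot,
                        log_ec50=log_ec50, emax=emax, replicate=replicate)


class TestDeltaFromWT:
    def test_mutant_equal_to_wt_gives_zero(self):
        records = [rec("WT", "wt", "Gs", -7.0),
                   rec("M1", "state_changing", "Gs", -7.0)]
        d = delta_from_wt(records)
        assert d["delta_log_ec50"].iloc[0] == pytest.approx(0.0)

    def test_simple_shift_arithmetic(self):
        records = [rec("WT", "wt", "Gs", -7.0),
                   rec("M1", "state_changing", "Gs", -5.5)]
        d = delta_from_wt(records)
        assert d["delta_log_ec50"].iloc[0] == pytest.approx(1.5)

    def test_replicates_averaged_before_differencing(self):
        records = [rec("WT", "wt", "Gs", -7.1, replicate=1),
                   rec("WT", "wt", "Gs", -6.9, replicate=2),
                   rec("M1", "state_changing", "Gs", -6.2, replicate=1),
                   rec("M1", "state_changing", "Gs", -5.8, replicate=2)]
        d = delta_from_wt(records)
        assert len(d) == 1
        assert d["delta_log_ec50"].iloc[0] == pytest.approx(1.0)

    def test_per_gprotein_wild_type(self):
        records = [rec("WT", "wt", "Gs", -7.0), rec("WT", "wt", "G15", -6.0),
                   rec("M1", "state_changing", "Gs", -6.0),
                   rec("M1", "state_changing", "G15", -5.0)]
        d = delta_from_wt(records).set_index("g_protein")
        assert d.loc["Gs", "delta_log_ec50"] == pytest.approx(1.0)
        assert d.loc["G15", "delta_log_ec50"] == pytest.approx(1.0)

    def test_missing_wt_rejected(self):
        with pytest.raises(ValueError, match="wild-type"):
            delta_from_wt([rec("M1", "state_changing", "Gs", -6.0)])


class TestWilcoxonExact:
    def test_identical_groups_give_p_one(self):
        assert wilcoxon_rank_sum_exact([1, 2, 3], [1, 2, 3]) == 1.0
        assert wilcoxon_rank_sum_exact([5, 5, 5], [5, 5, 5]) == 1.0

    def test_fully_separated_three_vs_three(self):
        """{1,2,3} vs {4,5,6}: 2 of C(6,3)=20 assignments are as extreme,
        so the two-sided p is 0.1."""
        assert wilcoxon_rank_sum_exact([1, 2, 3], [4, 5, 6]) == \
            pytest.approx(0.1)

    @pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (4, 4), (5, 6),
                                       (6, 6), (8, 8)])
    def test_matches_brute_force_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for trial in range(8):
            # integer draws produce ties regularly
            a = rng.integers(0, 6, na).astype(float)
            b = rng.integers(0, 6, nb).astype(float)
            if len(set(a.tolist() + b.tolist())) == 1:
                continue
            assert wilcoxon_rank_sum_exact(a, b) == pytest.approx(
                brute_force_two_sided(a, b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for trial in range(6):
            a = rng.permutation(20)[:6].astype(float)
            b = rng.permutation(40)[20:28].astype(float) + 0.5
            expected = mannwhitneyu(a, b, method="exact",
                                    alternative="two-sided").pvalue
            assert wilcoxon_rank_sum_exact(a, b) == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        a = [0.1, 0.7, 1.3, 2.0]
        b = [0.4, 1.8, 2.5, 3.9]
        p0 = wilcoxon_rank_sum_exact(a, b)
        assert wilcoxon_rank_sum_exact(np.exp(a), np.exp(b)) == p0
        assert wilcoxon_rank_sum_exact(np.log(np.add(a, 1)),
                                       np.log(np.add(b, 1))) == p0

    def test_group_swap_invariance(self):
        a = [0.2, 0.5, 0.9, 2.2, 2.4]
        b = [1.0, 1.1, 3.0, 3.3, 4.8]
        assert wilcoxon_rank_sum_exact(a, b) == wilcoxon_rank_sum_exact(b, a)

    def test_one_sided_alternatives_sum_consistently(self):
        a, b = [1.0, 2.0, 3.0], [2.5, 4.0, 5.0]
        less = wilcoxon_rank_sum_exact(a, b, alternative="less")
        greater = wilcoxon_rank_sum_exact(a, b, alternative="greater")
        # tails overlap on the observed value only
        assert less + greater >= 1.0
        assert wilcoxon_rank_sum_exact(a, b) == pytest.approx(
            min(1.0, 2 * min(less, greater)))

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 25)
        b = rng.normal(1.0, 1.0, 25)
        p = wilcoxon_rank_sum_exact(a, b)
        expected = mannwhitneyu(a, b, method="asymptotic",
                                alternative="two-sided").pvalue
        assert p == pytest.approx(expected, rel=1e-6)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum_exact([1.0], [2.0, 3.0])

    @given(a=st.lists(st.integers(0, 8), min_size=2, max_size=7),
           b=st.lists(st.integers(0, 8), min_size=2, max_size=7))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rank_test_properties_hold_for_arbitrary_groups(self, a, b):
        """p is a valid probability, symmetric under group swap, and
        rank-based (invariant to a positive affine rescaling)."""
        p = wilcoxon_rank_sum_exact(a, b)
        assert 0.0 < p <= 1.0
        assert wilcoxon_rank_sum_exact(b, a) == pytest.approx(p)
        a2 = [3.0 * x - 7.0 for x in a]
        b2 = [3.0 * x - 7.0 for x in b]
        assert wilcoxon_rank_sum_exact(a2, b2) == pytest.approx(p)


class TestGroupComparison:
    def test_emulated_table_reproduces_published_statistics(self):
        """The synthetic mutant table reproduces the published group mean
        potency shifts exactly and the exact-test p-values at the nearest
        points of the discrete n=6,6 support."""
        comparisons = compare_groups(make_mutant_table(seed=0))
        gs, g15 = comparisons["Gs"], comparisons["G15"]
        assert gs.mean_delta_log_ec50["state_changing"] == \
            pytest.approx(1.07, abs=1e-9)
        assert gs.mean_delta_log_ec50["nonstate_changing"] == \
            pytest.approx(0.22, abs=1e-9)
        assert g15.mean_delta_log_ec50["state_changing"] == \
            pytest.approx(1.25, abs=1e-9)
        assert g15.mean_delta_log_ec50["nonstate_changing"] == \
            pytest.approx(0.25, abs=1e-9)
        assert gs.p_potency == pytest.approx(18 / 924)
        assert g15.p_potency == pytest.approx(4 / 924)
        assert gs.p_efficacy == pytest.approx(646 / 924)
        assert g15.p_efficacy == pytest.approx(286 / 924)

    def test_table_round_trip(self, tmp_path):
        records = make_mutant_table(seed=3)
        path = tmp_path / "mutants.tsv"
        write_mutant_table(path, records)
        loaded = load_mutant_table(path)
        assert len(loaded) == len(records)
        a = compare_groups(records)
        b = compare_groups(loaded)
        assert a["Gs"].p_potency == pytest.approx(b["Gs"].p_potency)

    def test_seed_only_permutes_rows(self):
        a = compare_groups(make_mutant_table(seed=0))
        b = compare_groups(make_mutant_table(seed=99))
        assert a["Gs"].p_potency == b["Gs"].p_potency
        assert a["G15"].mean_delta_log_ec50 == b["G15"].mean_delta_log_ec50
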
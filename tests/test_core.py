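import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from enrichbench.core import (
    BackgroundError,
    BackgroundSpec,
    bh_adjust,
    detection_filter,
    fcs_rank_test,
    ora_test,
    significant_sets,
)
from enrichbench.io import GeneSetLibrary

from conftest import make_de_table


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by exact integer enumeration of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
    )
    return float(Fraction(acc, total))


class TestDetectionFilter:
    def test_boundary_mean_is_kept(self):
        counts = pd.DataFrame(
            {"s1": [9, 10, 11], "s2": [10, 10, 13]},
            index=["GA", "GB", "GC"],
        )  # means 9.5, 10.0, 12.0
        assert detection_filter(counts, 10) == {"GB", "GC"}

    def test_all_zero_matrix_detects_nothing(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [0, 0]}, index=["G1", "G2"])
        assert detection_filter(counts, 10) == frozenset()

    def test_zero_threshold_keeps_everything(self):
        counts = pd.DataFrame({"s1": [0, 3]}, index=["G1", "G2"])
        assert detection_filter(counts, 0) == {"G1", "G2"}


def library_of(**sets):
    return GeneSetLibrary(sets={k: frozenset(v) for k, v in sets.items()})


class TestOraTest:
    def test_enumerated_tail_example(self):
        """N=20, K=5, n=5, k=3 gives the enumerated tail 1126/15504."""
        background = BackgroundSpec("custom", frozenset(f"G{i}" for i in range(20)))
        lib = library_of(S=[f"G{i}" for i in range(5)])
        query = frozenset(["G0", "G1", "G2", "G10", "G11"])
        res = ora_test(query, background, lib, min_set_size=1)
        assert res.loc[0, "k"] == 3
        assert res.loc[0, "p"] == pytest.approx(1126 / 15504, rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        background = BackgroundSpec("custom", frozenset(f"G{i}" for i in range(20)))
        lib = library_of(S=[f"G{i}" for i in range(5)])
        res = ora_test(frozenset(["G10", "G11"]), background, lib, min_set_size=1)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_query_equal_background_is_certain(self):
        genes = frozenset(f"G{i}" for i in range(10))
        background = BackgroundSpec("custom", genes)
        lib = library_of(S=[f"G{i}" for i in range(4)])
        res = ora_test(genes, background, lib, min_set_size=1)
        assert res.loc[0, "k"] == res.loc[0, "K"]
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_fisher_exact(self):
        """Upper-tail hypergeometric equals one-sided Fisher on the 2x2 table."""
        rng = np.random.default_rng(0)
        background = BackgroundSpec("custom", frozenset(f"G{i}" for i in range(25)))
        for _ in range(50):
            K = rng.integers(1, 25)
            n = rng.integers(1, 25)
            lib = library_of(S=[f"G{i}" for i in range(K)])
            query = frozenset(f"G{i}" for i in rng.choice(25, size=n, replace=False))
            res = ora_test(query, background, lib, min_set_size=1)
            k = int(res.loc[0, "k"])
            table = [[k, n - k], [K - k, 25 - K - (n - k)]]
            _, p_fisher = stats.fisher_exact(table, alternative="greater")
            assert res.loc[0, "p"] == pytest.approx(p_fisher, rel=1e-9)

    def test_set_size_window_applied_before_fdr(self):
        background = BackgroundSpec("custom", frozenset(f"G{i}" for i in range(30)))
        lib = library_of(
            BIG=[f"G{i}" for i in range(20)],
            SMALL=["G0", "G1"],
            OK=[f"G{i}" for i in range(5, 15)],
        )
        res = ora_test(
            frozenset(["G5", "G6", "G7"]), background, lib, min_set_size=3, max_set_size=15
        )
        assert set(res["set"]) == {"OK"}
        # FDR over the single tested set equals its p
        assert res.loc[0, "fdr"] == pytest.approx(res.loc[0, "p"])

    def test_strict_background_enforcement(self):
        background = BackgroundSpec("custom", frozenset(["G1", "G2"]))
        lib = library_of(S=["G1", "G2"])
        with pytest.raises(BackgroundError):
            ora_test(frozenset(["G1", "G9"]), background, lib, min_set_size=1)
        res = ora_test(
            frozenset(["G1", "G9"]), background, lib, min_set_size=1, on_missing="lenient"
        )
        assert res.loc[0, "N"] == 3  # G9 unioned in

    def test_empty_query_rejected(self, tiny_library):
        background = BackgroundSpec("custom", frozenset(["G01"]))
        with pytest.raises(ValueError):
            ora_test(frozenset(), background, tiny_library)


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_statsmodels_and_dominates_input(self, pvals):
        q = bh_adjust(pvals)
        _, q_ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert q == pytest.approx(q_ref, rel=1e-12, abs=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-15)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        assert bh_adjust(p[perm]) == pytest.approx(bh_adjust(p)[perm])


def rank_sum_exact_oracle(all_scores, member_idx):
    """Two-sided rank-sum p by enumerating every equally likely subset."""
    ranks = stats.rankdata(all_scores)
    k = len(member_idx)
    w = ranks[member_idx].sum()
    sums = [sum(c) for c in combinations(ranks, k)]
    eps = 1e-9
    p_ge = sum(s >= w - eps for s in sums) / len(sums)
    p_le = sum(s <= w + eps for s in sums) / len(sums)
    return min(1.0, 2 * min(p_ge, p_le))


class TestFcsRankTest:
    def _de(self, scores):
        genes = [f"G{i}" for i in range(len(scores))]
        # encode the desired signed score via log2fc sign and p magnitude
        log2fc = [1.0 if s >= 0 else -1.0 for s in scores]
        p = [10.0 ** (-abs(s)) for s in scores]
        return make_de_table(genes, log2fc, p)

    def test_top_three_of_eight_exact_p(self):
        """Set occupying ranks {6,7,8} of 8: two-sided exact p = 2/56."""
        de = self._de([1, 2, 3, 4, 5, 6, 7, 8])
        lib = library_of(TOP=["G5", "G6", "G7"])
        res = fcs_rank_test(de, lib, min_set_size=3)
        assert res.loc[0, "p"] == pytest.approx(2 / 56, rel=1e-12)
        assert res.loc[0, "s_score"] > 0

    def test_symmetric_members_score_zero(self):
        de = self._de([1, 2, 3, 4, 5, 6, 7])
        lib = library_of(MID=["G0", "G3", "G6"])  # ranks 1, 4, 7
        res = fcs_rank_test(de, lib, min_set_size=3)
        assert res.loc[0, "s_score"] == pytest.approx(0.0)

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(6, 13))
            scores = rng.normal(size=n).round(1)  # rounding invites ties
            k = int(rng.integers(2, min(n - 1, 10) + 1))
            member_idx = rng.choice(n, size=k, replace=False)
            de = self._de(scores)
            lib = library_of(S=[f"G{i}" for i in member_idx])
            res = fcs_rank_test(de, lib, min_set_size=2)
            expected = rank_sum_exact_oracle(scores, member_idx)
            assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_asymptotic_branch_tracks_scipy(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=120)
        member_idx = rng.choice(120, size=25, replace=False)
        de = self._de(scores)
        lib = library_of(S=[f"G{i}" for i in member_idx])
        res = fcs_rank_test(de, lib, min_set_size=5)
        mask = np.zeros(120, bool)
        mask[member_idx] = True
        _, p_ref = stats.mannwhitneyu(scores[mask], scores[~mask], alternative="two-sided")
        assert res.loc[0, "p"] == pytest.approx(p_ref, rel=1e-6)

    def test_degenerate_sets_are_skipped(self):
        de = self._de([1, 2, 3, 4])
        lib = library_of(ALL=["G0", "G1", "G2", "G3"], NONE=["X1", "X2"])
        res = fcs_rank_test(de, lib, min_set_size=1)
        assert len(res) == 0

    def test_s_score_stays_inside_open_unit_interval(self):
        de = self._de([1, 2, 3, 4, 5, 6, 7, 8])
        lib = library_of(TOP=["G6", "G7"], BOTTOM=["G0", "G1"])
        res = fcs_rank_test(de, lib, min_set_size=2).set_index("set")
        assert -1 < res.loc["BOTTOM", "s_score"] < 0 < res.loc["TOP", "s_score"] < 1


class TestSignificantSets:
    def _results(self):
        return pd.DataFrame(
            {
                "set": ["A", "B", "C"],
                "direction": ["up", "down", "up"],
                "p": [0.01, 0.04, 0.2],
                "fdr": [0.03, 0.05, 0.3],
            }
        )

    def test_fdr_threshold_is_strict(self):
        out = significant_sets(self._results(), "fdr", 0.05)
        assert out.members == {("A", "up")}  # B sits exactly at 0.05

    def test_nominal_mode_uses_raw_p(self):
        out = significant_sets(self._results(), "nominal", 0.05)
        assert out.members == {("A", "up"), ("B", "down")}

    def test_empty_results(self):
        out = significant_sets(pd.DataFrame(columns=["set", "direction", "p", "fdr"]))
        assert len(out) == 0

    def test_alpha_one_nominal_keeps_all_tested_sets(self):
        out = significant_sets(self._results(), "nominal", 1.0)
        assert len(out) == 3

    def test_fcs_direction_from_score_sign(self):
        res = pd.DataFrame(
            {"set": ["A", "B"], "s_score": [0.4, -0.2], "p": [0.001, 0.002],
             "fdr": [0.002, 0.002]}
        )
        out = significant_sets(res, "fdr", 0.05)
        assert out.members == {("A", "up"), ("B", "down")}
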
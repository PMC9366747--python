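import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmod.profiler import Event, IsomiRCall, ModificationProfile, Unaligned
from mirmod.ptm import (
    compare_groups,
    fraction_modified,
    fraction_modified_from_profiles,
    kruskal_wallis,
    positional_mono_fractions,
    top_sets,
    wilcoxon_signed_rank,
)
from oracles import oracle_kw, oracle_signed_rank_p


def _call(i, mirna="mir-a", events=()):
    return IsomiRCall(f"r{i}", mirna, 0, (0, 19), list(events))


MONO_C0 = Event("3p", 0, "addition", "C", "mono", True)


class TestFractionModified:
    def test_basic_fraction(self):
        calls = [_call(i) for i in range(9)] + \
                [_call(9 + i, events=[MONO_C0]) for i in range(3)]
        tab = fraction_modified({"s1": calls}, min_reads=10)
        row = tab.iloc[0]
        assert row["n_reads"] == 12
        assert row["fraction"] == pytest.approx(0.25)
        assert not row["excluded"]

    def test_low_coverage_mirna_excluded(self):
        calls = [_call(i) for i in range(9)]
        tab = fraction_modified({"s1": calls}, min_reads=10)
        assert tab.iloc[0]["excluded"]
        assert np.isnan(tab.iloc[0]["fraction"])

    def test_all_canonical_gives_zero(self):
        calls = [_call(i) for i in range(15)]
        tab = fraction_modified({"s1": calls}, min_reads=10)
        assert tab.iloc[0]["fraction"] == 0.0

    def test_invariant_to_read_order(self):
        rng = np.random.default_rng(3)
        calls = [_call(i, events=[MONO_C0] if rng.random() < 0.4 else [])
                 for i in range(40)]
        tab1 = fraction_modified({"s1": calls}, min_reads=10)
        shuffled = list(calls)
        rng.shuffle(shuffled)
        tab2 = fraction_modified({"s1": shuffled}, min_reads=10)
        pd.testing.assert_frame_equal(tab1, tab2)

    def test_end_restriction(self):
        ev5 = Event("5p", 1, "addition", "A", "mono", True)
        calls = [_call(0, events=[ev5]), _call(1, events=[MONO_C0])] + \
                [_call(i) for i in range(2, 12)]
        tab = fraction_modified({"s1": calls}, min_reads=10, end="3p")
        assert tab.iloc[0]["n_modified"] == 1

    def test_profile_aggregates_match_per_read_table(self):
        rng = np.random.default_rng(4)
        calls = [_call(i, events=[MONO_C0] if rng.random() < 0.3 else [])
                 for i in range(30)]
        prof = ModificationProfile(sample_id="s1")
        for c in calls:
            prof.add_call(c)
        a = fraction_modified({"s1": calls}, min_reads=10)
        b = fraction_modified_from_profiles({"s1": prof}, min_reads=10)
        pd.testing.assert_frame_equal(a, b)


class TestTopSets:
    def test_dominant_feature_first(self):
        counts = pd.DataFrame({"s1": [100, 5, 5], "s2": [90, 10, 5]},
                              index=["big", "m1", "m2"])
        assert top_sets(counts, "expressed", n=1) == ["big"]

    def test_tie_breaks_lexicographically(self):
        counts = pd.DataFrame({"s1": [50, 50, 1]}, index=["zzz", "aaa", "mid"])
        assert top_sets(counts, "expressed", n=2) == ["aaa", "zzz"]

    def test_enriched_mode_filters_by_padj(self):
        de = pd.DataFrame(
            {"log2fc": [5.0, 4.0, 3.0], "padj": [0.5, 0.01, 0.01]},
            index=["ns", "top", "second"],
        )
        with pytest.warns(UserWarning, match="significant"):
            got = top_sets(de, "enriched", n=3)
        assert got == ["top", "second"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(30, 4)),
            index=[f"m{i:02d}" for i in range(30)],
            columns=list("abcd"),
        )
        got = top_sets(counts, "expressed", group=["a", "b"], n=10)
        cpms = counts[["a", "b"]] / counts[["a", "b"]].sum() * 1e6
        score = cpms.mean(axis=1)
        expected = sorted(counts.index, key=lambda m: (-score[m], m))[:10]
        assert got == expected


class TestPositionalMonoFractions:
    def _profile(self):
        prof = ModificationProfile(sample_id="s1")
        for i in range(95):
            prof.add_call(_call(i))
        for i in range(5):
            prof.add_call(_call(95 + i, events=[MONO_C0]))
        return prof

    def test_basic_fraction(self):
        tab = positional_mono_fractions(self._profile())
        cell = tab[(tab["position"] == 0) & (tab["nucleotide"] == "C")]
        assert cell["fraction"].iloc[0] == pytest.approx(0.05)

    def test_no_additions_gives_all_zero(self):
        prof = ModificationProfile(sample_id="s1")
        for i in range(10):
            prof.add_call(_call(i))
        tab = positional_mono_fractions(prof)
        assert (tab["fraction"] == 0).all()

    def test_poly_runs_do_not_count_as_mono(self):
        prof = ModificationProfile(sample_id="s1")
        poly = [Event("3p", 1, "addition", "C", "poly", True),
                Event("3p", 2, "addition", "C", "poly", False)]
        for i in range(10):
            prof.add_call(_call(i, events=poly))
        tab = positional_mono_fractions(prof, positions=(1,))
        assert (tab["fraction"] == 0).all()

    def test_fractions_sum_to_at_most_one_per_position(self):
        rng = np.random.default_rng(6)
        prof = ModificationProfile(sample_id="s1")
        for i in range(200):
            events = []
            if rng.random() < 0.5:
                nt = "ACGU"[rng.integers(4)]
                pos = int(rng.integers(-1, 2))
                events = [Event("3p", pos, "addition", nt, "mono", True)]
            prof.add_call(_call(i, events=events))
        tab = positional_mono_fractions(prof)
        sums = tab.groupby("position")["fraction"].sum()
        assert (sums <= 1.0 + 1e-12).all()

    def test_empty_scope_fails(self):
        with pytest.raises(ValueError, match="empty scope"):
            positional_mono_fractions(self._profile(), mirna_set=["absent"])


class TestWilcoxonSignedRank:
    def test_five_positive_differences_exact_p(self):
        """All 5 paired differences positive: two-sided exact p = 2/32."""
        w, p = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5])
        assert w == pytest.approx(15.0)
        assert p == pytest.approx(0.0625)

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            _, p = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert p == 1.0

    def test_matches_enumeration_oracle_with_ties_and_zeros(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(2, 11))
            # half-integer grid forces ties; occasional zeros get dropped
            d = np.round(rng.normal(0, 2, n) * 2) / 2
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(oracle_signed_rank_p(d.tolist()))

    def test_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            d = rng.normal(0, 1, 12)
            _, p = wilcoxon_signed_rank(d)
            ref = stats.wilcoxon(d, mode="exact").pvalue
            assert p == pytest.approx(ref)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.5, 1, 60)
        _, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, correction=False, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestKruskalWallis:
    def test_symmetric_groups_give_zero_h(self):
        h, p = kruskal_wallis([1, 6], [2, 5], [3, 4])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi2_path_matches_scipy(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            g = [rng.normal(size=rng.integers(3, 8)) for _ in range(3)]
            h, p = kruskal_wallis(*g)
            ref_h, ref_p = stats.kruskal(*g)
            assert h == pytest.approx(ref_h)
            assert p == pytest.approx(ref_p)

    def test_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            sizes = [3, 3, 3]
            g = [np.round(rng.normal(size=s), 1).tolist() for s in sizes]
            h, p = kruskal_wallis(*g, method="exact")
            ref_h, ref_p = oracle_kw(g)
            assert h == pytest.approx(ref_h)
            assert p == pytest.approx(ref_p)

    def test_exact_with_ties(self):
        g = [[1, 1, 2], [2, 3, 3], [1, 3]]
        h, p = kruskal_wallis(*g, method="exact")
        ref_h, ref_p = oracle_kw([list(map(float, x)) for x in g])
        assert h == pytest.approx(ref_h)
        assert p == pytest.approx(ref_p)


class TestCompareGroups:
    def test_dispatch_and_pairing(self):
        vals = {"activated": [0.1, 0.2, 0.3, 0.25, 0.15],
                "EV": [0.2, 0.35, 0.4, 0.45, 0.3]}
        res = compare_groups(vals, test="wilcoxon_signed_rank")
        assert res["p"] == pytest.approx(0.0625)
        res_kw = compare_groups(vals, test="kruskal_wallis")
        assert res_kw["statistic"] > 0
        res_mw = compare_groups(vals, test="mann_whitney")
        ref = stats.mannwhitneyu(vals["activated"], vals["EV"],
                                 alternative="two-sided")
        assert res_mw["p"] == pytest.approx(ref.pvalue)

    def test_paired_lengths_must_match(self):
        with pytest.raises(ValueError, match="equal length"):
            compare_groups({"a": [1, 2], "b": [1, 2, 3]},
                           test="wilcoxon_signed_rank")
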
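"""MLG calling, P_sex clonality and diversity indices."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonering import (
    HaploidGenotype,
    assign_mlgs,
    allele_frequencies,
    clone_correct,
    genotypic_richness,
    p_gen,
    p_sex,
    p_sex_significance,
    simpson_diversity,
    simpson_evenness,
    unbiased_gene_diversity,
)
from clonering.clonality import p_gen_round_robin

from .conftest import make_record


def brute_force_groups(records):
    """O(N^2) pairwise grouping oracle for MLG assignment."""
    groups = []
    for rec in records:
        for grp in groups:
            if grp[0].genotype.key == rec.genotype.key:
                grp.append(rec)
                break
        else:
            groups.append([rec])
    return groups


class TestAssignMLGs:
    def test_two_identical_of_five_gives_four_mlgs(self):
        recs = [
            make_record("a", (1, 2), "MAT1-1"),
            make_record("b", (1, 2), "MAT1-1"),
            make_record("c", (1, 3), "MAT1-1"),
            make_record("d", (2, 2), "MAT1-2"),
            make_record("e", (2, 3), "MAT1-2"),
        ]
        mlgs = assign_mlgs(recs)
        assert len(mlgs) == 4
        assert mlgs[0].n_ramets == 2
        assert [g[0].sample_id for g in brute_force_groups(recs)] == [
            m.ramets[0].sample_id for m in mlgs
        ]

    def test_all_identical_is_one_mlg(self):
        recs = [make_record(f"s{i}", (1, 2), "MAT1-1") for i in range(7)]
        (mlg,) = assign_mlgs(recs)
        assert mlg.n_ramets == 7

    def test_opposite_mat_splits_identical_ssr_profiles(self):
        recs = [
            make_record("a", (1, 2), "MAT1-1"),
            make_record("b", (1, 2), "MAT1-2"),
        ]
        assert len(assign_mlgs(recs)) == 2

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 3), st.integers(1, 3),
                              st.booleans()), min_size=1, max_size=40))
    def test_matches_pairwise_oracle(self, profiles):
        recs = [
            make_record(f"s{i}", (a, b), "MAT1-1" if m else "MAT1-2")
            for i, (a, b, m) in enumerate(profiles)
        ]
        mlgs = assign_mlgs(recs)
        oracle = brute_force_groups(recs)
        assert sorted(m.n_ramets for m in mlgs) == sorted(len(g) for g in oracle)
        assert len(mlgs) == len(oracle)


class TestAlleleFrequencies:
    def test_hand_counts(self):
        recs = [make_record(f"s{i}", (a,), "MAT1-1") for i, a in enumerate([1, 1, 2, 2])]
        assert allele_frequencies(recs)[0] == {1: 0.5, 2: 0.5}

    def test_monomorphic_locus(self):
        recs = [make_record(f"s{i}", (7,), "MAT1-1") for i in range(4)]
        assert allele_frequencies(recs)[0] == {7: 1.0}

    def test_clone_correction_removes_clone_weight(self):
        clone = [make_record(f"c{i}", (1,), "MAT1-1") for i in range(200)]
        others = [make_record("x", (2,), "MAT1-1"), make_record("y", (3,), "MAT1-1")]
        raw = allele_frequencies(clone + others)
        cc = allele_frequencies(clone + others, clone_corrected=True)
        assert raw[0][1] == 200 / 202
        assert cc[0] == {1: pytest.approx(1 / 3), 2: pytest.approx(1 / 3),
                         3: pytest.approx(1 / 3)}


class TestPgenPsex:
    def test_pgen_is_product_of_allele_frequencies(self):
        g = HaploidGenotype((1, 1, 1), "MAT1-1")
        freqs = {0: {1: 0.5}, 1: {1: 0.5}, 2: {1: 0.5}}
        assert p_gen(g, freqs) == pytest.approx(0.125)
        freqs = {0: {1: 0.3}, 1: {1: 0.2}, 2: {1: 1.0}}
        assert p_gen(g, freqs) == pytest.approx(0.06)
        assert p_gen(g, {0: {1: 1.0}, 1: {1: 1.0}, 2: {1: 1.0}}) == 1.0

    def test_round_robin_excludes_focal_mlg(self):
        recs = [
            make_record("a", (1,), "MAT1-1"),
            make_record("b", (1,), "MAT1-1"),  # same MLG as a
            make_record("c", (2,), "MAT1-1"),
            make_record("d", (1,), "MAT1-2"),
        ]
        # focal (1,)/MAT1-1: others are (2,)/MAT1-1 and (1,)/MAT1-2
        assert p_gen_round_robin(recs[0].genotype, recs) == pytest.approx(0.5)

    def test_psex_equals_exact_binomial_summation(self):
        pgen, n, N = 0.01, 2, 10
        exact = sum(
            math.comb(N, k) * pgen**k * (1 - pgen) ** (N - k) for k in range(n, N + 1)
        )
        assert p_sex(pgen, n, N) == pytest.approx(exact, rel=1e-12)

    def test_psex_anchors_and_methods(self):
        assert p_sex(1.0, 5, 10) == 1.0
        assert p_sex(0.2, 1, 10) == 1.0  # singleton: undefined, returns 1
        pw = p_sex(0.01, 2, 10, method="parks_werth")
        exact = sum(
            math.comb(9, k) * 0.01**k * 0.99 ** (9 - k) for k in range(1, 10)
        )
        assert pw == pytest.approx(exact, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(0.01, 0.99),
        st.integers(2, 19),
        st.integers(20, 40),
    )
    def test_psex_monotone_in_copies_and_pgen(self, pgen, n, N):
        assert p_sex(pgen, n + 1, N) <= p_sex(pgen, n, N) + 1e-15
        assert p_sex(min(0.999, pgen * 1.1), n, N) >= p_sex(pgen, n, N) - 1e-15


class TestPsexSignificance:
    def test_dominant_clone_is_significant_and_deterministic(self, ring_sim):
        ds, _, _ = ring_sim
        recs = ds.resolved_records
        mlgs = assign_mlgs(recs)
        freqs = allele_frequencies(recs, clone_corrected=True)
        p_sex_significance(mlgs, freqs, seed=7)
        flags1 = [m.significant for m in mlgs]
        dominant = max(mlgs, key=lambda m: m.n_ramets)
        assert dominant.significant
        mlgs2 = assign_mlgs(recs)
        p_sex_significance(mlgs2, freqs, seed=7)
        assert [m.significant for m in mlgs2] == flags1

    def test_common_profile_duplicate_not_significant(self):
        # 1 locus, 2 alleles: a pair of the most common profile is expected
        recs = [make_record(f"s{i}", (1,), "MAT1-1") for i in range(8)]
        recs += [make_record(f"t{i}", (2,), "MAT1-1") for i in range(4)]
        mlgs = assign_mlgs(recs)
        freqs = allele_frequencies(recs)
        p_sex_significance(mlgs, freqs, n_sim=500, seed=3)
        common = next(m for m in mlgs if m.genotype.alleles == (1,))
        assert not common.significant

    def test_degenerate_null_flags_repeats(self):
        recs = [make_record(f"s{i}", (5, 5), "MAT1-1") for i in range(4)]
        mlgs = assign_mlgs(recs)
        freqs = allele_frequencies(recs)
        p_sex_significance(mlgs, freqs, n_sim=50, seed=1)
        assert mlgs[0].significant


class TestCloneCorrection:
    def test_significant_mlg_collapses_to_centroid(self):
        recs = [
            make_record("a", (1,), "MAT1-1", x=0.0, y=0.0),
            make_record("b", (1,), "MAT1-1", x=2.0, y=0.0),
        ]
        (mlg,) = assign_mlgs(recs)
        mlg.significant = True
        (entry,) = clone_correct([mlg])
        assert entry[1] == (1.0, 0.0)

    def test_non_significant_repeat_keeps_every_ramet(self):
        recs = [make_record(f"s{i}", (1,), "MAT1-1", x=float(i), y=0.0) for i in range(3)]
        (mlg,) = assign_mlgs(recs)
        mlg.significant = False
        assert len(clone_correct([mlg])) == 3

    def test_all_singletons_identity(self):
        recs = [make_record(f"s{i}", (i,), "MAT1-1", x=float(i), y=0.0) for i in range(1, 5)]
        mlgs = assign_mlgs(recs)
        corrected = clone_correct(mlgs)
        assert [e[0].key for e in corrected] == [r.genotype.key for r in recs]
        assert [e[1] for e in corrected] == [r.position for r in recs]


def compositions(n, g):
    """All ramet-count compositions of n samples into g MLGs (ordered)."""
    if g == 1:
        yield (n,)
        return
    for first in range(1, n - g + 2):
        for rest in compositions(n - first, g - 1):
            yield (first,) + rest


class TestDiversityIndices:
    @pytest.mark.parametrize(
        "n,g,expected",
        [(205, 2, 0.005), (66, 34, 0.508), (20, 20, 1.000), (271, 56, 0.204),
         (103, 63, 0.608), (88, 51, 0.575)],
    )
    def test_richness_reproduces_published_rows(self, n, g, expected):
        assert round(genotypic_richness(n, g), 3) == expected

    def test_richness_extremes(self):
        assert genotypic_richness(10, 1) == 0.0
        assert genotypic_richness(20, 20) == 1.0

    def test_simpson_hand_values(self):
        assert simpson_diversity([5]) == 0.0
        assert simpson_diversity([1] * 6) == 1.0
        assert simpson_diversity([3, 1]) == pytest.approx(0.5)

    def test_simpson_decreases_when_mlgs_merge(self, rng):
        counts = [4, 3, 2, 1, 1]
        merged = [7, 2, 1, 1]
        assert simpson_diversity(merged) < simpson_diversity(counts)

    def test_evenness_anchors_and_brute_force_minimum(self):
        assert simpson_evenness([2, 2, 2]) == pytest.approx(1.0)
        for n in range(4, 9):
            for g in range(2, n):
                values = {
                    tuple(sorted(c)): simpson_evenness(c)
                    for c in compositions(n, g)
                }
                skewed = tuple(sorted([1] * (g - 1) + [n - g + 1]))
                assert values[skewed] == pytest.approx(min(values.values()))
                assert all(-1e-9 <= v <= 1 + 1e-9 for v in values.values())

    def test_evenness_invariant_under_relabeling(self):
        assert simpson_evenness([4, 2, 1]) == simpson_evenness([1, 4, 2])

    def test_uhe_hand_values(self):
        freqs = {0: {1: 0.5, 2: 0.5}, 1: {7: 1.0}}
        out = unbiased_gene_diversity(freqs, 4)
        assert out["per_locus"][0] == pytest.approx(2 / 3)
        assert out["per_locus"][1] == 0.0
        assert out["mean"] == pytest.approx(1 / 3)
        assert out["mean"] == pytest.approx(np.mean(list(out["per_locus"].values())))
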
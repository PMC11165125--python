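"""Exact inheritance-model engines against the enumeration oracle.

Frozen expected values were computed ahead of time with an independent
brute-force enumeration over labeled chromosomes (all perfect matchings ×
all segregation patterns) and are asserted as exact rationals.
"""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from hexaseg import (
    DISOMIC,
    POLYSOMIC,
    GenotypeError,
    HomoeologGenotype,
    PairingModel,
    classify_offspring,
    disomic_gametes,
    dual_sourced_classes,
    matching_enumeration_gametes,
    mixed_gametes,
    offspring_distribution,
    parse_genotype,
    polysomic_gametes,
)

F = Fraction


class TestPolysomicGametes:
    def test_hexaploid_tri_type(self):
        # frozen from the matching-enumeration oracle: 15 matchings x 8 patterns
        d = polysomic_gametes("AABBCC")
        assert d.p("ABC") == F(8, 20)
        for g in ("AAB", "AAC", "ABB", "BBC", "ACC", "BCC"):
            assert d.p(g) == F(2, 20)

    def test_hexaploid_uneven(self):
        d = polysomic_gametes("ABBBCC")
        expected = {"ABC": F(3, 10), "BBC": F(3, 10), "ABB": F(3, 20),
                    "BCC": F(3, 20), "BBB": F(1, 20), "ACC": F(1, 20)}
        assert {str(g): p for g, p in d.items()} == expected

    def test_single_type(self):
        assert dict(polysomic_gametes("AA")) == {parse_genotype("A"): F(1)}

    def test_odd_ploidy_uniform_subsets(self):
        # 7 chromosomes: with univalent transmission 1/2 the gamete is
        # uniform over all 3- and 4-subsets (2 * C(7,3) = 70 of them)
        d = polysomic_gametes("ABBBBCC")
        assert d.p("ABB") == F(6, 70)  # C(1,1)*C(4,2)
        assert d.p("BBBB") == F(1, 70)
        assert d.p("ABBC") == F(12, 70)

    def test_too_small_parent(self):
        with pytest.raises(GenotypeError):
            polysomic_gametes("A")


class TestDisomicGametes:
    def test_leftover_bivalent(self):
        # AA and CC pair preferentially; leftover A and B form a bivalent
        d = disomic_gametes("AAABCC")
        assert dict(d) == {parse_genotype("AAC"): F(1, 2), parse_genotype("ABC"): F(1, 2)}

    def test_single_univalent(self):
        d = disomic_gametes("ABBBBCC")
        assert dict(d) == {parse_genotype("ABBC"): F(1, 2), parse_genotype("BBC"): F(1, 2)}

    def test_fully_paired(self):
        assert dict(disomic_gametes("AAAABB")) == {parse_genotype("AAB"): F(1)}

    def test_three_leftovers(self):
        # AAABBBC: one univalent chosen uniformly among leftovers {A, B, C}
        d = disomic_gametes("AAABBBC")
        assert sum(d.values()) == 1
        assert d.p("AB") == 0  # base AB always present, gamete never smaller


class TestMixtureAndOffspring:
    def test_mixture_boundaries(self):
        m1 = PairingModel(mode="mixed", f_di=1)
        m0 = PairingModel(mode="mixed", f_di=0)
        assert dict(mixed_gametes("AABBBC", m1)) == dict(disomic_gametes("AABBBC"))
        assert dict(mixed_gametes("AABBBC", m0)) == dict(polysomic_gametes("AABBBC"))

    def test_mixture_linear(self):
        m = PairingModel(mode="mixed", f_di=F(1, 2))
        d = mixed_gametes("AABBCC", m)
        assert d.p("ABC") == F(1, 2) * 1 + F(1, 2) * F(2, 5)

    def test_f1_cross_printed_expectations(self):
        off_d = offspring_distribution("AAABCC", "ABBBCC", DISOMIC)
        off_p = offspring_distribution("AAABCC", "ABBBCC", POLYSOMIC)
        assert off_d.p("AAABCC") == F(1, 4)
        assert off_p.p("AAABCC") == F(21, 200)

    def test_polysomic_selfing_parental_class(self):
        off = offspring_distribution("AABBCC", "AABBCC", POLYSOMIC)
        assert off.p("AABBCC") == F(11, 50)

    def test_disomic_selfing_1_2_1(self):
        off = offspring_distribution("ABBBBCC", "ABBBBCC", DISOMIC)
        assert dict(off) == {
            parse_genotype("AABBBBCC"): F(1, 4),
            parse_genotype("ABBBBCC"): F(1, 2),
            parse_genotype("BBBBCC"): F(1, 4),
        }

    def test_disomic_selfing_degenerate(self):
        off = offspring_distribution("AABBCC", "AABBCC", DISOMIC)
        assert dict(off) == {parse_genotype("AABBCC"): F(1)}

    def test_individual_vs_gamete_coupling_differ(self):
        mi = PairingModel(mode="mixed", f_di=F(1, 2), coupling="individual")
        mg = PairingModel(mode="mixed", f_di=F(1, 2), coupling="gamete")
        oi = offspring_distribution("AABBBC", "AABBBC", mi)
        og = offspring_distribution("AABBBC", "AABBBC", mg)
        assert oi != og
        assert abs(sum(oi.values()) - 1) == 0
        assert abs(sum(og.values()) - 1) == 0


class TestDualSourcedClasses:
    @pytest.mark.parametrize(
        "parent, n_classes",
        [("AABBCC", 1), ("AABBBC", 3), ("ABBBBCC", 3), ("AAABBBC", 19)],
    )
    def test_selfing_class_counts(self, parent, n_classes):
        full, _ = dual_sourced_classes(parent, parent)
        assert len(full) == n_classes

    def test_full_classes_inside_polysomic_support(self):
        full, partial = dual_sourced_classes("AAABBBC", "AAABBBC")
        poly = offspring_distribution("AAABBBC", "AAABBBC", POLYSOMIC)
        assert full <= poly.support
        assert partial <= poly.support
        assert not (full & partial)


class TestClassifyOffspring:
    @pytest.mark.parametrize(
        "child, category",
        [
            ("AABBCC", "full_dual_sourced"),
            ("AAABBC", "partial_dual_sourced"),
            ("AAAABC", "polysomic_only"),
            ("AAAAAC", "idr_indicative"),
            ("ABCCCCC", "idr_or_unreduced"),
            ("AABCC", "aneuploid_dysploid"),
        ],
    )
    def test_hexaploid_selfing_classes(self, child, category):
        assert classify_offspring("AABBCC", "AABBCC", child).category == category


class TestOracleEquivalence:
    def test_exhaustive_up_to_total_8(self):
        """Closed-form random pairing equals brute-force matching
        enumeration, exactly, for every type composition of 2..8 copies."""
        for total in range(2, 9):
            for a in range(total + 1):
                for b in range(total + 1 - a):
                    for c in range(total + 1 - a - b):
                        g = HomoeologGenotype(a, b, c, total - a - b - c)
                        assert dict(matching_enumeration_gametes(g)) == dict(
                            polysomic_gametes(g)
                        ), g

    def test_budget_guard(self):
        with pytest.raises(GenotypeError):
            matching_enumeration_gametes("AAAABBBBCCC")  # 11 chromosomes

    def test_trivial_pair(self):
        assert dict(matching_enumeration_gametes("AB")) == {
            parse_genotype("A"): F(1, 2), parse_genotype("B"): F(1, 2)
        }


composition = st.tuples(
    st.integers(0, 7), st.integers(0, 7), st.integers(0, 7)
).filter(lambda c: 2 <= sum(c) <= 7)


class TestInvariants:
    @given(composition, st.sampled_from(["disomic", "polysomic"]))
    @settings(max_examples=60, deadline=None)
    def test_normalization_and_conservation(self, counts, mode):
        """Every gamete distribution sums to 1 and transmits each type with
        probability exactly 1/2 (so offspring keep parental type ratios)."""
        parent = HomoeologGenotype(*counts)
        d = (disomic_gametes if mode == "disomic" else polysomic_gametes)(parent)
        assert sum(d.values()) == 1
        exp = d.expected_counts()
        for t in "ABCX":
            assert exp[t] == F(parent.count(t), 2)

    def test_relabeling_symmetry(self):
        swap = {"A": "B", "B": "A", "C": "C", "X": "X"}

        def relabel(g):
            return parse_genotype("".join(sorted(swap[ch] for ch in str(g))))

        for fn in (polysomic_gametes, disomic_gametes):
            d1 = fn("AABBBCC")
            d2 = fn("AABBBCC".translate(str.maketrans("AB", "BA")))
            assert {relabel(g): p for g, p in d1.items()} == dict(d2)

    def test_univalent_transmission_extremes(self):
        d0 = polysomic_gametes("ABBBBCC", univalent_transmission=0)
        d1 = polysomic_gametes("ABBBBCC", univalent_transmission=1)
        assert all(g.total == 3 for g in d0)
        assert all(g.total == 4 for g in d1)
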
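import math

import pytest

from confirmlab import (
    ContingencyTable,
    Rule,
    TestProfile,
    b_prime_from_LR,
    b_star,
    b_star_from_LR,
    bF_star,
    c_star,
    cF_star,
    disconfirmation,
    F_directional,
    from_test_profile,
    star_measure,
)
from tests.conftest import make_random_tables

E1H1 = Rule("e1", "h1")
E0H0 = Rule("e0", "h0")

NAT = from_test_profile(TestProfile(0.5, 0.95, 0.25))

ALL_RULES = [Rule(a, c) for a in ("e1", "e0") for c in ("h1", "h0")] + [
    Rule(a, c) for a in ("h1", "h0") for c in ("e1", "e0")
]


class TestBStar:
    @pytest.mark.parametrize(
        "table, rule, expected",
        [
            (NAT, E1H1, 0.9),  # (0.5 - 0.05)/0.5
            (NAT, E0H0, 0.45 / 0.95),  # (0.95 - 0.5)/0.95, prints as 0.47
            (from_test_profile(TestProfile(1.0, 0.1, 0.5)), E1H1, 0.1),  # (1 - 0.9)/1
        ],
    )
    def test_worked_values(self, table, rule, expected):
        assert b_star(table, rule).value == pytest.approx(expected, abs=1e-9)

    def test_no_counterexamples_is_full_confirmation(self):
        assert b_star(ContingencyTable(7, 3, 0, 5), E1H1).value == 1.0

    def test_matches_likelihood_ratio_transform(self, random_positive_tables):
        for t in random_positive_tables:
            lr = t.cond("e1", "h1") / t.cond("e1", "h0")
            assert b_star(t, E1H1).value == pytest.approx(
                (lr - 1) / max(lr, 1), abs=1e-12
            )

    def test_count_identity_cross_check(self, random_positive_tables):
        # ad - bc over max(a(c+d), c(a+b))
        for t in random_positive_tables[:100]:
            a, b, c, d = t.as_tuple()
            expected = (a * d - b * c) / max(a * (c + d), c * (a + b))
            assert b_star(t, E1H1).value == pytest.approx(expected, abs=1e-12)


class TestCStar:
    @pytest.mark.parametrize(
        "table, rule, expected",
        [
            (ContingencyTable(200, 0, 720, 80), E1H1, -520 / 720),  # prints -0.722
            (ContingencyTable(5, 1, 5, 1), E1H1, 0.0),
            (ContingencyTable(21, 10, 10, 20), E1H1, 11 / 21),  # prints 0.524
        ],
    )
    def test_worked_values(self, table, rule, expected):
        assert c_star(table, rule).value == pytest.approx(expected, abs=1e-9)

    def test_depends_only_on_antecedent_counts(self):
        base = ContingencyTable(12, 5, 7, 9)
        moved = ContingencyTable(12, 50, 7, 90)  # only e0 column changed
        assert c_star(base, E1H1).value == c_star(moved, E1H1).value

    def test_equals_b_star_under_balanced_prior(self):
        # a + b = c + d makes P(h1) = P(h0) = 0.5
        for t in make_random_tables(50, seed=9):
            d = t.a + t.b - t.c
            if d <= 0:
                continue
            bal = ContingencyTable(t.a, t.b, t.c, d)
            assert c_star(bal, E1H1).value == pytest.approx(
                b_star(bal, E1H1).value, abs=1e-9
            )


class TestCFStar:
    @pytest.mark.parametrize(
        "a, c, expected",
        [(20, 8, 12 / 28), (5, 5, 0.0), (200, 720, -520 / 920)],
    )
    def test_difference_over_sum(self, a, c, expected):
        t = ContingencyTable(a, 3, c, 7)
        assert cF_star(t, E1H1).value == pytest.approx(expected, abs=1e-12)

    def test_bF_star_is_F_on_every_rule(self, random_positive_tables):
        for t in random_positive_tables[:100]:
            for rule in ALL_RULES:
                assert bF_star(t, rule).value == pytest.approx(
                    F_directional(t, rule).value, abs=1e-12
                )


class TestFromLikelihoodRatio:
    @pytest.mark.parametrize(
        "lr, expected_b, expected_bprime",
        [(10, 0.9, 0.1), (1, 0.0, 1.0), (2, 0.5, 0.5), (0.5, -0.5, 0.5)],
    )
    def test_transforms(self, lr, expected_b, expected_bprime):
        assert b_star_from_LR(lr).value == pytest.approx(expected_b)
        assert b_prime_from_LR(lr).value == pytest.approx(expected_bprime)

    def test_undefined_lr(self):
        assert not b_star_from_LR(math.nan).defined


class TestDisconfirmation:
    def test_nat_bprime(self):
        assert disconfirmation(NAT, E1H1, kind="b").value == pytest.approx(0.1)

    def test_links_to_star_value(self, random_positive_tables):
        # b* = 1 - b'* when b* >= 0, b* = b'* - 1 otherwise (same for c)
        for t in random_positive_tables[:100]:
            for kind, fn in (("b", b_star), ("c", c_star)):
                star = fn(t, E1H1).value
                prime = disconfirmation(t, E1H1, kind=kind).value
                expected = 1 - prime if star >= 0 else prime - 1
                assert star == pytest.approx(expected, abs=1e-12)


class TestStarProperties:
    @pytest.mark.parametrize("name", ["b*", "c*", "cF*", "bF*"])
    def test_consequent_symmetry_exact(self, name, random_positive_tables):
        for t in random_positive_tables[:100]:
            for rule in ALL_RULES:
                lhs = star_measure(name, t, rule).value
                rhs = star_measure(name, t, rule.negated_consequent).value
                assert lhs == pytest.approx(-rhs, abs=1e-12)

    def test_b_star_from_F(self, random_positive_tables):
        # b* = 2F/(1+F) for F >= 0
        for t in random_positive_tables:
            F = F_directional(t, E1H1).value
            if F >= 0:
                assert b_star(t, E1H1).value == pytest.approx(2 * F / (1 + F), abs=1e-9)

    def test_scale_invariance(self, random_positive_tables):
        for t in random_positive_tables[:50]:
            scaled = t.scaled(17.5)
            for name in ("b*", "c*", "bF*", "cF*"):
                assert star_measure(name, t, E1H1).value == pytest.approx(
                    star_measure(name, scaled, E1H1).value, abs=1e-12
                )

    @pytest.mark.parametrize("name", ["b*", "c*", "cF*"])
    def test_logicality(self, name):
        no_counter = ContingencyTable(6, 2, 0, 9)
        no_positive = ContingencyTable(0, 2, 6, 9)
        assert star_measure(name, no_counter, E1H1).value == 1.0
        assert star_measure(name, no_positive, E1H1).value == -1.0

    def test_degenerate_pair_is_undefined_not_zero(self):
        t = ContingencyTable(0, 4, 0, 6)  # no e1 examples at all
        assert not c_star(t, E1H1).defined
        assert not cF_star(t, E1H1).defined
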
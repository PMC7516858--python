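import math

import numpy as np
import pytest

from confirmlab import (
    ContingencyTable,
    TestProfile,
    TruthFunction,
    avg_semantic_information,
    b_star,
    from_test_profile,
    logical_probability,
    mixture_information,
    mixture_truth,
    optimize_bprime,
    optimize_truth_function,
    semantic_information,
)
from confirmlab.semantic import conditional_log_likelihood
from tests.conftest import make_random_tables

PRIOR = {"h1": 0.25, "h0": 0.75}
MIX = mixture_truth({"h1"}, b_prime=0.1)


class TestTruthFunctions:
    def test_gaussian_peaks_at_one_at_center(self):
        tf = TruthFunction("gaussian", {"center": 20.0, "sigma": 3.5})
        assert tf(20.0) == 1.0
        assert 0 < tf(25.0) < 1

    def test_logistic_is_monotone(self):
        tf = TruthFunction("logistic", {"rate": 0.2, "midpoint": 65.0})
        xs = [40, 55, 65, 75, 90]
        values = [tf(x) for x in xs]
        assert values == sorted(values)
        assert tf(65.0) == pytest.approx(0.5)

    def test_mixture_floor_and_peak(self):
        assert MIX("h1") == 1.0
        assert MIX("h0") == pytest.approx(0.1)

    def test_json_round_trip(self):
        for tf in (
            MIX,
            TruthFunction("gaussian", {"center": 20.0, "sigma": 3.5}),
            TruthFunction("tabular", {"values": {"h1": 1.0, "h0": 0.25}}),
        ):
            back = TruthFunction.from_json(tf.to_json())
            assert back.family == tf.family
            probe = "h1" if tf.family != "gaussian" else 21.5
            assert back(probe) == tf(probe)

    def test_out_of_range_truth_rejected(self):
        with pytest.raises(ValueError):
            TruthFunction("tabular", {"values": {"h1": 1.5}})


class TestLogicalProbability:
    def test_tautology_is_one(self):
        taut = mixture_truth({"h1"}, b_prime=1.0)
        assert logical_probability(PRIOR, taut) == pytest.approx(1.0)

    def test_mixture_value(self):
        # P(h1) + b' P(h0)
        assert logical_probability(PRIOR, MIX) == pytest.approx(0.325)

    def test_crisp_part_only(self):
        crisp = mixture_truth({"h1"}, b_prime=0.0)
        assert logical_probability(PRIOR, crisp) == pytest.approx(0.25)


class TestSemanticInformation:
    def test_constant_truth_conveys_nothing(self):
        taut = mixture_truth({"h1"}, b_prime=1.0)
        assert semantic_information("h1", taut, PRIOR) == pytest.approx(0.0)

    def test_correct_and_misleading_predictions(self):
        assert semantic_information("h1", MIX, PRIOR) == pytest.approx(
            math.log2(1 / 0.325), abs=1e-9
        )
        assert semantic_information("h0", MIX, PRIOR) == pytest.approx(
            math.log2(0.1 / 0.325), abs=1e-9
        )

    def test_average_matches_mixture_closed_form(self):
        table = ContingencyTable(20, 180, 8, 792)
        sampling = {"h1": table.cond("h1", "e1"), "h0": table.cond("h0", "e1")}
        prior = {"h1": table.prob("h1"), "h0": table.prob("h0")}
        via_avg = avg_semantic_information(sampling, mixture_truth({"h1"}, 0.1), prior)
        assert via_avg == pytest.approx(float(mixture_information(table, 0.1)), abs=1e-12)

    def test_matched_truth_gives_kl_divergence(self):
        table = ContingencyTable(20, 180, 8, 792)
        bstar_prime = optimize_bprime(table)
        value = float(mixture_information(table, bstar_prime))
        p = {"h1": table.cond("h1", "e1"), "h0": table.cond("h0", "e1")}
        q = {"h1": table.prob("h1"), "h0": table.prob("h0")}
        kl = sum(p[h] * math.log2(p[h] / q[h]) for h in p)
        assert value == pytest.approx(kl, abs=1e-12)


class TestOptimizeBPrime:
    def test_closed_form_examples(self):
        nat = from_test_profile(TestProfile(0.5, 0.95, 0.25))
        assert optimize_bprime(nat) == pytest.approx(0.1)
        counts = ContingencyTable(20, 180, 8, 792)
        assert optimize_bprime(counts) == pytest.approx(0.1)
        no_counter = ContingencyTable(5, 5, 0, 10)
        assert optimize_bprime(no_counter) == 0.0

    def test_numeric_mode_agrees_with_closed_form(self):
        for t in make_random_tables(30, seed=11):
            assert optimize_bprime(t, "grid") == pytest.approx(
                optimize_bprime(t), abs=1e-6
            )

    def test_grid_search_never_beats_closed_form(self):
        grid = np.arange(0.0, 1.0001, 1e-4)
        for t in make_random_tables(20, seed=12):
            closed = optimize_bprime(t)
            objective = mixture_information(t, grid)
            assert float(mixture_information(t, closed)) >= np.nanmax(objective) - 1e-10

    def test_links_to_b_star(self):
        from confirmlab import Rule

        for t in make_random_tables(50, seed=13):
            b = b_star(t, Rule("e1", "h1")).value
            if b >= 0:
                assert b == pytest.approx(1 - optimize_bprime(t), abs=1e-12)


class TestOptimizeTruthFunction:
    def test_scales_transition_column_to_peak_one(self):
        nat = from_test_profile(TestProfile(0.5, 0.95, 0.25))
        tf = optimize_truth_function(nat, "e1")
        assert tf("h1") == pytest.approx(1.0)
        assert tf("h0") == pytest.approx(0.1)

    def test_uniform_channel_gives_tautology(self):
        tf = optimize_truth_function(ContingencyTable(1, 1, 1, 1), "e1")
        assert tf("h1") == tf("h0") == 1.0

    def test_majority_counterexample_column(self):
        tf = optimize_truth_function(ContingencyTable(200, 0, 720, 80), "e1")
        assert tf("h1") == pytest.approx(1.0)
        assert tf("h0") == pytest.approx(0.9)


class TestLikelihoodIdentity:
    def test_average_information_matches_log_likelihood(self):
        """N1 * (I(h; th_e1) + sum_i P(h_i|e1) log2 P(h_i)) equals the
        log-likelihood of the positive-result sub-sample."""
        for t in make_random_tables(50, seed=14):
            for b_prime in (0.05, 0.3, 0.8, 1.0):
                truth = mixture_truth({"h1"}, b_prime)
                n1 = t.a + t.c
                sampling = {"h1": t.a / n1, "h0": t.c / n1}
                prior = {"h1": t.prob("h1"), "h0": t.prob("h0")}
                avg_info = avg_semantic_information(sampling, truth, prior)
                entropy_term = sum(
                    sampling[h] * math.log2(prior[h]) for h in sampling
                )
                lhs = n1 * (avg_info + entropy_term)
                rhs = conditional_log_likelihood(t, truth)
                assert lhs == pytest.approx(rhs, abs=1e-9)
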
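import pytest

from confirmlab import (
    ContingencyTable,
    Rule,
    check_logicality_normalization,
    check_monotonicity,
    check_symmetry,
    desiderata_report,
    nicod_fisher_check,
    random_tables,
    raven_experiment,
)
from confirmlab.reproduce import computed_raven_grid


@pytest.fixture(scope="module")
def tables():
    return random_tables(300, seed=99)


class TestSymmetries:
    @pytest.mark.parametrize("measure", ["b*", "c*", "cF*", "F", "Z"])
    def test_hypothesis_symmetry_holds(self, measure, tables):
        assert check_symmetry(measure, "HS", tables).holds

    @pytest.mark.parametrize("measure", ["F", "b*"])
    def test_evidence_and_commutativity_symmetry_fail_with_witness(self, measure, tables):
        for kind in ("ES", "CS"):
            result = check_symmetry(measure, kind, tables)
            assert not result.holds
            assert result.witness is not None

    def test_cs_failure_on_asymmetric_counts(self):
        # F(e1->h1) and F(h1->e1) differ whenever b != c
        result = check_symmetry("F", "CS", [ContingencyTable(20, 180, 8, 792)])
        assert not result.holds

    def test_full_exchange_symmetry_table_satisfies_ts(self, tables):
        symmetric = [ContingencyTable(t.a, t.b, t.b, t.a) for t in tables[:50]]
        for measure in ("F", "b*", "c*", "D"):
            assert check_symmetry(measure, "TS", symmetric).holds

    def test_cs_needs_a_converse_form(self, tables):
        with pytest.raises(ValueError):
            check_symmetry("D", "CS", tables)


class TestMonotonicity:
    @pytest.mark.parametrize("measure", ["F", "L", "Z", "b*", "c*"])
    def test_monotone_measures(self, measure):
        assert check_monotonicity(measure, 1, 6).holds

    @pytest.mark.parametrize("measure", ["D", "M"])
    def test_non_monotone_measures_yield_witness(self, measure):
        result = check_monotonicity(measure, 1, 6)
        assert not result.holds
        assert result.witness is not None

    def test_n_is_monotone_despite_folklore(self):
        # N = a/(a+b) - c/(c+d): every partial derivative has the allowed
        # sign, so unit increments can never falsify it on positive counts
        assert check_monotonicity("N", 1, 6).holds


class TestLogicalityNormalization:
    def test_star_and_F_pass_both(self, tables):
        edge = tables[:100] + [ContingencyTable(4, 2, 0, 3), ContingencyTable(0, 2, 4, 3)]
        for measure in ("F", "Z", "b*", "c*"):
            logicality, normalization = check_logicality_normalization(measure, edge)
            assert logicality.holds
            assert normalization.holds

    def test_log_ratio_measure_fails_normalization(self):
        logicality, normalization = check_logicality_normalization(
            "L", [ContingencyTable(4, 2, 0, 3)]
        )
        assert not normalization.holds


class TestNicodFisher:
    def test_only_prediction_confirmation_passes_at_symmetric_base(self, raven_base):
        passing = {m for m in ("D", "M", "Z", "S", "N", "F", "c*", "b*", "cF*")
                   if nicod_fisher_check(m, raven_base)}
        assert passing == {"c*", "cF*"}

    def test_fails_for_s_and_n_when_b_exceeds_c(self):
        base = ContingencyTable(20, 15, 5, 20)
        assert not nicod_fisher_check("S", base)
        assert not nicod_fisher_check("N", base)
        assert nicod_fisher_check("c*", base)


class TestRavenExperiment:
    def test_published_rows(self, raven_base):
        grid = computed_raven_grid(raven_base)
        assert grid.loc["F"].tolist()[:3] == pytest.approx([0.333, 0.340, 0.348], abs=5e-4)
        assert grid.loc["c*"].tolist()[:3] == pytest.approx([0.5, 0.524, 0.5], abs=5e-4)
        assert grid.loc["D"].tolist()[:3] == pytest.approx([0.167, 0.169, 0.175], abs=5e-4)

    def test_only_c_star_prefers_the_positive_example(self, raven_base):
        rows = raven_experiment(raven_base, ["D", "M", "C", "Z", "F", "c*"])
        assert rows["c*"].advantage > 0
        for m in ("D", "M", "F"):
            assert rows[m].advantage < 0
        for m in ("C", "Z"):
            assert rows[m].advantage == pytest.approx(0.0, abs=5e-4)

    def test_increments_shrink_with_prior_sample_size(self, raven_base):
        """Ten times the evidence makes one new example ten times less
        influential: the degree of confirmation is absolute, its increment
        is not."""
        big = raven_base.scaled(10)
        small_rows = raven_experiment(raven_base, ["D", "c*"])
        big_rows = raven_experiment(big, ["D", "c*"])
        assert big_rows["D"].after_da == pytest.approx(0.1669, abs=5e-5)
        assert big_rows["c*"].after_da == pytest.approx(0.5025, abs=5e-5)
        for m in ("D", "c*"):
            assert abs(big_rows[m].after_da - big_rows[m].base_value) < abs(
                small_rows[m].after_da - small_rows[m].base_value
            )


class TestDesiderataReport:
    def test_report_shape_and_verdicts_for_b_star(self, tables):
        report = desiderata_report("b*", tables=tables, grid_hi=5)
        assert report.symmetries["HS"].holds
        assert not report.symmetries["ES"].holds
        assert report.monotonicity.holds
        assert report.logicality.holds
        assert report.normalization.holds
        assert report.nicod_fisher is False
        payload = report.as_dict()
        assert payload["measure"] == "b*"
        assert payload["symmetries"]["ES"]["witness"] is not None
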
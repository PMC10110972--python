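import math

import pytest
from hypothesis import given, strategies as st

from scarsignal import (
    ContingencyTable,
    ReportSet,
    SMQ_SCOPE,
    build_contingency,
    build_culprit_list,
    classify_signal,
    compute_ror,
    filter_scar_reports,
    screen_positive_drugs,
    signal_matrix,
)
from scarsignal.disproportionality import SignalResult, scope_order

from conftest import make_report

SJS = "Stevens–Johnson syndrome"


def textbook_ror(a, b, c, d):
    """Independent textbook odds ratio with Woolf 95% log-interval (z=1.96)."""
    odds_ratio = (a / c) / (b / d)
    half = 1.96 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return odds_ratio, math.exp(math.log(odds_ratio) - half), math.exp(
        math.log(odds_ratio) + half
    )


class TestComputeRor:
    def test_balanced_table(self):
        est = compute_ror(ContingencyTable(5, 5, 5, 5))
        assert est.ror == 1.0
        assert est.ci_low == pytest.approx(0.1732400118281132, rel=1e-12)
        assert est.ci_high == pytest.approx(5.77233855763176, rel=1e-12)

    def test_eleven_fold_signal(self):
        est = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert est.ror == pytest.approx(11.0, rel=1e-12)
        assert est.ci_low == pytest.approx(5.559514928894626, rel=1e-12)
        assert est.ci_high == pytest.approx(21.76448872744693, rel=1e-12)

    @given(
        a=st.integers(1, 50), b=st.integers(1, 50),
        c=st.integers(1, 50), d=st.integers(1, 50),
    )
    def test_cross_product_symmetry_gives_unity(self, a, b, c, d):
        if a * d == b * c:
            assert compute_ror(ContingencyTable(a, b, c, d)).ror == pytest.approx(1.0)

    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    def test_inversion_symmetry(self, a, b, c, d):
        """Swapping the drug/other-drug columns inverts ROR and swaps CI bounds."""
        est = compute_ror(ContingencyTable(a, b, c, d))
        inv = compute_ror(ContingencyTable(b, a, d, c))
        assert inv.ror == pytest.approx(1 / est.ror, rel=1e-9)
        assert inv.ci_low == pytest.approx(1 / est.ci_high, rel=1e-9)
        assert inv.ci_high == pytest.approx(1 / est.ci_low, rel=1e-9)

    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    def test_ci_symmetric_on_log_scale(self, a, b, c, d):
        est = compute_ror(ContingencyTable(a, b, c, d))
        upper = math.log(est.ci_high) - math.log(est.ror)
        lower = math.log(est.ror) - math.log(est.ci_low)
        assert abs(upper - lower) < 1e-12

    def test_zero_cell_not_evaluable_by_default(self):
        est = compute_ror(ContingencyTable(0, 10, 10, 10))
        assert not est.evaluable and est.ror is None

    def test_haldane_mode_corrects_and_flags(self):
        est = compute_ror(ContingencyTable(0, 10, 10, 10), zero_cell="haldane")
        assert est.evaluable and est.corrected
        assert est.ror == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))
        # full tables are untouched by the mode
        clean = compute_ror(ContingencyTable(5, 5, 5, 5), zero_cell="haldane")
        assert clean.ror == 1.0 and not clean.corrected

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ContingencyTable(-1, 2, 3, 4)


def _result(a, ci_low, evaluable=True):
    return SignalResult(
        drug="d", scope=SMQ_SCOPE, table=ContingencyTable(a, 1, 1, 1),
        ror=2.0, ci_low=ci_low, ci_high=4.0, evaluable=evaluable,
        positive=False,
    )


class TestClassifySignal:
    def test_three_cases_lower_bound_above_one(self):
        assert classify_signal(_result(3, 1.01)) is True

    def test_two_cases_never_positive(self):
        assert classify_signal(_result(2, 5.0)) is False

    def test_lower_bound_exactly_one_is_negative(self):
        assert classify_signal(_result(100, 1.0)) is False

    def test_not_evaluable_is_negative(self):
        res = SignalResult(
            drug="d", scope=SMQ_SCOPE, table=ContingencyTable(5, 0, 1, 1),
            ror=None, ci_low=None, ci_high=None, evaluable=False, positive=False,
        )
        assert classify_signal(res) is False


class TestBuildContingency:
    def test_hand_enumerated_2x2(self, four_report_set):
        t = build_contingency(four_report_set, "drugx", SMQ_SCOPE)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_empty_set(self):
        t = build_contingency(ReportSet([]), "drugx", SMQ_SCOPE)
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)

    def test_absent_drug_gives_empty_margin(self, four_report_set):
        t = build_contingency(four_report_set, "neverseen", SMQ_SCOPE)
        assert t.a + t.b == 0 and t.total == 4

    def test_pt_scope_counts_that_pt_only(self, four_report_set):
        t_sjs = build_contingency(four_report_set, "drugx", SJS)
        assert (t_sjs.a, t_sjs.b) == (1, 1)
        t_ten = build_contingency(four_report_set, "drugx", "Toxic epidermal necrolysis")
        assert t_ten.a == 0 and t_ten.total == 4


def _matrices_for(report_set, **kwargs):
    scar, _ = filter_scar_reports(report_set)
    culprits, _ = build_culprit_list(scar)
    return signal_matrix(report_set, culprits, **kwargs), culprits


class TestSignalMatrix:
    def test_nineteen_results_per_drug_in_scope_order(self, four_report_set):
        matrices, culprits = _matrices_for(four_report_set)
        assert set(matrices) == {"drugx", "drugy"}
        for m in matrices.values():
            assert [r.scope for r in m.results] == scope_order()

    def test_matches_brute_force_recount(self, four_report_set):
        matrices, _ = _matrices_for(four_report_set)
        for drug, matrix in matrices.items():
            for res in matrix.results:
                expected = build_contingency(four_report_set, drug, res.scope)
                assert res.table == expected

    def test_cell_conservation_and_pt_smq_coherence(self, four_report_set):
        matrices, _ = _matrices_for(four_report_set)
        for matrix in matrices.values():
            a_smq = matrix.results[0].table.a
            for res in matrix.results:
                assert res.table.total == len(four_report_set)
                assert res.table.a <= a_smq

    def test_never_cooccurring_pt_not_evaluable(self, four_report_set):
        matrices, _ = _matrices_for(four_report_set)
        ten = [r for r in matrices["drugx"].results
               if r.scope == "Toxic epidermal necrolysis"][0]
        assert not ten.evaluable and not ten.positive

    def test_scar_only_background_restricts_totals(self, four_report_set):
        matrices, _ = _matrices_for(four_report_set, background="scar_only")
        for matrix in matrices.values():
            assert all(r.table.total == 2 for r in matrix.results)


class TestScreen:
    def test_histogram_and_rescan_consistency(self, four_report_set):
        matrices, _ = _matrices_for(four_report_set)
        positives, histogram = screen_positive_drugs(matrices)
        assert sum(histogram.values()) == len(matrices)
        assert positives == [
            d for d, m in matrices.items() if m.n_positive >= 1
        ]
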
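"""Call thresholds, follow-up sample logic, and cohort metrics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddnipt.fetal_fraction import QCReason, SampleQC
from ddnipt.genotype_model import FetalGenotype, PosteriorSummary
from ddnipt.workflow import (
    Call,
    CallThresholds,
    DiscordantCallsError,
    FinalCall,
    GenotypeCall,
    PregnancyResult,
    call_genotype,
    cohort_summary,
    evaluate_pregnancy,
)

QC_PASS = SampleQC(passed=True, reasons=())
QC_LOW_FF = SampleQC(passed=False, reasons=(QCReason.LOW_FETAL_FRACTION,))


def post(p_hom):
    return PosteriorSummary(
        p_hom=p_hom,
        f_post={"median": 0.1, "q2.5": 0.08, "q97.5": 0.12},
        conc_var_post={}, conc_ff_post={}, diagnostics={},
        total_samples=200000, engine="quadrature",
    )


def gcall(call, p_hom=None, weeks=None, sid="s"):
    return GenotypeCall(
        sample_id=sid, call=call, p_hom=p_hom, gestation_weeks=weeks
    )


class TestCallGenotype:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.99, Call.HOM_REF),
            (0.95, Call.HOM_REF),  # thresholds are inclusive
            (0.94, Call.NO_CALL_INTERMEDIATE),
            (0.50, Call.NO_CALL_INTERMEDIATE),
            (0.06, Call.NO_CALL_INTERMEDIATE),
            (0.05, Call.HET),
            (0.01, Call.HET),
        ],
    )
    def test_threshold_rule(self, p, expected):
        assert call_genotype(post(p), QC_PASS).call is expected

    def test_qc_failure_preempts_calling(self):
        c = call_genotype(post(0.99), QC_LOW_FF, f_hat=0.015)
        assert c.call is Call.QC_FAIL
        assert "LOW_FETAL_FRACTION" in c.reasons

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_p_hom(self, p1, p2):
        order = {Call.HET: 0, Call.NO_CALL_INTERMEDIATE: 1, Call.HOM_REF: 2}
        lo, hi = sorted((p1, p2))
        assert (
            order[call_genotype(post(hi), QC_PASS).call]
            >= order[call_genotype(post(lo), QC_PASS).call]
        )

    @given(st.floats(0.0, 1.0), st.floats(0.5, 0.999), st.floats(0.001, 0.499))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_qc_fail_dominates_any_threshold(self, p, hi, lo):
        thr = CallThresholds(p_hom_call=hi, p_het_call=lo)
        assert call_genotype(post(p), QC_LOW_FF, thr).call is Call.QC_FAIL

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            CallThresholds(p_hom_call=0.05, p_het_call=0.95)


class TestEvaluatePregnancy:
    def test_follow_up_resolves_intermediate_first_sample(self):
        res = evaluate_pregnancy(
            "p1",
            [
                gcall(Call.NO_CALL_INTERMEDIATE, 0.5, weeks=12, sid="a"),
                gcall(Call.HOM_REF, 0.99, weeks=20, sid="b"),
            ],
        )
        assert res.final_call is FinalCall.HOM_REF
        assert res.n_samples_used == 2

    def test_only_qc_failures_unresolved(self):
        res = evaluate_pregnancy("p1", [gcall(Call.QC_FAIL, weeks=15)])
        assert res.final_call is FinalCall.UNRESOLVED

    def test_single_conclusive_sample(self):
        res = evaluate_pregnancy("p1", [gcall(Call.HET, 0.01, weeks=15)])
        assert res.final_call is FinalCall.HET and res.n_samples_used == 1

    def test_first_conclusive_in_gestational_order_wins(self):
        # later conclusive samples are not consulted once a call is fixed
        res = evaluate_pregnancy(
            "p1",
            [
                gcall(Call.HOM_REF, 0.99, weeks=24, sid="late"),
                gcall(Call.NO_CALL_INTERMEDIATE, 0.6, weeks=10, sid="early"),
                gcall(Call.HOM_REF, 0.98, weeks=16, sid="mid"),
            ],
        )
        assert res.n_samples_used == 2
        assert res.sample_calls[0].sample_id == "early"

    def test_conflicting_conclusive_calls_raise(self):
        with pytest.raises(DiscordantCallsError):
            evaluate_pregnancy(
                "p1",
                [gcall(Call.HOM_REF, 0.99, weeks=12), gcall(Call.HET, 0.01, weeks=20)],
            )

    def test_undated_samples_sort_last_with_warning(self):
        with pytest.warns(UserWarning, match="gestational age"):
            res = evaluate_pregnancy(
                "p1",
                [gcall(Call.HOM_REF, 0.99, sid="undated"),
                 gcall(Call.QC_FAIL, weeks=12, sid="dated")],
            )
        assert res.sample_calls[0].sample_id == "dated"

    def test_empty_pregnancy_rejected(self):
        with pytest.raises(ValueError):
            evaluate_pregnancy("p1", [])


def preg(pid, final, truth_map, truth):
    truth_map[pid] = truth
    return PregnancyResult(
        pregnancy_id=pid, sample_calls=(), final_call=final, n_samples_used=1
    )


class TestCohortSummary:
    def test_clinical_cohort_arithmetic(self):
        # 33 correct conclusive calls of 38 pregnancies, 0 wrong:
        # 33/38 = 86.8% sensitivity, 100% specificity
        truth = {}
        results = [
            preg(f"h{i}", FinalCall.HOM_REF, truth, FetalGenotype.HOM_REF)
            for i in range(17)
        ]
        results += [
            preg(f"e{i}", FinalCall.HET, truth, FetalGenotype.HET) for i in range(16)
        ]
        results += [
            preg(f"u{i}", FinalCall.UNRESOLVED, truth, FetalGenotype.HOM_REF)
            for i in range(5)
        ]
        s = cohort_summary(results, truth)
        assert s["n_called"] == 33 and s["n_total"] == 38
        assert s["sensitivity_pct"] == pytest.approx(86.8, abs=0.05)
        assert s["specificity_pct"] == pytest.approx(100.0)

    def test_all_unresolved(self):
        truth = {}
        results = [
            preg(f"u{i}", FinalCall.UNRESOLVED, truth, FetalGenotype.HET)
            for i in range(3)
        ]
        s = cohort_summary(results, truth)
        assert s["sensitivity_pct"] == 0.0
        assert s["specificity_pct"] is None

    def test_wrong_call_counts_against_both_metrics(self):
        truth = {}
        results = [
            preg("a", FinalCall.HOM_REF, truth, FetalGenotype.HOM_REF),
            preg("b", FinalCall.HOM_REF, truth, FetalGenotype.HET),
        ]
        s = cohort_summary(results, truth)
        assert s["sensitivity_pct"] == 50.0
        assert s["specificity_pct"] == 50.0
        assert s["confusion"][("HET", "HOM_REF")] == 1

    def test_truth_mismatch_rejected(self):
        results = [
            PregnancyResult("x", (), FinalCall.HOM_REF, 1),
        ]
        with pytest.raises(ValueError, match="truth"):
            cohort_summary(results, {})
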
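"""Clinical decision layer: per-sample calls, follow-up logic, cohort metrics.

A sample's posterior probability of fetal homozygosity is turned into a
genotype call with conservative symmetric thresholds (call homozygous
reference when p >= 0.95, heterozygous when p <= 0.05, otherwise no call);
QC-failed samples are never called.  Within a pregnancy, samples are
considered in gestational order and the first conclusive call stands;
inconclusive or failed samples trigger consideration of the next (follow-up)
sample.  Cohort metrics follow the clinical usage: sensitivity is the
fraction of all pregnancies receiving a correct conclusive call, and
specificity the fraction of conclusive calls that are correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .fetal_fraction import SampleQC
from .genotype_model import FetalGenotype, PosteriorSummary


class Call(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    NO_CALL_INTERMEDIATE = "NO_CALL_INTERMEDIATE"
    QC_FAIL = "QC_FAIL"


class FinalCall(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    UNRESOLVED = "UNRESOLVED"


_CONCLUSIVE = {Call.HOM_REF, Call.HET}


class DiscordantCallsError(ValueError):
    """Two samples of one pregnancy produced opposite conclusive calls."""


@dataclass(frozen=True)
class CallThresholds:
    """Posterior-probability call thresholds (inclusive comparisons)."""

    p_hom_call: float = 0.95
    p_het_call: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.p_het_call < self.p_hom_call < 1.0:
            raise ValueError("need 0 < p_het_call < p_hom_call < 1")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    call: Call
    p_hom: float | None
    f_hat: float | None = None
    gestation_weeks: float | None = None
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class PregnancyResult:
    pregnancy_id: str
    sample_calls: tuple[GenotypeCall, ...]
    final_call: FinalCall
    n_samples_used: int


def call_genotype(
    post: PosteriorSummary | None,
    qc: SampleQC,
    thr: CallThresholds | None = None,
    sample_id: str = "",
    f_hat: float | None = None,
    gestation_weeks: float | None = None,
) -> GenotypeCall:
    """Threshold the posterior into a call; QC failure pre-empts calling."""
    thr = thr or CallThresholds()
    if not qc.passed:
        return GenotypeCall(
            sample_id=sample_id,
            call=Call.QC_FAIL,
            p_hom=None if post is None else post.p_hom,
            f_hat=f_hat,
            gestation_weeks=gestation_weeks,
            reasons=tuple(r.value for r in qc.reasons),
        )
    if post is None:
        raise ValueError("posterior required for a QC-passing sample")
    if post.p_hom >= thr.p_hom_call:
        call = Call.HOM_REF
    elif post.p_hom <= thr.p_het_call:
        call = Call.HET
    else:
        call = Call.NO_CALL_INTERMEDIATE
    return GenotypeCall(
        sample_id=sample_id,
        call=call,
        p_hom=post.p_hom,
        f_hat=f_hat,
        gestation_weeks=gestation_weeks,
    )


def evaluate_pregnancy(
    pregnancy_id: str, calls: Sequence[GenotypeCall]
) -> PregnancyResult:
    """Resolve a pregnancy from its samples in gestational order.

    The first conclusive sample fixes the final call; earlier QC failures or
    intermediate probabilities mean the next (follow-up) sample is consulted.
    Samples with unknown gestational age sort last, with a warning.  Opposite
    conclusive calls within one pregnancy raise
    :class:`DiscordantCallsError` — observed cohorts show complete
    within-pregnancy concordance, so discordance indicates an assay or
    labelling problem rather than biology.
    """
    if not calls:
        raise ValueError("a pregnancy needs at least one sample")
    if any(c.gestation_weeks is None for c in calls) and len(calls) > 1:
        warnings.warn(
            f"pregnancy {pregnancy_id}: samples with unknown gestational age "
            "sort after dated samples",
            stacklevel=2,
        )
    ordered = sorted(
        calls,
        key=lambda c: (c.gestation_weeks is None, c.gestation_weeks or 0.0),
    )
    conclusive = [c for c in ordered if c.call in _CONCLUSIVE]
    if len({c.call for c in conclusive}) > 1:
        raise DiscordantCallsError(
            f"pregnancy {pregnancy_id}: conflicting conclusive calls "
            f"{[c.call.value for c in conclusive]}"
        )
    final = FinalCall.UNRESOLVED
    n_used = len(ordered)
    for i, c in enumerate(ordered):
        if c.call in _CONCLUSIVE:
            final = FinalCall(c.call.value)
            n_used = i + 1
            break
    return PregnancyResult(
        pregnancy_id=pregnancy_id,
        sample_calls=tuple(ordered),
        final_call=final,
        n_samples_used=n_used,
    )


def cohort_summary(
    results: Sequence[PregnancyResult],
    truth: Mapping[str, FetalGenotype],
) -> dict:
    """Cohort-level diagnostic performance against confirmed genotypes.

    sensitivity (%): correct conclusive calls / all pregnancies — the
    diagnostic yield times correctness, i.e. the share of pregnancies the
    test resolved correctly.
    specificity (%): correct conclusive calls / conclusive calls (``None``
    when nothing was called).  The full confusion table is returned so other
    definitions can be computed.
    """
    missing = [r.pregnancy_id for r in results if r.pregnancy_id not in truth]
    if missing:
        raise ValueError(f"no truth genotype for pregnancies: {missing}")
    n_total = len(results)
    confusion = {
        (t.value, c.value): 0
        for t in FetalGenotype
        for c in FinalCall
    }
    n_called = n_correct = 0
    for r in results:
        t = truth[r.pregnancy_id]
        confusion[(t.value, r.final_call.value)] += 1
        if r.final_call is not FinalCall.UNRESOLVED:
            n_called += 1
            if r.final_call.value == t.value:
                n_correct += 1
    sensitivity = 100.0 * n_correct / n_total if n_total else None
    specificity = 100.0 * n_correct / n_called if n_called else None
    return {
        "n_total": n_total,
        "n_called": n_called,
        "n_correct": n_correct,
        "sensitivity_pct": sensitivity,
        "specificity_pct": specificity,
        "concordance_pct": specificity,
        "confusion": confusion,
    }
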
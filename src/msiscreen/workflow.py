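"""Screening decision logic: borderline repeat policy and adjudication.

A primary MSI score in the borderline zone [-5, +5] triggers repeat
testing on a freshly collected sample. The screening policy treats
borderline results that cannot be repeated, or that remain borderline on
repeat, as MSI-H: in a surveillance setting the sensitive resolution is
preferred, since urine cfDNA may carry less tumour signal than tissue and
a missed cancer costs more than a triggered work-up.

Calls are adjudicated against the reference standard: histological
confirmation for positives, and at least 12 months of cancer-free follow-up
for negatives; negatives with shorter follow-up are unevaluable and are
excluded from the accuracy contingency.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .diagnostics import ContingencyTable
from .scoring import Call, ClassifierModel, MSIScoreResult, score_sample
from .simulate import simulate_sample
from .types import CaseRecord, MarkerDef, SampleType

MIN_FOLLOWUP_DAYS = 365


class ResolutionPath(str, enum.Enum):
    CLEAR_PRIMARY = "clear_primary"
    REPEAT_CONFIRMED = "repeat_confirmed"
    BORDERLINE_AS_MSIH_NO_REPEAT = "borderline_as_msih_no_repeat"
    BORDERLINE_AS_MSIH_PERSISTENT = "borderline_as_msih_persistent"
    STRICT_PRIMARY = "strict_primary"  # sign-only policy, no borderline logic


class Adjudication(str, enum.Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"
    UNEVALUABLE = "unevaluable"


class RepeatPolicy(str, enum.Enum):
    """How borderline primaries are resolved.

    ``BORDERLINE_AS_MSIH``: repeat when possible; unresolved borderlines
    count as MSI-H (the screening policy). ``STRICT``: the primary score's
    sign is final and the borderline zone is ignored.
    """

    BORDERLINE_AS_MSIH = "borderline_as_msih"
    STRICT = "strict"


@dataclass
class FinalCall:
    subject_id: str
    primary_result: MSIScoreResult
    repeat_result: Optional[MSIScoreResult]
    resolved_call: Call
    resolution_path: ResolutionPath


def resolve_call(
    primary: MSIScoreResult,
    repeat: Optional[MSIScoreResult] = None,
    *,
    subject_id: str = "",
) -> FinalCall:
    """Apply the borderline repeat policy to a primary (and repeat) result.

    A non-borderline primary stands. A borderline primary is overridden by
    a non-borderline repeat; if no repeat is available, or the repeat is
    itself borderline, the resolved call is MSI-H.
    """
    if primary.call is None:
        raise ValueError("primary result has no call (QC failure)")
    if repeat is not None and not primary.borderline:
        raise ValueError("repeat supplied for a non-borderline primary")
    if not primary.borderline:
        return FinalCall(
            subject_id, primary, None, primary.call, ResolutionPath.CLEAR_PRIMARY
        )
    if repeat is None or repeat.call is None:
        return FinalCall(
            subject_id,
            primary,
            None,
            Call.MSI_H,
            ResolutionPath.BORDERLINE_AS_MSIH_NO_REPEAT,
        )
    if repeat.borderline:
        return FinalCall(
            subject_id,
            primary,
            repeat,
            Call.MSI_H,
            ResolutionPath.BORDERLINE_AS_MSIH_PERSISTENT,
        )
    return FinalCall(
        subject_id, primary, repeat, repeat.call, ResolutionPath.REPEAT_CONFIRMED
    )


def adjudicate(case: CaseRecord, final: FinalCall) -> Adjudication:
    """Compare a resolved call with the reference standard.

    A positive call needs a known outcome (histology) to count as TP/FP.
    A negative call needs either a confirmed cancer (FN) or a cancer-free
    follow-up of at least 12 months (TN); anything less is unevaluable.
    """
    outcome = case.outcome_cancer_within_followup
    if final.resolved_call is Call.MSI_H:
        if outcome is None:
            return Adjudication.UNEVALUABLE
        return Adjudication.TP if outcome else Adjudication.FP
    if outcome:
        return Adjudication.FN
    if outcome is False and case.followup_days >= MIN_FOLLOWUP_DAYS:
        return Adjudication.TN
    return Adjudication.UNEVALUABLE


@dataclass
class SubjectOutcome:
    subject_id: str
    final: FinalCall
    adjudication: Adjudication


@dataclass
class ScreeningReport:
    outcomes: list[SubjectOutcome]
    contingency: ContingencyTable
    unevaluable: int
    policy: RepeatPolicy
    seed: Optional[int] = None

    def timeline_rows(self) -> list[dict]:
        """Per-subject flat rows (subject, score, call, path, adjudication)."""
        rows = []
        for o in self.outcomes:
            rows.append(
                {
                    "subject_id": o.subject_id,
                    "msi_score": o.final.primary_result.msi_score,
                    "repeat_score": (
                        o.final.repeat_result.msi_score
                        if o.final.repeat_result
                        else None
                    ),
                    "resolved_call": o.final.resolved_call.value,
                    "resolution_path": o.final.resolution_path.value,
                    "adjudication": o.adjudication.value,
                }
            )
        return rows


def _simulated_repeat(
    case: CaseRecord,
    panel: Sequence[MarkerDef],
    model: ClassifierModel,
    seed: int,
) -> Optional[MSIScoreResult]:
    """Fresh draw at the subject's tumour fraction (re-collection, not
    re-sequencing). Only possible for synthetic cases carrying truth."""
    primary = case.primary_sample()
    if primary.true_tumour_fraction is None:
        return None
    repeat = simulate_sample(
        panel,
        primary.true_tumour_fraction,
        sum(s.depth for s in primary.spectra.values()) // len(primary.spectra),
        SampleType.URINE,
        seed,
        sample_id=f"{primary.sample_id}_repeat",
        subject_id=case.subject_id,
        collection_day=primary.collection_day + 14,
        marker_instability=case.marker_instability,
    )
    return score_sample(model, repeat)


def run_screen(
    cohort: Sequence[CaseRecord],
    model: ClassifierModel,
    *,
    policy: RepeatPolicy = RepeatPolicy.BORDERLINE_AS_MSIH,
    panel: Optional[Sequence[MarkerDef]] = None,
    allow_repeat: bool = True,
    seed: int = 0,
) -> ScreeningReport:
    """Score a cohort's primary urine samples and adjudicate final calls.

    Under the default policy, a borderline primary triggers a simulated
    repeat collection when ``allow_repeat`` is set and the case carries
    synthetic truth (otherwise the borderline is resolved MSI-H directly).
    QC-failed primaries (no call) are recorded as unevaluable.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    policy = RepeatPolicy(policy)
    outcomes: list[SubjectOutcome] = []
    counts = {a: 0 for a in Adjudication}
    for i, case in enumerate(cohort):
        primary_result = score_sample(model, case.primary_sample())
        if primary_result.call is None:
            final = FinalCall(
                case.subject_id,
                primary_result,
                None,
                Call.MSS,
                ResolutionPath.CLEAR_PRIMARY,
            )
            adj = Adjudication.UNEVALUABLE
            outcomes.append(SubjectOutcome(case.subject_id, final, adj))
            counts[adj] += 1
            continue
        if policy is RepeatPolicy.STRICT:
            final = FinalCall(
                case.subject_id,
                primary_result,
                None,
                primary_result.call,
                ResolutionPath.STRICT_PRIMARY,
            )
        else:
            repeat_result = None
            if primary_result.borderline and allow_repeat and panel is not None:
                rep_seed = int(
                    np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0]
                    >> 1
                )
                repeat_result = _simulated_repeat(case, panel, model, rep_seed)
            final = resolve_call(
                primary_result, repeat_result, subject_id=case.subject_id
            )
        adj = adjudicate(case, final)
        outcomes.append(SubjectOutcome(case.subject_id, final, adj))
        counts[adj] += 1
    contingency = ContingencyTable(
        tp=counts[Adjudication.TP],
        fp=counts[Adjudication.FP],
        fn=counts[Adjudication.FN],
        tn=counts[Adjudication.TN],
    )
    return ScreeningReport(
        outcomes=outcomes,
        contingency=contingency,
        unevaluable=counts[Adjudication.UNEVALUABLE],
        policy=policy,
        seed=seed,
    )
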
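"""Naive-Bayes MSI classifier over per-marker variant allele frequencies.

Each marker contributes a log10 likelihood ratio
``log10 f_MSI-H(vaf) / f_MSS(vaf)`` where the class-conditional densities
are Beta distributions on [0, 1] fitted by the method of moments from
labelled training profiles. Marker independence is assumed, so the sample
evidence is the sum of marker log ratios; a single positive multiplier
(``score_scale``) maps the raw sum onto the reporting scale, calibrated so
the central mass of training scores spans approximately [-25, +30].
Scores >= 0 are called MSI-H, < 0 MSS; scores in [-5, +5] are flagged
borderline and trigger repeat testing in the screening workflow.

Both densities are floored at a small pseudocount before the ratio is
taken, so a VAF far outside either class's support yields a large but
finite contribution.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import AlleleSpectrum, MarkerDef, SampleProfile

BORDERLINE_LOW = -5.0
BORDERLINE_HIGH = 5.0

DEFAULT_PSEUDOCOUNT = 1e-6
DEFAULT_QC_MIN_DEPTH = 100
DEFAULT_QC_MIN_MARKERS = 10

#: Reporting range the score scale is calibrated to.
SCORE_RANGE = (-25.0, 30.0)
#: Training-score percentiles mapped into SCORE_RANGE.
CALIBRATION_PERCENTILES = (1.0, 99.0)

# VAFs are clipped into the open unit interval before density evaluation.
_VAF_EPS = 1e-9
# Variance floor for the method-of-moments fit: training VAFs can be nearly
# constant (deep sequencing of a stable class), which would degenerate the
# Beta fit.
_VAR_FLOOR = 1e-7


class Call(str, enum.Enum):
    MSI_H = "MSI-H"
    MSS = "MSS"


def variant_allele_frequency(spectrum: AlleleSpectrum) -> float:
    """Total frequency of non-reference alleles; errors on zero depth."""
    return spectrum.variant_allele_frequency()


def _fit_beta_moments(
    vafs: np.ndarray, pseudocount: float
) -> tuple[float, float]:
    """Method-of-moments Beta fit with pseudocount shrinkage toward 1/2.

    The pseudocount acts as two phantom observations at VAF 0 and 1,
    keeping the fitted support off the boundary when a class is (nearly)
    pure.
    """
    v = np.clip(np.asarray(vafs, dtype=float), _VAF_EPS, 1.0 - _VAF_EPS)
    n = v.size
    mean = (v.sum() + 0.5 * pseudocount) / (n + pseudocount)
    var = max(float(np.var(v)), _VAR_FLOOR)
    var = min(var, mean * (1.0 - mean) * 0.999)  # Beta feasibility bound
    common = mean * (1.0 - mean) / var - 1.0
    alpha = mean * common
    beta = (1.0 - mean) * common
    return float(alpha), float(beta)


@dataclass(frozen=True)
class MarkerEvidenceModel:
    """Class-conditional Beta densities of one marker's VAF."""

    marker_id: str
    msih_alpha: float
    msih_beta: float
    mss_alpha: float
    mss_beta: float
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        for p in (self.msih_alpha, self.msih_beta, self.mss_alpha, self.mss_beta):
            if not (p > 0 and math.isfinite(p)):
                raise ValueError("Beta shape parameters must be positive finite")

    def msih_density(self, vaf: float) -> float:
        return float(
            stats.beta.pdf(
                np.clip(vaf, _VAF_EPS, 1 - _VAF_EPS), self.msih_alpha, self.msih_beta
            )
        )

    def mss_density(self, vaf: float) -> float:
        return float(
            stats.beta.pdf(
                np.clip(vaf, _VAF_EPS, 1 - _VAF_EPS), self.mss_alpha, self.mss_beta
            )
        )


def marker_log_ratio(model: MarkerEvidenceModel, vaf: float) -> float:
    """log10 likelihood ratio MSI-H vs MSS at the observed VAF.

    Densities are floored at the model pseudocount, so the ratio is always
    finite.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must lie in [0, 1]")
    num = max(model.msih_density(vaf), model.pseudocount)
    den = max(model.mss_density(vaf), model.pseudocount)
    return math.log10(num) - math.log10(den)


@dataclass
class ClassifierModel:
    """Trained panel-wide naive-Bayes MSI scorer."""

    markers: dict[str, MarkerEvidenceModel]
    score_scale: float
    qc_min_depth: int = DEFAULT_QC_MIN_DEPTH
    qc_min_markers: int = DEFAULT_QC_MIN_MARKERS

    def __post_init__(self) -> None:
        if self.score_scale <= 0:
            raise ValueError("score_scale must be > 0")
        if not self.markers:
            raise ValueError("model must cover at least one marker")


@dataclass
class MSIScoreResult:
    """Per-sample scoring output: marker evidence, total score, call, QC."""

    sample_id: str
    per_marker_log_ratio: dict[str, float]
    msi_score: Optional[float]
    call: Optional[Call]
    borderline: bool
    qc_pass: bool
    markers_used: int
    qc_excluded_markers: list[str] = field(default_factory=list)


def classify(msi_score: float) -> tuple[Call, bool]:
    """Categorical call and borderline flag for a score.

    MSI-H iff score >= 0 (a score of exactly 0 is called MSI-H: the
    sensitive tie-break appropriate to screening, and 0 lies inside the
    borderline zone so it triggers repeat testing regardless); borderline
    iff the score lies in the closed interval [-5, +5].
    """
    if not math.isfinite(msi_score):
        raise ValueError("msi_score must be finite")
    call = Call.MSI_H if msi_score >= 0.0 else Call.MSS
    return call, BORDERLINE_LOW <= msi_score <= BORDERLINE_HIGH


def _raw_score(
    markers: dict[str, MarkerEvidenceModel],
    profile: SampleProfile,
    qc_min_depth: int,
) -> tuple[dict[str, float], list[str]]:
    ratios: dict[str, float] = {}
    excluded: list[str] = []
    for marker_id in sorted(set(markers) & set(profile.spectra)):
        spec = profile.spectra[marker_id]
        if spec.depth < qc_min_depth:
            excluded.append(marker_id)
            continue
        ratios[marker_id] = marker_log_ratio(
            markers[marker_id], spec.variant_allele_frequency()
        )
    return ratios, excluded


def score_sample(model: ClassifierModel, profile: SampleProfile) -> MSIScoreResult:
    """Score one profile: summed marker log ratios on the reporting scale.

    Markers below the depth QC threshold are excluded; if fewer than
    ``qc_min_markers`` remain the result is flagged ``qc_pass=False`` (the
    call, if any markers remain, is still reported). With zero usable
    markers no call is made.
    """
    ratios, excluded = _raw_score(model.markers, profile, model.qc_min_depth)
    markers_used = len(ratios)
    if markers_used == 0:
        return MSIScoreResult(
            sample_id=profile.sample_id,
            per_marker_log_ratio={},
            msi_score=None,
            call=None,
            borderline=False,
            qc_pass=False,
            markers_used=0,
            qc_excluded_markers=excluded,
        )
    score = model.score_scale * sum(ratios.values())
    call, borderline = classify(score)
    return MSIScoreResult(
        sample_id=profile.sample_id,
        per_marker_log_ratio=ratios,
        msi_score=score,
        call=call,
        borderline=borderline,
        qc_pass=markers_used >= model.qc_min_markers,
        markers_used=markers_used,
        qc_excluded_markers=excluded,
    )


def train_classifier(
    training: Sequence[tuple[SampleProfile, Call]],
    panel: Sequence[MarkerDef],
    *,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    qc_min_depth: int = DEFAULT_QC_MIN_DEPTH,
    qc_min_markers: int = DEFAULT_QC_MIN_MARKERS,
) -> ClassifierModel:
    """Fit per-marker class-conditional Beta densities and the score scale.

    Requires at least two samples of each class. Markers with no
    depth-passing sample in either class are dropped with a warning. The
    score scale maps the 1st/99th percentiles of raw training scores into
    the reporting range [-25, +30]; a single multiplier cannot pin both
    endpoints, so the binding (smaller) ratio is used and the calibrated
    range is contained within the target range.
    """
    labels = [Call(label) for _, label in training]
    for cls in (Call.MSI_H, Call.MSS):
        if labels.count(cls) < 2:
            raise ValueError(f"need >= 2 training samples of class {cls.value}")

    markers: dict[str, MarkerEvidenceModel] = {}
    for marker in panel:
        class_vafs: dict[Call, list[float]] = {Call.MSI_H: [], Call.MSS: []}
        for (profile, _), label in zip(training, labels):
            spec = profile.spectra.get(marker.marker_id)
            if spec is None or spec.depth < qc_min_depth:
                continue
            class_vafs[label].append(spec.variant_allele_frequency())
        if not class_vafs[Call.MSI_H] or not class_vafs[Call.MSS]:
            import warnings

            warnings.warn(
                f"marker {marker.marker_id} has no passing training sample "
                "in one class; dropped from the model",
                stacklevel=2,
            )
            continue
        a_h, b_h = _fit_beta_moments(np.array(class_vafs[Call.MSI_H]), pseudocount)
        a_s, b_s = _fit_beta_moments(np.array(class_vafs[Call.MSS]), pseudocount)
        markers[marker.marker_id] = MarkerEvidenceModel(
            marker_id=marker.marker_id,
            msih_alpha=a_h,
            msih_beta=b_h,
            mss_alpha=a_s,
            mss_beta=b_s,
            pseudocount=pseudocount,
        )
    if not markers:
        raise ValueError("no marker retained by training")

    raw = np.array(
        [
            sum(_raw_score(markers, profile, qc_min_depth)[0].values())
            for profile, _ in training
        ]
    )
    lo_q, hi_q = np.percentile(raw, CALIBRATION_PERCENTILES)
    lo_t, hi_t = SCORE_RANGE
    candidates = []
    if hi_q > 0:
        candidates.append(hi_t / hi_q)
    if lo_q < 0:
        candidates.append(lo_t / lo_q)  # both negative -> positive ratio
    score_scale = min(candidates) if candidates else 1.0
    return ClassifierModel(
        markers=markers,
        score_scale=float(score_scale),
        qc_min_depth=qc_min_depth,
        qc_min_markers=qc_min_markers,
    )
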
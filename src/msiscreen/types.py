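"""Core data containers shared across the pipeline.

The atomic evidence unit is the :class:`AlleleSpectrum`: a histogram of
sequencing read counts over microsatellite allele lengths, expressed as
signed offsets in nucleotides relative to the reference repeat length
(0 = reference, negative = deletion, positive = insertion). A
:class:`SampleProfile` bundles one spectrum per panel marker for a single
biospecimen; a :class:`CaseRecord` bundles a subject's samples with the
clinical truth/outcome fields needed to adjudicate a screening call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class SampleType(str, enum.Enum):
    URINE = "urine"
    TUMOUR = "tumour"
    PLASMA = "plasma"
    BLOOD = "blood"


class CohortDesign(str, enum.Enum):
    """Study designs: symptomatic tumour/urine pairs vs asymptomatic screening."""

    SYMPTOMATIC_UTUC = "symptomatic_utuc"
    LYNCH_SCREENING = "lynch_screening"


@dataclass(frozen=True)
class MarkerDef:
    """A mononucleotide-repeat marker of the amplicon panel.

    Parameters
    ----------
    marker_id : str
        Panel name, e.g. ``"AKMmono02"``.
    reference_repeat_length : int
        Repeat tract length in nucleotides of the reference allele.
    stutter_rate : float
        Per-read probability of a polymerase-slippage (stutter) artefact,
        i.e. of the read reporting an allele offset != 0 for a stable
        template. Must lie in [0, 0.5).
    mmrd_deletion_mean : float
        Mean somatic deletion size (nt) of the unstable allele component.
    mmrd_deletion_sd : float
        Spread of the somatic deletion size.
    """

    marker_id: str
    reference_repeat_length: int
    stutter_rate: float
    mmrd_deletion_mean: float
    mmrd_deletion_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.reference_repeat_length <= 0:
            raise ValueError("reference_repeat_length must be > 0")
        if not 0.0 <= self.stutter_rate < 0.5:
            raise ValueError("stutter_rate must lie in [0, 0.5)")
        if self.mmrd_deletion_mean <= 0:
            raise ValueError("mmrd_deletion_mean must be > 0")
        if self.mmrd_deletion_sd < 0:
            raise ValueError("mmrd_deletion_sd must be >= 0")


@dataclass
class AlleleSpectrum:
    """Read-count histogram over allele-length offsets for one marker."""

    marker_id: str
    counts: dict[int, int]

    def __post_init__(self) -> None:
        for offset, count in self.counts.items():
            if count < 0:
                raise ValueError(
                    f"negative read count {count} at offset {offset} "
                    f"({self.marker_id})"
                )

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[int, float]:
        """Allele frequencies (counts / depth); requires depth > 0."""
        d = self.depth
        if d == 0:
            raise ValueError(f"zero-depth spectrum for {self.marker_id}")
        return {off: c / d for off, c in sorted(self.counts.items())}

    def variant_allele_frequency(self) -> float:
        """Total frequency of non-reference (offset != 0) alleles."""
        d = self.depth
        if d == 0:
            raise ValueError(f"zero-depth spectrum for {self.marker_id}")
        return 1.0 - self.counts.get(0, 0) / d


@dataclass
class SampleProfile:
    """One biospecimen's allele spectra across the marker panel."""

    sample_id: str
    subject_id: str
    sample_type: SampleType
    collection_day: int
    spectra: dict[str, AlleleSpectrum]
    true_tumour_fraction: Optional[float] = None  # synthetic truth only

    def __post_init__(self) -> None:
        for marker_id, spec in self.spectra.items():
            if spec.marker_id != marker_id:
                raise ValueError(
                    f"spectrum keyed {marker_id} carries marker_id "
                    f"{spec.marker_id}"
                )

    @property
    def marker_ids(self) -> list[str]:
        return sorted(self.spectra)


@dataclass
class CaseRecord:
    """A subject in a cohort, with samples and adjudication truth.

    ``truth_mmrd_cancer`` is the synthetic ground truth (or known clinical
    truth); ``outcome_cancer_within_followup`` is what the reference
    standard established, ``None`` when unknown.
    """

    subject_id: str
    cohort: CohortDesign
    samples: list[SampleProfile] = field(default_factory=list)
    truth_mmrd_cancer: Optional[bool] = None
    outcome_cancer_within_followup: Optional[bool] = None
    followup_days: int = 0
    # Per-marker fraction of tumour-derived molecules carrying the somatic
    # deletion (clonal heterogeneity); shared across a subject's samples so
    # urine and tumour VAF patterns are concordant.
    marker_instability: Optional[dict[str, float]] = None

    def primary_sample(self, sample_type: SampleType = SampleType.URINE) -> SampleProfile:
        """Earliest sample of the given type (the screening index test)."""
        candidates = [s for s in self.samples if s.sample_type == sample_type]
        if not candidates:
            raise ValueError(
                f"case {self.subject_id} has no {sample_type.value} sample"
            )
        return min(candidates, key=lambda s: s.collection_day)
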
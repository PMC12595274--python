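"""Synthetic amplicon allele-spectrum generator.

Emulates the statistical structure of a multiplex-PCR mononucleotide-repeat
MSI assay applied to cell-free DNA: each marker's read histogram is a
multinomial draw from a two-component mixture over allele-length offsets,

    (1 - f) * background  +  f * unstable,

where ``f`` is the tumour fraction of the specimen. The background
component models PCR/sequencing stutter around the reference allele
(per-read slippage with a geometric step count, deletion-biased 3:1,
because mononucleotide stutter is empirically deletion-dominated). The
unstable component places a discretised-normal deletion of several
nucleotides, convolved with the same stutter kernel, and is attenuated by a
per-marker *mutant fraction* — the proportion of tumour molecules actually
carrying the somatic deletion at that marker — which encodes clonal
heterogeneity and gives each tumour a marker-level VAF fingerprint shared
between its tissue and the urine it sheds into.

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence`` spawn keys, so cohorts are reproducible and
independent of generation order.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import (
    AlleleSpectrum,
    CaseRecord,
    CohortDesign,
    MarkerDef,
    SampleProfile,
    SampleType,
)

# Offset window of the simulated histograms (nt relative to reference).
OFFSET_MIN = -15
OFFSET_MAX = 8
OFFSETS = np.arange(OFFSET_MIN, OFFSET_MAX + 1)

# Stutter kernel shape: P(step = k) = p (1-p)^(k-1), deletion:insertion 3:1.
STUTTER_STEP_P = 0.7
STUTTER_DELETION_ODDS = 0.75

#: Default 14-marker mononucleotide panel. Synthetic stand-in for a
#: clinical amplicon panel: marker names follow the field's naming style,
#: repeat lengths and noise parameters span the realistic range for
#: mononucleotide tracts of 20-27 bp.
DEFAULT_PANEL: tuple[MarkerDef, ...] = tuple(
    MarkerDef(name, length, stutter, del_mean)
    for name, length, stutter, del_mean in [
        ("AKMmono01", 22, 0.040, 3.5),
        ("AKMmono02", 24, 0.055, 4.0),
        ("AKMmono03", 20, 0.030, 3.0),
        ("AKMmono04", 25, 0.060, 4.5),
        ("AKMmono05", 23, 0.045, 4.0),
        ("AKMmono06", 21, 0.035, 3.0),
        ("AKMmono07", 26, 0.070, 5.0),
        ("AKMmono08", 22, 0.040, 3.5),
        ("EJmono05", 24, 0.050, 4.0),
        ("EJmono08", 27, 0.080, 5.5),
        ("EJmono10", 21, 0.035, 3.0),
        ("EJmono12", 25, 0.060, 4.5),
        ("EJmono14", 23, 0.045, 4.0),
        ("LRmono03", 22, 0.040, 3.5),
    ]
)

DEFAULT_DEPTH = 2000


def _offset_index(offset: int) -> int:
    return offset - OFFSET_MIN


def background_pmf(marker: MarkerDef) -> np.ndarray:
    """Stutter-only allele pmf over OFFSETS for a stable template."""
    pmf = np.zeros_like(OFFSETS, dtype=float)
    pmf[_offset_index(0)] = 1.0 - marker.stutter_rate
    p = STUTTER_STEP_P
    for k in range(1, max(-OFFSET_MIN, OFFSET_MAX) + 1):
        step = p * (1.0 - p) ** (k - 1)
        if -k >= OFFSET_MIN:
            pmf[_offset_index(-k)] += (
                marker.stutter_rate * STUTTER_DELETION_ODDS * step
            )
        if k <= OFFSET_MAX:
            pmf[_offset_index(k)] += (
                marker.stutter_rate * (1.0 - STUTTER_DELETION_ODDS) * step
            )
    return pmf / pmf.sum()


def _deletion_size_pmf(marker: MarkerDef) -> np.ndarray:
    """Discretised-normal pmf over deletion sizes 1..|OFFSET_MIN| nt."""
    sizes = np.arange(1, -OFFSET_MIN + 1)
    if marker.mmrd_deletion_sd <= 1e-12:
        pmf = np.zeros(sizes.size)
        target = int(np.clip(round(marker.mmrd_deletion_mean), 1, sizes[-1]))
        pmf[target - 1] = 1.0
        return pmf
    z = (sizes - marker.mmrd_deletion_mean) / marker.mmrd_deletion_sd
    pmf = np.exp(-0.5 * z * z)
    return pmf / pmf.sum()


@functools.lru_cache(maxsize=4096)
def _mixture_pmf_cached(
    marker: MarkerDef, tumour_fraction: float, mutant_fraction: float
) -> tuple[float, ...]:
    bg = background_pmf(marker)
    del_sizes = _deletion_size_pmf(marker)  # sizes 1..-OFFSET_MIN
    # Somatic-deletion pmf as offsets -|OFFSET_MIN|..-1, convolved with the
    # stutter kernel (mutant templates stutter too); mass shifted outside
    # the histogram window is dropped and the pmf renormalised.
    full = np.convolve(del_sizes[::-1], bg)  # index t <-> offset 2*OFFSET_MIN + t
    start = OFFSET_MIN - 2 * OFFSET_MIN  # index of OFFSET_MIN
    mutant = np.zeros(OFFSETS.size)
    chunk = full[start : start + OFFSETS.size]
    mutant[: chunk.size] = chunk
    mutant /= mutant.sum()
    unstable = mutant_fraction * mutant + (1.0 - mutant_fraction) * bg
    mix = (1.0 - tumour_fraction) * bg + tumour_fraction * unstable
    return tuple(mix / mix.sum())


def spectrum_pmf(
    marker: MarkerDef,
    tumour_fraction: float,
    mutant_fraction: float = 1.0,
) -> np.ndarray:
    """Analytic allele pmf over OFFSETS for the background/unstable mixture.

    ``mutant_fraction`` attenuates the unstable component: only that
    proportion of tumour-derived molecules carries the somatic deletion,
    the remainder behaving like background.
    """
    if not 0.0 <= tumour_fraction <= 1.0:
        raise ValueError("tumour_fraction must lie in [0, 1]")
    if not 0.0 <= mutant_fraction <= 1.0:
        raise ValueError("mutant_fraction must lie in [0, 1]")
    return np.array(
        _mixture_pmf_cached(marker, float(tumour_fraction), float(mutant_fraction))
    )


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def simulate_spectrum(
    marker: MarkerDef,
    tumour_fraction: float,
    depth: int,
    rng_seed,
    mutant_fraction: float = 1.0,
) -> AlleleSpectrum:
    """Draw one marker's read histogram: Multinomial(depth, mixture pmf)."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    pmf = spectrum_pmf(marker, tumour_fraction, mutant_fraction)
    counts = _rng(rng_seed).multinomial(depth, pmf)
    return AlleleSpectrum(
        marker_id=marker.marker_id,
        counts={int(o): int(c) for o, c in zip(OFFSETS, counts) if c > 0},
    )


def simulate_sample(
    panel: Sequence[MarkerDef],
    tumour_fraction: float,
    depth: int,
    sample_type: SampleType,
    seed,
    *,
    sample_id: str = "S1",
    subject_id: str = "subject1",
    collection_day: int = 0,
    marker_instability: Optional[dict[str, float]] = None,
) -> SampleProfile:
    """Simulate one biospecimen: independent spectra for every panel marker.

    Each marker draws from its own counter-based substream
    (``SeedSequence(seed, spawn_key=(marker_index,))`` with markers taken
    in sorted-id order), so profiles are reproducible and independent of
    panel ordering.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    ids = [m.marker_id for m in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker_ids in panel")
    spectra: dict[str, AlleleSpectrum] = {}
    for i, marker in enumerate(sorted(panel, key=lambda m: m.marker_id)):
        sub = np.random.SeedSequence(seed, spawn_key=(i,))
        m_frac = 1.0
        if marker_instability is not None:
            m_frac = marker_instability.get(marker.marker_id, 1.0)
        spectra[marker.marker_id] = simulate_spectrum(
            marker, tumour_fraction, depth, sub, mutant_fraction=m_frac
        )
    return SampleProfile(
        sample_id=sample_id,
        subject_id=subject_id,
        sample_type=sample_type,
        collection_day=collection_day,
        spectra=spectra,
        true_tumour_fraction=tumour_fraction,
    )


@dataclass(frozen=True)
class TumourFractionDist:
    """Parametric tumour-fraction distribution for urine cfDNA.

    Default is log-uniform on [0.01, 0.5]: urine tumour content spans
    orders of magnitude and is bounded well below tissue.
    """

    family: str = "log_uniform"
    low: float = 0.01
    high: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in ("log_uniform", "uniform", "fixed"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 0.0 <= self.low <= self.high <= 1.0:
            raise ValueError("require 0 <= low <= high <= 1")
        if self.family == "log_uniform" and self.low <= 0.0:
            raise ValueError("log_uniform requires low > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.low
        if self.family == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(
            math.exp(rng.uniform(math.log(self.low), math.log(self.high)))
        )


# Tissue specimens are required to have substantial tumour content
# (histopathology-confirmed), so tumour tissue draws Uniform(0.4, 0.9).
TUMOUR_TISSUE_TF = (0.4, 0.9)

# Range of the per-marker mutant fraction for an unstable tumour: clonal
# heterogeneity attenuates each marker's signal by a subject-specific factor.
MUTANT_FRACTION_RANGE = (0.3, 1.0)


@dataclass
class CohortConfig:
    """Configuration of a simulated study cohort.

    Exactly one of the design-specific parameter sets must be given:
    ``mmrd_prevalence`` for the symptomatic tumour/urine-pair design, or
    ``annual_incidence`` + ``lead_time_years`` for asymptomatic screening
    (per-subject disease probability compounds geometrically,
    ``1 - (1 - incidence)^lead``).
    """

    n_subjects: int
    design: CohortDesign
    mmrd_prevalence: Optional[float] = None
    annual_incidence: Optional[float] = None
    lead_time_years: Optional[float] = None
    tumour_fraction_distribution: TumourFractionDist = field(
        default_factory=TumourFractionDist
    )
    depth_per_marker: int = DEFAULT_DEPTH
    followup_days: int = 540
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        self.design = CohortDesign(self.design)
        if self.design is CohortDesign.SYMPTOMATIC_UTUC:
            if self.mmrd_prevalence is None or (
                self.annual_incidence is not None
                or self.lead_time_years is not None
            ):
                raise ValueError(
                    "symptomatic_utuc design requires mmrd_prevalence only"
                )
        else:
            if (
                self.annual_incidence is None
                or self.lead_time_years is None
                or self.mmrd_prevalence is not None
            ):
                raise ValueError(
                    "lynch_screening design requires annual_incidence and "
                    "lead_time_years only"
                )

    @property
    def disease_probability(self) -> float:
        if self.design is CohortDesign.SYMPTOMATIC_UTUC:
            return float(self.mmrd_prevalence)
        return 1.0 - (1.0 - self.annual_incidence) ** self.lead_time_years


def draw_marker_instability(
    panel: Sequence[MarkerDef], rng: np.random.Generator
) -> dict[str, float]:
    """Subject-specific per-marker mutant fractions (clonal fingerprint)."""
    lo, hi = MUTANT_FRACTION_RANGE
    return {
        m.marker_id: float(rng.uniform(lo, hi))
        for m in sorted(panel, key=lambda x: x.marker_id)
    }


def simulate_case(
    subject_id: str,
    design: CohortDesign,
    affected: bool,
    panel: Sequence[MarkerDef],
    seed,
    *,
    urine_tumour_fraction: float = 0.0,
    tumour_tissue_fraction: float = 0.0,
    depth: int = DEFAULT_DEPTH,
    followup_days: int = 540,
    marker_instability: Optional[dict[str, float]] = None,
) -> CaseRecord:
    """Build one subject's CaseRecord with simulated samples.

    An affected subject in the symptomatic design contributes a tumour and
    a pre-operative urine; the screening design contributes urine only.
    """
    ss = np.random.SeedSequence(seed)
    urine_seed, tumour_seed = (int(s) for s in ss.generate_state(2) >> 1)
    samples = [
        simulate_sample(
            panel,
            urine_tumour_fraction if affected else 0.0,
            depth,
            SampleType.URINE,
            urine_seed,
            sample_id=f"{subject_id}_U0",
            subject_id=subject_id,
            collection_day=0,
            marker_instability=marker_instability if affected else None,
        )
    ]
    if design is CohortDesign.SYMPTOMATIC_UTUC:
        samples.append(
            simulate_sample(
                panel,
                tumour_tissue_fraction if affected else 0.0,
                depth,
                SampleType.TUMOUR,
                tumour_seed,
                sample_id=f"{subject_id}_T0",
                subject_id=subject_id,
                collection_day=0,
                marker_instability=marker_instability if affected else None,
            )
        )
    return CaseRecord(
        subject_id=subject_id,
        cohort=design,
        samples=samples,
        truth_mmrd_cancer=affected,
        outcome_cancer_within_followup=affected,
        followup_days=followup_days,
        marker_instability=marker_instability if affected else None,
    )


def simulate_cohort(
    config: CohortConfig, panel: Sequence[MarkerDef] = DEFAULT_PANEL
) -> list[CaseRecord]:
    """Simulate a full study cohort under the configured design.

    Each subject draws from its own ``SeedSequence(seed, spawn_key=(i,))``
    substream; the same config therefore yields an identical cohort
    regardless of evaluation order.
    """
    p_disease = config.disease_probability
    cases: list[CaseRecord] = []
    for i in range(config.n_subjects):
        sub_ss = np.random.SeedSequence(config.seed, spawn_key=(i,))
        rng = _rng(sub_ss)
        affected = bool(rng.uniform() < p_disease)
        urine_tf = 0.0
        tissue_tf = 0.0
        instability = None
        if affected:
            urine_tf = config.tumour_fraction_distribution.sample(rng)
            tissue_tf = float(rng.uniform(*TUMOUR_TISSUE_TF))
            instability = draw_marker_instability(panel, rng)
        case_seed = int(rng.integers(0, 2**31 - 1))
        cases.append(
            simulate_case(
                f"subj{i:04d}",
                config.design,
                affected,
                panel,
                case_seed,
                urine_tumour_fraction=urine_tf,
                tumour_tissue_fraction=tissue_tf,
                depth=config.depth_per_marker,
                followup_days=config.followup_days,
                marker_instability=instability,
            )
        )
    return cases


def simulate_training_set(
    n_per_class: int,
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
    panel: Sequence[MarkerDef] = DEFAULT_PANEL,
    tf_dist: Optional[TumourFractionDist] = None,
) -> list[tuple[SampleProfile, str]]:
    """Labelled training profiles for classifier fitting.

    Unstable samples draw urine-range tumour fractions floored at a clearly
    detectable 0.1 (log-uniform up to 0.9, spanning urine cfDNA to tissue),
    each with its own clonal marker fingerprint; stable samples have tumour
    fraction 0. Labels are the strings "MSI-H"/"MSS".
    """
    rng = _rng(seed)
    if tf_dist is None:
        tf_dist = TumourFractionDist("log_uniform", 0.1, 0.9)
    training: list[tuple[SampleProfile, str]] = []
    for i in range(n_per_class):
        tf = tf_dist.sample(rng)
        instability = draw_marker_instability(panel, rng)
        pos = simulate_sample(
            panel,
            tf,
            depth,
            SampleType.URINE,
            int(rng.integers(0, 2**31 - 1)),
            sample_id=f"train_pos{i}",
            subject_id=f"train_pos{i}",
            marker_instability=instability,
        )
        neg = simulate_sample(
            panel,
            0.0,
            depth,
            SampleType.URINE,
            int(rng.integers(0, 2**31 - 1)),
            sample_id=f"train_neg{i}",
            subject_id=f"train_neg{i}",
        )
        training.append((pos, "MSI-H"))
        training.append((neg, "MSS"))
    return training


_EVENT_KINDS = ("resection", "recurrence", "ablation")


def simulate_longitudinal(
    case: CaseRecord,
    events: Sequence[tuple[int, str]],
    sample_days: Sequence[int],
    panel: Sequence[MarkerDef] = DEFAULT_PANEL,
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
) -> list[SampleProfile]:
    """Urine profiles along a clinical timeline.

    Tumour fraction holds at the case's baseline until a resection or
    ablation (drops to 0) and is restored by a recurrence. Day 0 is the
    first urine analysis.
    """
    days_of_events = [d for d, _ in events]
    if days_of_events != sorted(days_of_events):
        raise ValueError("events must be sorted by day")
    for _, kind in events:
        if kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
    baseline = case.primary_sample().true_tumour_fraction or 0.0
    profiles = []
    for j, day in enumerate(sample_days):
        tf = baseline
        for event_day, kind in events:
            if event_day > day:
                break
            tf = 0.0 if kind in ("resection", "ablation") else baseline
        day_seed = int(
            np.random.SeedSequence(seed, spawn_key=(j,)).generate_state(1)[0] >> 1
        )
        profiles.append(
            simulate_sample(
                panel,
                tf,
                depth,
                SampleType.URINE,
                day_seed,
                sample_id=f"{case.subject_id}_D{day}",
                subject_id=case.subject_id,
                collection_day=day,
                marker_instability=case.marker_instability if tf > 0 else None,
            )
        )
    return profiles
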
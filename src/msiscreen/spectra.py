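"""Background-normalised allele spectra and urine-tumour VAF concordance.

Microsatellite amplicons carry systematic stutter error, so a sample's
allele spectrum is interpreted relative to a matched background specimen
(typically blood or plasma cfDNA, assumed tumour-free): per allele offset,
the background frequency is subtracted from the sample frequency. The
resulting signed deltas highlight the somatically shifted alleles.

Per-marker variant allele frequencies form a fingerprint of a tumour's
clonal composition. Correlating the VAF vectors of a urine sample and a
candidate tumour across the panel attributes the urine MSI signal to (or
away from) that tumour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .types import AlleleSpectrum, SampleProfile

MIN_CONCORDANCE_MARKERS = 3


@dataclass
class NormalizedSpectrum:
    """Per-offset frequency differences, sample minus reference."""

    marker_id: str
    delta_frequency: dict[int, float]


@dataclass
class ConcordanceResult:
    """Cross-sample correlation of per-marker VAFs."""

    sample_pair: tuple[str, str]
    per_marker_vaf_pairs: list[tuple[float, float]]
    correlation: Optional[float]
    n_markers: int
    method: str = "pearson"
    reason: Optional[str] = None  # set when correlation is undefined


def normalize_spectrum(
    sample: AlleleSpectrum, reference: AlleleSpectrum
) -> NormalizedSpectrum:
    """Subtract background allele frequencies, offset by offset.

    Differences are taken over the union of offsets observed in either
    spectrum (missing offsets count as frequency 0) and are kept signed:
    a negative delta at the reference offset is the depletion that
    balances the somatic gain elsewhere.
    """
    if sample.marker_id != reference.marker_id:
        raise ValueError(
            f"marker mismatch: {sample.marker_id} vs {reference.marker_id}"
        )
    f_sample = sample.frequencies()
    f_ref = reference.frequencies()
    offsets = sorted(set(f_sample) | set(f_ref))
    return NormalizedSpectrum(
        marker_id=sample.marker_id,
        delta_frequency={
            off: f_sample.get(off, 0.0) - f_ref.get(off, 0.0) for off in offsets
        },
    )


def _profile_vafs(
    profile: SampleProfile,
    reference: Optional[SampleProfile],
    min_depth: int,
) -> dict[str, float]:
    vafs: dict[str, float] = {}
    for marker_id, spec in profile.spectra.items():
        if spec.depth < min_depth:
            continue
        v = spec.variant_allele_frequency()
        if reference is not None:
            ref_spec = reference.spectra.get(marker_id)
            if ref_spec is None or ref_spec.depth < min_depth:
                continue
            v -= ref_spec.variant_allele_frequency()
        vafs[marker_id] = v
    return vafs


def vaf_concordance(
    profile_a: SampleProfile,
    profile_b: SampleProfile,
    *,
    method: str = "pearson",
    reference_a: Optional[SampleProfile] = None,
    reference_b: Optional[SampleProfile] = None,
    min_depth: int = 100,
) -> ConcordanceResult:
    """Correlation of per-marker VAFs between two profiles.

    When a matched background profile (blood/plasma cfDNA) is supplied for
    a side, that side's VAFs are background-subtracted first. The
    correlation is undefined (``correlation=None`` with a reason) with
    fewer than three shared passing markers or a constant VAF vector.
    ``method`` is ``"pearson"`` (default) or ``"spearman"`` for a
    rank-based alternative.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    vafs_a = _profile_vafs(profile_a, reference_a, min_depth)
    vafs_b = _profile_vafs(profile_b, reference_b, min_depth)
    shared = sorted(set(vafs_a) & set(vafs_b))
    pairs = [(vafs_a[m], vafs_b[m]) for m in shared]
    result = ConcordanceResult(
        sample_pair=(profile_a.sample_id, profile_b.sample_id),
        per_marker_vaf_pairs=pairs,
        correlation=None,
        n_markers=len(shared),
        method=method,
    )
    if len(shared) < MIN_CONCORDANCE_MARKERS:
        result.reason = f"only {len(shared)} shared passing markers (need >= 3)"
        return result
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        result.reason = "constant VAF vector"
        return result
    if method == "pearson":
        r = stats.pearsonr(xs, ys).statistic
    else:
        r = stats.spearmanr(xs, ys).statistic
    result.correlation = float(r)
    return result


def plot_normalized_spectra(
    rows: dict[str, dict[str, NormalizedSpectrum]],
    path,
    marker_order: Optional[list[str]] = None,
):
    """Small-multiples plot of normalised spectra: one row per sample, one
    column per marker, bars of signed delta-frequency over allele offset.

    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sample_ids = list(rows)
    markers = marker_order or sorted({m for r in rows.values() for m in r})
    fig, axes = plt.subplots(
        len(sample_ids), len(markers),
        figsize=(2.0 * len(markers), 1.4 * len(sample_ids)),
        squeeze=False, sharey=True,
    )
    for i, sid in enumerate(sample_ids):
        for j, mid in enumerate(markers):
            ax = axes[i][j]
            norm = rows[sid].get(mid)
            if norm is not None:
                offsets = sorted(norm.delta_frequency)
                ax.bar(offsets, [norm.delta_frequency[o] for o in offsets],
                       width=0.8, color="steelblue")
            ax.axvline(0, color="red", linewidth=0.6)
            if i == 0:
                ax.set_title(mid, fontsize=7)
            if j == len(markers) - 1:
                ax.yaxis.set_label_position("right")
                ax.set_ylabel(sid, fontsize=7, rotation=270, labelpad=10)
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
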
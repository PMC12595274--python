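# Methods

## Problem setting

Mismatch-repair-deficient (MMRd) tumours accumulate insertion/deletion
variants in microsatellites (microsatellite instability, MSI). Urothelial
carcinoma arising in Lynch syndrome is almost always MMRd, and tumour DNA
is shed into voided urine as cell-free DNA (ucfDNA). `msiscreen` models a
screening assay that reads the allele-length distributions of a panel of
14 mononucleotide-repeat amplicons from ucfDNA, scores each sample with a
naive-Bayes classifier, and evaluates the resulting screen with exact
binomial statistics. Because the package is developed and tested without
access to patient sequence data, a synthetic generator reproduces the
statistical structure of the assay's evidence, and every downstream stage
is exercised against it.

## Allele-spectrum model

The atomic observation is a histogram of read counts over allele-length
offsets (nucleotides relative to the reference repeat; 0 = reference,
negative = deletion). A specimen with tumour fraction *f* draws its reads
from the mixture

    p(offset) = (1 - f) * p_bg(offset) + f * p_unstable(offset).

**Background (stutter).** PCR slippage on mononucleotide tracts produces
spurious ±k alleles. Each read stutters with per-marker probability
`stutter_rate` (panel defaults 0.03–0.08); the step count is geometric
(step parameter 0.7) and the direction deletion-biased 3:1, reflecting the
empirical deletion dominance of mononucleotide stutter. The histogram
window is [-15, +8] nt; truncated tail mass (≈1e-6 relative) is
renormalised.

**Unstable component.** The somatic allele is a deletion whose size is a
discretised normal (per-marker mean 3–5.5 nt, sd 1.5), convolved with the
same stutter kernel — mutant templates stutter too. Each affected subject
additionally carries a per-marker *mutant fraction* drawn Uniform(0.3, 1):
the proportion of tumour-derived molecules at that marker that actually
harbour the deletion. This encodes clonal heterogeneity, and because the
pattern is shared between a subject's tumour and urine it is what makes
per-marker VAF fingerprints informative for source attribution. Without
it, every marker would shift by the same amount and cross-sample VAF
correlation would be degenerate.

Counts are a single multinomial draw of `depth` reads (default 2,000 per
marker; the assay itself is not depth-limited in any way we model, so
depth is a free parameter). The analytic mixture pmf is exposed
(`spectrum_pmf`) and the simulator samples from it exactly, so tests can
compare empirical frequencies against direct enumeration.

**Tumour-fraction regimes.** Urine cfDNA tumour content is unmeasured in
the motivating study; we take it log-uniform on [0.01, 0.5] as the default
screening condition (orders-of-magnitude spread, bounded below tissue).
Tumour tissue draws Uniform(0.4, 0.9) — tissue specimens require
histologically confirmed substantial tumour content. Blood/plasma cfDNA is
modelled as tumour fraction ≈ 0, i.e. pure background. These are design
choices for a plausible operating regime, not estimates of any dataset;
sensitivity to them can be probed by passing a different
`TumourFractionDist`.

## Seeding discipline

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawn keys: one substream per subject, one per
marker within a sample (markers in sorted-id order). Cohorts are therefore
bit-reproducible and independent of generation order.

## Naive-Bayes MSI score

Per marker, the evidence is the variant allele frequency (VAF): the total
frequency of non-reference offsets. Class-conditional VAF densities under
MSI-H and MSS are Beta distributions fitted by the method of moments, with
a small pseudocount acting as phantom boundary observations and a variance
floor (1e-7) guarding degenerate (near-constant) training VAFs. The
marker's contribution is the log10 likelihood ratio, with both densities
floored at the pseudocount (1e-6) so the ratio is always finite. Marker
independence is assumed; contributions add. Equal class priors are used,
so the score is a pure summed log-likelihood ratio.

**Scale calibration.** A single positive multiplier maps raw summed
ratios onto the reporting scale. It is chosen so the 1st–99th percentile
of training scores lands inside [-25, +30]; one multiplier cannot pin both
endpoints, so the binding (smaller) of the two one-sided ratios is used
and the calibrated range is contained in, rather than equal to, the
reporting range.

**Calls.** Score ≥ 0 → MSI-H, < 0 → MSS; exactly 0 is called MSI-H (the
sensitive tie-break appropriate to screening — and 0 lies inside the
borderline zone, so it triggers repeat testing regardless). Scores in the
closed interval [-5, +5] are borderline. QC: markers need ≥ 100 reads to
contribute; a result with < 10 of 14 usable markers is flagged (call still
reported); zero usable markers yields no call.

**Saturation.** The density floor deliberately caps per-marker evidence.
A consequence is that expected score is monotone in tumour fraction only
up to a saturation plateau: once a sample's VAFs sit far outside the MSS
density's support at every marker, the MSS side of every ratio is floored
and the score tracks the MSI-H density alone, which declines past its
mode. At the panel defaults the plateau begins around tumour fraction
0.2 and the mean score stays within a few percent of the plateau top
thereafter. Monotonicity is therefore asserted on the rising regime plus
plateau stability, at assay operating conditions (depth 2,000,
cohort-mean mutant fraction 0.65).

## Background normalisation and source attribution

For spectra interpretation, a matched background specimen (blood or plasma
cfDNA, assumed tumour-free) defines the error baseline: per offset, its
frequency is subtracted from the sample's, over the union of observed
offsets, signed values retained (the depletion at offset 0 balances the
somatic gain). Normalisation is antisymmetric by construction.

Source attribution correlates per-marker VAF vectors between a urine
sample and a candidate tumour (Pearson by default; Spearman available).
When a matched background profile is supplied, VAFs are
background-subtracted first. The correlation is reported as a single
descriptive statistic per pair — no p-value and no per-marker multiplicity
correction, matching the qualitative use of the comparison. It is
undefined (with a recorded reason) below three shared passing markers or
for a constant vector.

## Screening workflow

Borderline primaries trigger repeat testing on a freshly collected sample
(simulated as a fresh draw at the same tumour fraction — re-collection,
not re-sequencing). A clear repeat stands; an absent or still-borderline
repeat resolves to MSI-H. The alternative `STRICT` policy (sign-only, no
borderline logic) exists for policy comparisons; the policy-monotonicity
property is asserted with repeat collection disabled, because with repeats
enabled a borderline positive can legitimately be resolved MSS by the
repeat draw — a property of the stochastic repeat, not of the resolution
rule.

Adjudication against the reference standard: a positive call needs a
known outcome (TP/FP); a negative call needs either a confirmed cancer
(FN) or ≥ 365 days of cancer-free follow-up (TN); anything else is
unevaluable and excluded from the contingency (but conserved in the
cohort accounting).

## Diagnostic statistics

Sensitivity, specificity, PPV and NPV carry exact Clopper-Pearson
intervals via the beta-quantile closed form; the test suite validates the
implementation against an independent bisection solver of the binomial
tail equations, guarding tail-convention off-by-ones. Zero denominators
yield flagged undefined entries rather than errors. Display rounding is
one decimal in percent, with interior values never shown as 0.0% or
100.0% (an exact bound of 99.967% displays as 99.9%), matching clinical
reporting practice; full precision is retained internally.

ROC curves sweep all unique score thresholds; the trapezoidal AUC is
cross-checked at run time against the Mann-Whitney rank formulation (ties
half-weighted) and against exhaustive pair counting in tests.

Study-design probabilities are exact binomial upper tails. For screening
yield, the per-subject probability compounds the annual incidence
geometrically over the lead time, `p_eff = 1 - (1 - incidence)^lead`; at
the relevant rates this differs negligibly from the linear approximation,
and both satisfy the design bounds the statistics reproduce.

## Problem sizes and numerical choices

Simulation-backed tests use cohorts of 25–80 subjects, 100–200 replicates
or seeds per property, and depth 300–2,000 reads per marker; the
CI-coverage sweep uses 10^4 replicates per (n, p) cell. VAFs are clipped
to [1e-9, 1 - 1e-9] before Beta evaluation; score additivity is exact to
1e-9; the coverage property is conservative (≥ nominal) by construction
of the exact interval.

## Limitations

The generator emulates marginal allele-spectrum structure, not raw reads:
no PCR duplicates, alignment artefacts, inter-run batch effects, sample
degradation, or non-stationary stutter. Real urine cfDNA may exhibit
tumour fractions, fragment-length biases and marker dropout patterns this
mixture does not capture, so passing tests demonstrate correctness of the
analysis pipeline under its stated model, not clinical performance. The
classifier here is trained on synthetic cohorts; no claim is made that
its fitted densities match any proprietary clinical model. Endometrial
cancer detection and mutation-hotspot extensions are out of scope, and
comparator tests (haematuria, cytology, imaging) enter only as fixed
contingency counts.
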
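# Methods

This note records the statistical model, the default parameters and why
they hold their values, the limits of the synthetic generators, and how
choices that the window-average aCGH methodology leaves underdetermined
were resolved.

## Model

### Calling

Probe-level log2 ratios are partitioned, per chromosome, into
consecutive windows of exactly 10 probes (the last window per chromosome
may be shorter and is retained). A window's statistic is the arithmetic
mean of its non-missing probes. Calls use strict inequalities: GAIN if
mean > `gain_cut`, LOSS if mean < `loss_cut`, NORMAL otherwise; a mean
exactly at a cut is NORMAL. Any window intersecting an exclusion mask —
even partially — is MASKED and never contributes to counting or testing.
Masks cover: a `telomere_pad` at both chromosome ends, the centromere
interval, the whole p-arm of acrocentric chromosomes, and the entirety
of chrX/chrY.

With ~6 kb probe spacing a window spans ~60 kb, so the method is blind
to focal events below roughly half a window; that is an accepted
property of the approach, not a defect.

### Threshold calibration

A self-self hybridization carries no true aberration, so every call on
it is a false positive. `calibrate_thresholds` sets
`gain_cut` to the (1 − 0.005) empirical quantile (`method="higher"`) and
`loss_cut` to the 0.007 quantile (`method="lower"`) of the control's
unmasked autosomal window means. Combined with strict calling
inequalities, order statistics guarantee the empirical FPR at the
returned cuts is at most the target (and within one count of it). The
asymmetric defaults (0.005 gains / 0.007 losses) reflect the empirically
heavier loss tail of real controls. Targets near 0.5 would put a
quantile on the wrong side of zero; cuts are clamped to ±1e-9 so the
`loss_cut < 0 < gain_cut` invariant always holds.

### Aberrations and breakpoints

Per sample, maximal runs of same-direction calls form aberration
segments; MASKED gaps are bridged by default so a centromere does not
split a chromosome-spanning event. Counting: whole-chromosome segment =
1 aberration / 0 breakpoints; interior segment = 1 / 2; segment touching
exactly one chromosome end = 1 / 1. Genome fraction aberrant uses only
unmasked windows in the denominator (bp-weighted by default). Group
contrasts on these per-sample metrics use the Mann–Whitney U test by
default (counts are skewed), with a t-test option.

### Differential regions and SRO

Each unmasked window yields two 2×2 tables — early/late × gain-carrier
or not, and × loss-carrier or not — tested with a two-sided Fisher exact
test. The p-value follows the sum-of-small-p rule: all tables with the
observed margins whose hypergeometric probability does not exceed the
observed table's contribute. It is computed entirely in integer
arithmetic (`math.comb`, integer weight comparison, one division at the
end), so ties are classified exactly; the test suite checks it against
both `scipy.stats.fisher_exact` and an exhaustive `fractions.Fraction`
oracle over all 122,500 tables with group sizes ≤ 25.

Runs of consecutive same-direction windows with p < α (default 0.05, no
multiple-testing correction — region-level recurrence across adjacent
windows provides the practical specificity, and the planted-truth
benchmarks measure the realized false-region rate directly) merge into a
region carrying the unweighted mean of its member p-values. Regions
intersecting a centromere mask are dropped as likely technical. The SRO
search inside a region scans all window sub-intervals and keeps the one
fully covered — via an aberrant run of at least `min_carrier_run = 2`
windows — by the most enriched-group carriers; ties break toward the
largest bp extent, then leftmost.

### Expression integration

Gene state per sample: if all overlapped unmasked windows agree, that
state; on disagreement, the state of the window containing the gene
midpoint; if all overlapped windows are masked, MASKED. The dosage
statistic is median(carriers) / median(copy-normals) on the positive
linear expression scale: concordant gain ⇔ ratio ≥ 1.5 (inclusive),
concordant loss ⇔ ratio < 0.75 (strict). The group-difference test is a
classic equal-variance two-sided t-test on log2 expression centered on
the per-gene median (Welch available as an option). Shortlist =
concordant ∧ overlapping a differential region of the matching direction
∧ group p < 0.05, sorted by p, then ratio extremity, then gene id.

## Default parameters

| Parameter | Default | Why |
|---|---|---|
| probes per window | 10 | the window-average method's defining constant |
| probe spacing | 6000 bp | platform-realistic mean tiling interval |
| gain/loss cuts | +0.1 / −0.1 | standard log2 thresholds for single-copy changes on attenuated tumor material |
| calibration FPR targets | 0.005 / 0.007 | per-window false-call rates observed at ±0.1 on a real self-self control |
| `telomere_pad` | 120 kb | two windows; the unreliable-telomere width is not standardized, so it is a parameter |
| probe noise sd (synthetic) | 0.1·√10/Φ⁻¹(0.995) ≈ 0.1228 | makes the window-mean FPR at +0.1 exactly 0.005, matching the calibration regime |
| planted event magnitude | ±0.45 | attenuated single-copy change, ~9σ above threshold at window level |
| α (windows, regions, shortlist) | 0.05 | conventional; exposed in `ExclusionPolicy`/`integrate` |
| `min_carrier_run` | 2 windows | one calibrated false-positive window cannot hijack the SRO |
| concordance cuts | 1.5 / 0.75 | median-ratio thresholds for dosage response |
| `dosage_effect` (synthetic) | 1.8–2.0 | ~one extra copy; 2.0 is the canonical doubling |
| cohort sizes | 23 vs 17 | the study-scale two-group regime all statistics are sized for |

## Synthetic generators: realism and limits

Cohorts are built as: per-probe value = Σ magnitudes of overlapping
events + Gaussian noise. Background events arrive Poisson per sample
(rate 2.0) with exponential lengths (~2 Mb); recurrent loci are planted
with exact per-group carrier counts. Expression is log-normal around a
gene baseline, multiplied/divided by `dosage_effect` per net copy state
for coupled genes. Controls are pure noise (self-self) or noise ± 0.4 on
chrX/chrY (female-vs-male).

Deliberately not modeled: GC/wave artifacts, tumor purity and
subclonality, probe-specific variance, MSI phenotypes, segmentation
(the window-average calls replace it). Consequently cohort-level
real-data summaries (median aberration counts, replicate r² values,
specific gene lists) are not reproduction targets; planted-truth
recovery is.

One realism consequence matters for verification: background events can
overlap a planted locus in a carrier and cancel part of its signal, so
the true maximal-carrier interval of a region can be smaller than the
planted bounds. Benchmarks therefore score SRO placement against the
noiseless-limit oracle (same truth events, zero probe noise, same SRO
search), which is the ground truth of the data actually planted.

## Numerical choices

- Fisher p in exact integer arithmetic; float only at the final
  division. `lru_cache` over tables (study-scale margins recur across
  thousands of windows).
- Empirical quantiles with explicit `method="higher"`/`"lower"` so the
  FPR guarantee is one-sided by construction, not by luck.
- Window means via `nanmean` so missing probes shrink the window rather
  than poison it; an all-missing unmasked window is NORMAL with a logged
  warning.
- All writers format floats to 6 significant digits and fix column
  order, making outputs byte-stable; the pipeline manifest records
  sha256 checksums of every artifact.
- A single pipeline seed expands through `np.random.SeedSequence.spawn`
  into independent substreams (cohort / control / annotation /
  expression) so stages can be regenerated independently.

## Resolutions of underdetermined choices

- **One-end segments:** a segment touching exactly one chromosome end
  counts 1 breakpoint — interpolated between the stated whole-chromosome
  (0) and interior (2) rules, since exactly one copy-number transition
  lies inside the chromosome.
- **Gene–window conflicts:** resolved by the gene's midpoint window — a
  deterministic, position-based rule favoring the window holding most of
  the gene body.
- **Region score:** the unweighted mean of member-window p-values (the
  conventional region summary; no length weighting since windows are
  near-uniform in extent).
- **FPR bookkeeping is per window, not per probe:** calls are made on
  windows, so the calibration target and the empirical FPR are defined
  on window means.
- **Telomere width:** never standardized; exposed as `telomere_pad`
  (default two windows) rather than hard-coded.
- **SRO tie-breaking:** "smallest interval shared by the most carriers"
  is degenerate under monotone coverage (it would always collapse to one
  window); the implemented rule keeps the maximal-overlap stretch whole
  (largest extent, then leftmost) and requires carrier runs of ≥ 2
  windows — see `find_sro`'s docstring.
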
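# Methods

## Scope and data model

`sangeredit` quantifies targeted RNA editing from Sanger traces of
RT-PCR amplicons. The pipeline is: ABIF trace (or externally quantified
peak table) → per-base four-channel peak areas → alignment of basecalls
to the reference amplicon → per-site editing ratios per replicate →
background correction against control replicates → two-criterion
significance call. A `Chromatogram` carries the four analyzed trace
channels, the basecalled sequence (IUPAC letters allowed) and the
called-peak positions; all reference coordinates in external tables and
results are 1-based, trace sample indices are 0-based and internal.

## Peak-area integration

Each called base owns a half-open window running from the midpoint to
its left neighbour peak to the midpoint to its right neighbour
(outermost windows extended symmetrically). Windows therefore tile the
span between first and last called peak; with no baseline correction
the per-channel window areas sum exactly to the trapezoidal integral of
the channel over that span, so signal is repartitioned, never lost.
Integration is trapezoidal at native sampling — no resampling or
smoothing, for reproducibility.

Three baseline modes exist:

* `none` — integrate the channel as-is;
* `window_min` — subtract the channel's minimum within the window;
* `chord` (default) — subtract the straight line joining the channel
  levels at the two window edges, each estimated as a 3-sample average.

`chord` is the classical valley-to-valley baseline of chromatographic
peak integration and is the default for a measured reason. The raw
window minimum is a minimum order statistic: on a noisy trace it
undershoots the true baseline by ≈1.3 noise SD, which inflates both
ratio channels additively and pulls editing ratios toward 0.5; at the
default noise level this biased recovered fractions by up to −0.05 at
high editing. The chord estimate is unbiased for a stationary noise
floor, removes constant channel offset exactly, tracks the clipped-noise
floor of near-empty channels, and — because the window edges sit
symmetrically around the peak and co-located peaks in different
channels share the same Gaussian shape — subtracts proportionally from
substrate and product channels, leaving their area ratio intact. With
it, recovery bias at generator defaults stays within ±0.013 over the
whole fraction grid, dominated by the irreducible crosstalk term
(see below).

Known limitation: when a candidate site directly neighbours a reference
peak in the *same channel as the substrate or product* (e.g. an A site
flanked by a G), the neighbour's tail leaks into the window and the
baseline estimate partially absorbs it; control subtraction removes most
but not all of the residual. Editing at such sites is quantified with a
small context-dependent bias that the control-corrected statistics
tolerate but do not eliminate.

## Reference mapping

Basecalls are aligned to the reference with a global Needleman–Wunsch /
Gotoh algorithm: match +2, mismatch −2, first gapped column −5, each
further gapped column −1. Scoring is IUPAC-aware: an ambiguity call
(R, Y, …) counts as a match when its base set contains the reference
base — essential, since mixed A/G signal at an edited site is exactly
what a trace viewer calls R. Traceback ties are broken deterministically
(diagonal, then gap in the basecalls, then gap in the reference). An
alignment whose IUPAC-aware identity over aligned columns falls below a
configurable floor (default 70%) raises a mapping failure rather than
producing unreliable coordinates. Reference positions not covered by an
aligned call are *not evaluable* for that replicate — absence of signal
is not evidence of zero editing — and become missing cells in the
editing matrix. The aligner's scores are cross-checked in the test
suite against an independent implementation (Biopython's
`PairwiseAligner`) under the same scheme.

Forward-strand reads are the default (the assay sequences with a primer
matching the amplicon 5' end); reverse-primer reads can be handled by
reverse-complementing the reference and reading the complementary
channel pair.

## Editing ratios and significance

The relative editing at a site is `product / (substrate + product)`
area — `G/(A+G)` for adenosine deamination, `T/(C+T)` for cytidine
deamination (as read in cDNA). A site-replicate is missing when
substrate + product area does not exceed `min_total_area` (default 0,
i.e. only an exactly-zero sum is missing).

Background correction subtracts the per-position *mean* of the control
replicates from each sample replicate; controls and samples are
independent infiltrations, so no replicate pairing is assumed.
Corrected values may be negative and are not clipped — clipping would
shrink the standard deviation dishonestly. Criterion 1 requires the
corrected mean to exceed three times the sample SD (n−1 denominator) of
the corrected replicate values, with strict inequality. Criterion 2
compares means: the uncorrected sample mean must be at least twice the
control mean (≥). The wording of the second rule could also be read
per-replicate; that stricter variant is available behind
`strict_criterion2` (default off). When the control mean is numerically
zero (< 1e-9), criterion 2 reduces to "any positive editing". At least
`min_replicates` (default 3, matching the 3–4 biological replicates the
assay typically uses) non-missing sample values and one control value
are required per site; otherwise the site is reported as not evaluable,
never as 0%.

No multiple-testing correction is applied — the 3σ rule is the stated
guard — and the per-run candidate count is reported so users can apply
an FDR externally.

## Synthetic traces

The generator emits one Gaussian peak per reference base (spacing 12
samples, peak SD 3, amplitude 1000 fluorescence units). An edited
position with true fraction f splits its amplitude (1−f)/f between
substrate and product channels — the mixed-template signal of a
partially edited amplicon. Three noise processes are modelled, each with
a defended default:

* **crosstalk** 0.01 — each peak leaks 1% of its amplitude symmetrically
  into every other channel; the simplest mechanism producing the nonzero
  background that control subtraction must remove, at the level of a
  well-calibrated capillary instrument;
* **channel noise** SD 10 (1% of amplitude) — additive Gaussian detector
  noise, traces clipped at zero;
* **amplitude CV** 0.1 — one global factor per replicate, modelling
  replicate-to-replicate signal strength variation; it cancels in every
  ratio by design, which the scale-invariance tests verify.

Basecalls derive from the noiseless per-peak amplitudes: the maximum
channel's base, or the two-base IUPAC code when the minor channel
exceeds 25% of the major — the threshold at which trace viewers flag
secondary peaks, chosen so the IUPAC-aware aligner is genuinely
exercised at f between roughly 0.2 and 0.8. Peak jitter exists as a
parameter but defaults to 0, keeping analytic oracles (exact Gaussian
areas, exact ratios in the noise-free limit) available. Controls are
generated from the same model with all fractions zero. Per-replicate
seeds spawn deterministically from one master seed; identical inputs
give bit-identical traces.

What the generator deliberately does not model: PCR amplification bias,
reverse-transcription errors, mobility shifts, dye blobs, and
basecaller miscalls away from edited sites. Passing recovery tests
therefore demonstrate the correctness of the quantification given a
well-behaved trace, not robustness to every failure mode of real
capillary data.

With the defaults and the corrected-mean estimator, the residual
recovery bias is dominated by symmetric crosstalk, which attenuates the
corrected value to f·(1−c)/(1+c) ≈ 0.98·f — at most −0.02 at f = 1.
The characterization harness (`estimate_operating_characteristics`)
measures, per true fraction, the Monte-Carlo call rate (type-I error at
f = 0, power at f > 0) with binomial standard errors and the mean bias.
At defaults with 4 vs 4 replicates the measured type-I error is below
1% and power at f ≥ 0.25 exceeds 95%; the problem sizes used by the
test suite and the acceptance script (12 sites × 5 runs for the
fraction grid, 200 sites × 5 runs for the null rate) were chosen to
give those rates stable two-digit resolution at interactive runtimes.

## Calibration and CAPS

The calibration analysis mirrors the wet-lab check of mixing an edited
and an unedited plasmid at known ratios and sequencing the mix: the
synthetic analogue simulates one trace per mixing fraction and measures
the peak-ratio fraction at the mutated site; ordinary least squares of
measured on expected summarises sensitivity (slope) and reproducibility
(r²). At defaults the fit recovers slope ≈ 0.99 with r² > 0.999.

The CAPS module computes the cleaved fraction of a digested lane from
band quantities on a molar scale (mass inputs are divided by fragment
length first, since shorter fragments carry less mass per molecule).
Only the larger expected cleavage fragment is counted — both fragments
appear per cut molecule, and counting both would double the cleaved
amount. Band lengths match expectations within a relative tolerance
(default 10%); an undigested control lane, when provided, must contain
the uncleaved band or the assay is flagged as failed. Group comparison
uses the unpaired two-tailed t-test; Welch's unequal-variance form is
the default (the safer choice when only "unpaired t-test" is specified)
with the pooled-variance form behind a flag. Degenerate zero-variance
groups yield t = 0, p = 1 when means agree and a signed infinite t with
p = 0 otherwise.

## Workbook import

Externally quantified editing analyses (e.g. a spreadsheet exported
from a trace viewer) are imported through a generic column-mapped
worksheet reader rather than a hardcoded layout: the caller names the
worksheet columns holding position, base and either the four raw
channel areas or per-replicate precomputed ratios. Raw-area worksheets
join the pipeline before the ratio step; ratio worksheets skip peak
integration entirely.

## Numerical conventions

Window edges are fractional (midpoints between integer peak positions);
integrals interpolate linearly at the edges, which is what makes the
tiling conservation exact to floating tolerance. Areas are clipped at
zero after baseline subtraction. External numeric fields round-trip
through text at 6 significant digits. Ties in the run summary's
strongest site break toward the smallest reference position. All
stochastic components consume a `numpy` `Generator` seeded from a
single integer.
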
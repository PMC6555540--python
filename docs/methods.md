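# Methods

## Linkage model of the GIM suppressor cross

A GIM screen crosses a query strain to the pooled barcoded deletion
collection, sporulates, selects haploids carrying the deletion marker,
and grows the pool competitively.  For a deletion at genomic position
x and a suppressor locus at position y on the same chromosome, the
fraction p of marker-selected spores that also carry the suppressor
allele equals the recombination fraction between x and y; on other
chromosomes the loci assort independently and p = 1/2.

* **Map function.** Genetic distance is `d = |x − y| / 1000 × cM_per_kb`
  with a uniform rate of 0.35 cM/kb (a typical budding-yeast genome
  average; configurable).  Recombination follows Haldane's no-interference
  map function `r(d) = (1 − e^(−2d/100))/2` (d in cM).  Both choices are
  recorded in output metadata; crossover interference would only sharpen
  the linkage decay and does not change the scan's logic.
* **Competition.** Spores carrying the suppressor double every
  `τ_s` = 135 min, spores without it every `τ_u` = 180 min (the measured
  doubling times of the suppressed double mutant and the unsuppressed
  deletion strain).  After a pooled competition of T = 1350 min
  (10 generations of the faster grower; the protocol's actual duration
  is not published, so a round two-day-scale pooled growth was fixed
  once) the query-pool abundance of barcode i is
  `a_i = p_i·2^(T/τ_s) + (1−p_i)·2^(T/τ_u)`; the control pool has no
  fitness differential.
* **Noise.** Intensities are abundance × unit-mean lognormal noise,
  CV 0.2 per channel, independent across channels — microarray-like
  multiplicative noise that keeps intensities positive.
* **Positive control.** When a query-marker locus is configured,
  query-channel abundance is additionally multiplied by `r(d_q)/0.5`,
  the double-recombinant fraction normalised to its unlinked value:
  barcodes at the marker itself vanish from the query pool and the
  effect decays with the same Haldane kernel.
* **Barcode placement.** Barcodes are apportioned to chromosomes
  proportionally to length (largest-remainder rounding) at uniform
  random positions; the default genome is the 16 *S. cerevisiae*
  chromosomes with their sacCer3 lengths, ~4,500 barcodes ≈ one per
  2.7 kb.

## Genome scan

1. **Normalisation.** Each channel is median-scaled to 1; zeros are
   replaced beforehand by half the channel's smallest positive value.
   Scan results are invariant to channel-wise rescaling, and a
   constant added to all scores leaves every p-value unchanged.
2. **Score.** `s_i = log2(control_i / query_i)`: counter-selected
   (depleted) barcodes score high, so linked loci are maxima.
3. **Smoothing.** Per chromosome, the mean over every run of W = 20
   consecutive barcodes (step 1, full windows only — shrinking edge
   windows would inflate edge variance).  The window centre is the
   median of the W positions.  Chromosomes with fewer than W barcodes
   yield no windows and a logged warning.
4. **Peak calling.** Local maxima of the windowed track (plateaus
   collapse to their leftmost window, so output is deterministic) whose
   prominence above the chromosome's median window score exceeds one
   median absolute deviation of that chromosome's window scores.
5. **Significance.** Scores are shuffled across all barcodes genome-wide
   with positions fixed — this preserves the score distribution exactly
   — the profile recomputed, and the genome-wide maximum window score
   recorded per shuffle.  A peak's p-value is
   `(1 + #{perm max ≥ peak score}) / (n_perm + 1)`, i.e. family-wise
   calibrated against the best peak a null genome produces.  All local
   maxima passing prominence are returned with their p-values, sorted
   by (p, −score); callers filter at their chosen α.  The permutation is
   vectorised (one permutation matrix, cumulative-sum window means), so
   a 4,500-barcode scan with 1,000 permutations takes well under a
   second.

Whether the original analysis smoothed across chromosome boundaries or
applied an explicit peak threshold is not published; per-chromosome
smoothing is the conservative reading, and the permutation test is this
package's addition.

## Growth, frequency and phenotype estimators

* **Doubling time.** OLS of log2(OD600) on time; `τ = 1/slope`, with a
  delta-method SE.  The exponential window is the full series when its
  R² ≥ 0.99, otherwise the contiguous run of ≥ 4 points maximising R²
  (longest on ties) — this skips lag and saturation phases without
  manual gating, and a manual window override exists.  The fit is exact
  on noiseless exponentials and invariant to OD rescaling.
* **Suppression index.** `(τ_mut − τ_double)/(τ_mut − τ_wt)`; 1 = full
  rescue, 0 = none, unit-free.
* **Mutation frequency.** `colonies / (cells plated × survival)` with a
  Clopper–Pearson 95% CI on the colony count over viable cells; the UV
  effect is the frequency ratio with a log-scale delta-method CI from
  the two binomial SEs.  This is a plain frequency comparison, not a
  Luria–Delbrück fluctuation-rate estimate.
* **Spread counts.** Mean/median, percentile-bootstrap CI (2,000
  resamples, seeded) and method-of-moments negative-binomial dispersion
  `k = m²/(s² − m)` (∞ when the sample is not over-dispersed).  Strain
  comparisons default to Welch's t-test (two-sided), with Mann–Whitney
  and permutation variants; marking significance at α = 0.01 follows
  the convention for such occupancy comparisons (a figure legend
  stating "p-values > 0.01" for significant differences is read as a
  typo for p < 0.01).
* **ChIP occupancy.** Replicate percent-input divided by the reference
  strain's per-amplicon median; median ± SD per (strain, amplicon) and
  Welch tests against the reference.  Invariant to global rescaling.
* **Fold changes.** Every signal divided by its replicate's
  internal-control probe (5S for TRO, PGK1/SCR1 for blots, an explicit
  "loading" pseudo-probe for pulse gels without a named control), then
  fold = ratio of per-strain medians, CI by bootstrap over replicates.
  Ratio of medians was chosen over mean of ratios for robustness at the
  2–3 replicates these assays have.  The TRO "Pol I" value is the mean
  of the 5'ETS, 18S.2, 25S.1 and 3'ETS probes; with a shared control
  denominator this grouping commutes with normalisation on noiseless
  data.

## What the synthetic data does and does not emulate

The generators reproduce the statistical structure the estimators rely
on: linkage-dependent depletion with the correct distance decay,
exponential growth with multiplicative noise, (over)dispersed counts,
replicate loading artefacts removed by an internal control, and
binomial colony counts.  They do not emulate deletion-collection
quirks (missing essential-gene barcodes, barcode cross-hybridisation,
batch effects across arrays), lag/saturation growth mechanics beyond a
piecewise test case, chromatin or rDNA copy-number dynamics, or
clone-to-clone heterogeneity in pulse labelling.  Passing tests
demonstrate estimator correctness and calibration under this model,
not robustness to those real-data artefacts.

## Problem sizes and numerical choices

Recovery suites run at the study's scale: 100 noisy screens of 4,500
barcodes (plus 200 null screens for type-I calibration, 100–200
permutations per scan), 200 growth curves per strain (20 points over
10 h, CV 2%), 100 Poisson spread samples of 200 genes per strain, 300
replicate signal-table sets per fold effect, and 500 simulated plating
assays; the whole suite completes in well under a minute of CPU.
Tolerances mirror each estimator's sampling noise at those sizes (2%
for doubling-time means, 5% for count means, 10–15% for medians of
3-replicate fold estimates).  Degenerate inputs are errors, not
silent answers: flat growth curves, all-zero intensity channels, zero
control signals (named by replicate) and zero reference medians all
raise; identical zero-variance count samples return p = 1 with a
warning rather than NaN.

## Known limitations

* The permutation null assumes exchangeable barcode scores; spatial
  autocorrelation of array artefacts would make it anti-conservative.
* The delta-method CI for the UV fold requires non-zero colony counts
  in both conditions; with zero spontaneous colonies the estimator
  refuses and suggests reporting a bound from the CI limit.
* Bootstrap CIs over 3 replicates are coarse (few distinct resamples);
  they are reported for transparency, not as exact coverage intervals.
* Peak calls at barcode resolution: candidate genes are the window's
  deletion strains; fine-mapping below barcode spacing is out of scope.
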
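# Methods

## Poisson occupancy quantification

A droplet is positive when it received at least one amplifiable copy, so
the positive count k among N analyzable droplets is binomial with success
probability p = 1 − e^(−λ). The maximum-likelihood estimate is the closed
form λ̂ = −ln(1 − k/N) (computed via `log1p` for small fractions), and the
concentration is C = λ̂/v. k = 0 gives λ̂ = 0; k = N is a saturation error —
the likelihood is unbounded and the only remedy is dilution.

**Confidence intervals.** A Wilson interval on p̂ = k/N (Clopper–Pearson
optional) is mapped through λ = −ln(1 − p). The log map is monotone, so
interval endpoints map directly. Coverage of the nominal 95% interval was
verified by simulation at λ ∈ {0.05, 0.2, 1.0} and N = 23,527 to fall in
[0.93, 0.97].

**Effective droplet volume.** v defaults to 6.236 × 10⁻⁴ µL. The vendor's
nominal volume is not public; this value is back-derived from the
self-consistency of one instrument-reported chip, where all three gated
populations imply the same volume within 0.2% (v = λ̂/C applied to each
row). Any dead-volume or pre-reaction dilution factor the reader software
applies is absorbed into this constant, which is configurable per run
(`calibrate_droplet_volume` recomputes it from any reported row).

**Broken-fraction arithmetic.** With the blue double population (total)
and a JEM1 reference, C_ctg = C_total − C_ref, % unbroken =
100·C_ctg/C_ref, % broken = 100 − % unbroken (the two always sum to 100
exactly). The reference defaults to the green (probe) channel; the blue
upper population serves as cross-check, and their relative difference
(`consistency_delta`) raises a warning above a 5% default tolerance. A
switch reverses the roles.

**Ratio interval.** The percentage carries a delta-method interval on
log(λ_diff/λ_ref). Because the reference gate is nested inside the total
gate (every JEM1-positive droplet is blue-positive), the two estimators
share droplets and cov(λ̂_total, λ̂_ref) = var(λ̂_ref) exactly for indicator
gates; the interval uses this covariance rather than assuming
independence, which would roughly double its width at the default
concentrations. It remains approximate (first-order, and both counts come
from one chip). Empirical coverage over 200 simulated chips at the default
configuration sits within [0.90, 0.99].

**Negative differences.** A slightly negative C_ctg (reference above
total) is expected noise when the true unbroken fraction is near zero: if
|λ_diff| lies inside the z·σ band of zero it is clamped to 0 with a
warning. The band uses the conservative independent-variance σ, because a
negative difference already signals that the gates are not nested as the
covariance argument assumes. Beyond the band it is an error pointing at
the gating.

**Rounding.** Reports round half-up to one decimal, matching instrument
ledgers; all arithmetic and comparisons keep full precision.

## Droplet gating

Automatic thresholds come from a deterministic one-dimensional k-means per
channel: centers initialized at the 25/75th (two populations) or
17/50/83rd (three) intensity percentiles, assignment boundaries at
midpoints between adjacent centers with ties to the lower cluster, up to
100 iterations over internally sorted data (hence order-independent).
Thresholds are the midpoints between final centers. Constant channels or
emptied clusters raise an error naming the channel. Manual thresholds
always override fitting; provenance is recorded.

With heavily skewed class proportions (e.g. > 83% negatives) the quantile
initialization starts all centers inside the negative cloud and the
algorithm relies on k-means updates to migrate them; this works at the
default separations but is the first thing to check on marginal data —
set manual thresholds if in doubt.

The optional red (Alexa 647) channel is a fill control only: a floor
filter can drop under-filled droplets before gating, and by default no
filtering is applied. No inter-run intensity normalization is attempted;
units are arbitrary.

## Partition simulator

Per droplet, JEM1 copies ~ Poisson(c_jem1·v) and CTG copies ~
Poisson(c_ctg·v), independently; each CTG copy is broken with probability
f independently (binomial thinning, so unbroken copies are Poisson with
mean c_ctg·v·(1−f)). The latent class is JEM1-containing (≥1 JEM1 copy),
CTG-only (0 JEM1, ≥1 unbroken CTG) or negative; a broken CTG copy never
amplifies. Intensities are Gaussian around per-class means — blue
1,000/8,000/20,000, green 1,000/10,000, sd 600, arbitrary units chosen so
classes separate by ≳ 11 sd. An optional `linked` mode co-assigns one JEM1
and one CTG copy per genome, for sensitivity analysis of the independence
assumption (genomic DNA is digested before partitioning, so unlinked is
the default).

Defaults are the published chip's conditions: 23,527 droplets,
v = 6.236 × 10⁻⁴ µL, 206.6 cp/µL of each locus (one genome equivalent
carries one copy of each), broken fraction 0.346. All randomness flows
through a single integer seed (`numpy.random.default_rng`); replicate runs
derive child seeds from it via `SeedSequence`.

What the simulator does **not** emulate: droplet-volume variability
(monodisperse assumption), partial amplification ("rain") and intensity
drift, PCR efficiency and inhibition, and the instrument's droplet QC
(why a 25,000-droplet chip yields 23,527 analyzable droplets is not
modeled — `n_droplets` is taken as already-QC'd). Passing recovery tests
therefore demonstrate correctness of the statistics under the partition
model, not robustness to rain-heavy or poorly separated real chips.

`recover` closes the loop (simulate → fit thresholds → gate → quantify)
and reports bias and interval coverage. At the default scale the
percent-broken estimator's finite-chip bias is below 0.2 points; a seeded
sweep in the tests shows |bias| shrinking over 1,000 / 5,000 / 23,527
droplets (2,000 / 800 / 300 replicates — sizes chosen so the Monte-Carlo
error resolves the trend).

## Southern densitometry

Net volume per band is signal minus its own background (U1−U2, U3−U4,
U5−U6, U7−U8 for full-length, contracted, 5′ break, 3′ break); percentages
are nets over the net total. Background exceeding signal is an error by
default (a sound scan never shows it; silent clamping would hide scanner
misuse) with an opt-in `clamp` that zeroes the net under a warning. The 5′
and 3′ break percentages should be equal in principle; `end_agreement`
flags discrepancies above a tolerance (default 5 points) as a symptom of
non-linear chemiluminescent detection. Standard half-up rounding to one
decimal reproduces all published lane values.

## DSB-qPCR support

Standards are mass-balance mixtures of digested and undigested stocks:
digested mass fraction = target percent, total mass = final concentration
× final volume; infeasible recipes (stock more dilute than the final
concentration) fail naming the limiting stock. The standard curve is an
ordinary least-squares fit of mean Ct (replicates averaged first) on
percent DSB on a linear axis — a log-percent option exists because figure
axes are sometimes logarithmic — reporting slope, intercept, signed r, |r|
and r². Inversion is (Ct − intercept)/slope, with estimates outside
[0, 100] returned under an extrapolation warning. Melt analysis smooths
fluorescence with a 5-point moving average (configurable), takes −dF/dT by
central differences and counts local maxima above a prominence fraction
(default 0.1) of the derivative peak; two peaks mean an off-target product
and disqualify the dye concentration. Ct calling from raw amplification
curves is out of scope — Ct values are inputs.

## Design notes and limitations

* Config files are JSON; CSV is comma-separated UTF-8 with a mandatory
  header, and thousands separators (plain, no-break or narrow spaces,
  commas) are stripped from numeric fields on read.
* Reports always carry both the rounded display values and full precision.
* The brute-force oracle used in tests maximizes the binomial occupancy
  likelihood on a refined grid, independent of the closed form.
* The cross-method comparison (densitometry vs dPCR) uses the 5′-end
  percentage, the end at which the repeat-proximal break is fully
  resolved on the blot.
* Two-population blue fits return only `blue_low`; full duplex gating
  requires both blue thresholds.
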
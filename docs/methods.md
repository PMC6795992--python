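# Methods

## The power-law clock

The model is a power-law decay of the apparent evolutionary rate with
measurement timescale, expressed as a linear relationship between log node
age and log node height:

    log t = α + β log s

with *t* the age of an internal node in millions of years (Myr) and *s* its
height in expected substitutions per site per lineage. Logs are natural and
time is in Myr throughout: with the central-SU point estimates
(α = 4.114, β = 1.762) this convention yields *s* ≈ 1.32 at *t* = 100 Myr —
an average long-term rate near 1.3 × 10⁻⁸ substitutions/site/year, the
realistic order for a co-speciating retrovirus — whereas base-10 logs or
years would imply absurd magnitudes. Predictions are invariant to the log
base (β is base-invariant, α transforms by the log of the base), so the
choice is purely presentational; the results object records it.

Assumptions worth stating explicitly:

- **Co-speciation.** Calibration nodes are virus divergences assumed to be
  synchronous with dated host divergences. The calibration table carries the
  host date as median + 95% interval; nothing in the fit tests the
  co-speciation assumption itself (internal-consistency checks are up to the
  analyst, e.g. dating held-out host-matched nodes).
- **Strict-clock posterior input.** Trees are expected ultrametric up to
  numeric noise. Node height is defined as the *mean* root-to-tip path below
  the node; for exactly ultrametric trees every descendant tip gives the
  same value, and a tip-path spread above 10⁻⁶ triggers a logged warning
  rather than an error (the mean is the least-biased single summary).
- **Per-tree calibration.** The line is refitted in every posterior tree
  with one fresh date draw per calibration point per tree, rather than once
  on pooled points. This propagates tree and date uncertainty jointly; the
  pooled per-target time draws are a Monte Carlo composite of both sources.
- **Unweighted least squares.** With three calibration points there is
  little information to estimate weights; OLS in log–log space is the
  simplest estimator consistent with the model, and with two points it is
  exact interpolation.

## Date sampling

A host date (median *m*, 95% bounds *l*, *u*) becomes a normal distribution
with mean *m* and sd `max((m − l)/1.96, (u − m)/1.96)` — the conservative
(wider) half-interval. Draws ≤ 0 are rejected and redrawn, i.e. the
distribution is truncated at 0⁺; the clock takes log *t*, so positivity is
required. For realistic host dates (medians ≥ ~2.6 sd above zero) truncation
distorts the first two moments by well under a percent; the test suite
checks the sampler against the analytic truncated normal.

Trees in which a calibration or target clade has non-positive height are
skipped with a warning; if more than 20% of trees are skipped the fit
aborts, since the pooled summaries would no longer represent the posterior.
Monophyly of each named clade is recorded per tree as a diagnostic, but the
MRCA is used regardless — forcing monophyly would silently bias heights.

## HPD intervals

The 95% HPD is the shortest contiguous window of sorted samples containing
⌈0.95 n⌉ of them, leftmost on ties (the convention of standard MCMC
post-processing tools). A brute-force enumeration over all windows is kept
as the test oracle.

## Region tools

Coordinates are 1-based inclusive alignment columns; gap columns count.
Consensus filtering keeps recombination events detected by at least four
programmes at P < 0.05 (both thresholds configurable). Breakpoint clustering
is single-linkage in one dimension with a default 50-column gap — an
automated stand-in for what is usually a visual delimitation of hotspot
intervals on the event map; the gap needs dataset-specific tuning.
Alignment splitting removes the hotspot columns and emits the flanking
regions in order; excision of a recombinant segment of a single sequence
replaces its characters with gaps rather than deleting columns, because
deleting columns of one record in a rectangular alignment is not defined —
blanking preserves column homology for every other record.

Site rates are rescaled to a global mean of exactly 1 (each posterior sample
row independently, when a sample matrix is given). Region summaries are
arithmetic means over the region's columns; the focal/complement rate ratio
is computed per posterior sample as the ratio of region means and summarised
by its mean and by HPDs on both the linear and the natural-log scale — the
log interval is the symmetric, honest one for a multiplicative quantity.

## Codon usage

Counts are pooled over the sequences of a group (not averaged per-sequence
frequencies) across the specified regions read in frame. The contingency
table always has the 61 sense codons as rows — stop codons and triplets
containing gaps or ambiguity codes go to a per-group discard tally, and
zero-count rows are retained — so a three-group comparison always has
df = (61 − 1)(3 − 1) = 120. The statistic is Pearson's χ² with
margin-derived expectations and no continuity correction; cells with zero
expected count contribute zero. Caveat: codons pooled over phylogenetically
related sequences are not independent observations, so the nominal P value
overstates significance on real (or tree-simulated) data; it is a
descriptive comparison, not a calibrated test.

## Synthetic data

The generators provide every pipeline input with known truth:

- **Posterior tree samples.** A host tree with node heights in Myr defines
  true node times; true heights are the inverse power law
  `s = exp((log t − α)/β)`. Each posterior draw multiplies every internal
  node's true height by an independent lognormal(0, σ) factor — lognormal
  keeps heights positive and is symmetric on the log scale where the clock
  lives. Parent-above-child ordering is enforced by conditioning each node's
  factor below its parent's drawn height (exact inverse-CDF truncated
  sampling, equivalent to rejection but robust when a draw puts a child near
  its parent). Branch lengths are rebuilt from the noisy heights, so the
  trees are exactly ultrametric.
- **Alignments.** Regions are simulated independently down per-region trees
  under the one-parameter equal-rates substitution model (per-branch
  transition `p(b) = ¾(1 − e^(−4b/3))`), concatenated with declared hotspot
  filler columns drawn iid uniform per sequence. This exercises splitting
  and codon counting; it does not emulate indels, rate heterogeneity across
  sites, or base composition bias.
- **Rate matrices.** Per-column gamma rates with region-structured means and
  a chosen sd, then rescaled to mean 1 per sample.
- **Event tables.** Consensus events with breakpoints inside the two
  flanking hotspots supported by all programmes, plus weakly supported
  spurious events anywhere.

The shipped demo geometry mirrors the study design the package targets:
eleven taxa; calibration nodes at 8.6, 5.3 and 100 Myr (bounds ≈ ±20% of the
median, i.e. a ~10% coefficient of variation, the scale of published host
timetable intervals); shallow target clades at 1.075 and 0.415 Myr; a deep
two-variant split at 29.892 Myr; α = 4.114, β = 1.762, σ = 0.1, 500 trees by
default. These values were fixed once when the demo was designed. Passing
tests on this geometry show the estimator and its uncertainty propagation
are correct under the model's own assumptions; they do not validate the
power law, the co-speciation assumption, or robustness to model
misspecification on real data.

## Coverage experiment

`hpd_coverage_experiment` measures frequentist calibration of the pooled 95%
HPD. A naive design — fixed truth, iid per-tree noise — would make the
pooled median concentrate ~√n_trees faster than the interval width, so the
interval would cover a fixed truth essentially always and the experiment
would measure nothing. The experiment therefore draws each replicate from
the model's own generative distribution (simulation-based calibration):
true calibration dates are drawn from the date priors, and the posterior
tree sample is centred on a once-per-replicate "observed" height vector
drawn around truth with the same σ as the posterior spread — emulating a
posterior whose width matches the data error, as in a normal location model.
Under this design both uncertainty components are calibrated and empirical
coverage sits at ~0.93–0.95 with 200 replicates of 500 trees (σ = 0.1).
Problem sizes (200 replicates × 500 trees) keep the experiment around
twenty seconds while leaving the binomial noise on coverage (~1.5 points)
well inside the ±4-point acceptance band.

## Numerical conventions and degenerate inputs

- HPD ties broken leftmost; `n < 2` samples are an error.
- `fit_power_law` requires ≥ 2 points, all positive, with ≥ 2 distinct
  heights (all-equal heights raise a singular-fit error).
- Zero-width host-date intervals give sd = 0 and constant draws; sd = 0 with
  non-positive mean is an error.
- All randomness flows from a single seed through `numpy` `SeedSequence`
  spawning, with fixed per-stage children in the pipeline, so stages can be
  rerun in isolation and whole runs are byte-reproducible.

## Known limitations

- The clock extrapolates: target heights outside the calibration range (the
  usual case for shallow nodes) inherit the regression's extrapolation
  error, which the per-tree refit only partially reflects.
- Calibration points are treated as independent; shared phylogenetic error
  between nested calibration nodes is not modelled.
- The synthetic sequence model is intentionally minimal (no indels, no
  among-site rate variation), so codon-usage and rate-profile results on
  simulated data are structural checks, not realism checks.
- Automated hotspot delimitation (single-linkage clustering) will not
  reproduce manually curated hotspot bounds without tuning the gap.
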
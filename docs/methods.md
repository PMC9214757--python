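# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Data model and formats

All coordinates are 0-based half-open (BED convention).  A genome is an
ordered bin table with dense global bin ids; contact maps are symmetric
matrices over that table, stored dense in memory (the package targets
hundreds to a few thousand bins per chromosome) and serialized as sparse
upper-triangle triplet text (`bin_i bin_j value`).  Per-bin tracks (PC1,
DI, insulation, biases) are bedGraph; intervals (TADs, boundaries,
conserved regions) are BED; loops are BEDPE.  Matrix `kind` tags (raw /
balanced / observed_expected / difference) are enforced at operation
boundaries so, for example, the DI cannot accidentally be computed on
unbalanced counts.

## Synthetic contact maps

The generator draws independent Poisson counts around a fully specified
expectation so that every downstream statistic has an analytic or
brute-force oracle:

    E_ij = depth_scale · (d_ij · bin_size)^(−α)          cis decay
         · exp(+g) same-compartment / exp(−g) opposite   g = ln(1 + c)
         · τ if i, j inside one planted domain
         · λ at planted loop pixels
         · b_i b_j,   ln b ~ Normal(0, bias_log_sd²)

with `d_ij = |i − j|` clipped below at 1 (the diagonal reuses the one-bin
expectation; all downstream statistics exclude the diagonal).  Trans
pixels get a flat `trans_background · depth_scale · b_i b_j`.  One root
seed drives named substreams (biases, counts, PC1 pairs, expression) so
each operation is reproducible in isolation.

Default study conditions: 40-kb bins, α = 1, depth_scale 2×10⁷ (≈500
expected counts at one-bin separation — deep coverage at desk scale,
standing in for the hundreds of millions of read pairs a real stage
library yields), compartment blocks of 10 bins, domains of 20 bins at
τ = 3, loops at λ = 8, bias sd 0.3.  The demo uses 2-Mb compartment
blocks (50 bins), matching the real-genome situation where compartment
blocks are much larger than domains, and tiles domains contiguously, as
real domains largely are.

What the generator does **not** emulate: overdispersion beyond Poisson
(no biological replicate variance), restriction-fragment geometry,
translocations and copy-number effects, distance-dependent bias
structure, nested/hierarchical domains, and gradual (non-step)
compartment transitions.  Passing the plant-and-recover suite therefore
demonstrates correctness of the estimators under their own model
assumptions, not performance on real libraries.

Poisson noise is an implementation choice; the matrices this pipeline is
designed for come with no stated noise model, and Poisson is the minimal
model consistent with read sampling.  An overdispersion knob is future
work.

## ICE balancing

Plain iterative correction: divide each entry by the product of its two
row-sum factors (relative to the mean row sum), accumulate the factors
into the bias vector, stop when the maximum relative deviation of row
sums is below `tol` (default 1e-5; default `max_iter` 1000 because plain
iteration converges slowly on small noisy matrices).  Bins in the bottom
2% of coverage plus zero-coverage bins are masked first; both knobs are
exposed.  The returned biases satisfy `raw = b_i · b_j · balanced`
exactly (the global scale is folded into `b`), which the loop caller
relies on.  Non-convergence flags the result rather than raising, so
degraded inputs remain inspectable.

A caveat that matters for validation: ICE biases are identified only up
to the structural coverage profile of the underlying expectation.  A
linear chromosome with power-law decay is *not* doubly balanced (edge
rows see fewer partners), so recovered biases are the planted biases
times a smooth structural component.  Bias-recovery checks therefore
either factor that component out with a noise-free reference or plant
biases on an expectation that was double-balanced first.

## Observed/expected and decay statistics

The per-distance expected value is the mean balanced value over unmasked
pixel positions at that separation, per chromosome, zeros included — the
inclusive convention, consistent with the replicate correlation, which
counts every possible interaction in the 2-Mb band including shared
zeros (a flag switches to a nonzero-union correlation).  Distances with
zero expectation are masked.

P(s) uses the same inclusive denominator, then normalizes to unit mass
over represented distances (per-distance averaging first, total-mass
normalization second).  The slope track is the centred finite difference
of the LOWESS fit of `log10 P` vs `log10 s` (span 0.3 by default; the
smoother, not its span, is dictated by practice), which is exact on
power laws and straightforward to test, unlike an analytic LOWESS
derivative.  Exponent-recovery checks read the slope over 0.2–2 Mb
separations, where desk-scale coverage keeps per-distance means well
determined even for steep decay (α = 2.3).

Cis-short/cis-long fractions split at 2 Mb with ties assigned to the
long side (documented, configurable).  Chromosome-pair enrichment uses a
margin-product expected rescaled so total expected equals total observed
over distinct pairs; a uniform background then gives enrichment exactly
1 for every pair.

## Compartments

PC1 is computed per chromosome as the leading eigenvector of the Pearson
correlation matrix of O/E columns over unmasked bins; no explained-
variance or arm-split diagnostics are applied by default.  The sign is
fixed per chromosome by positive correlation with an explicit
orientation track (gene density or mean expression per bin is the
recommended choice; the demo uses the planted labels).  Chromosomes with
fewer than 10 usable bins are masked with a warning.

Saddle strength ranks bins by PC1 genome-wide, cuts five equal-occupancy
groups, averages cis O/E within each group pair, and reports
`(AA + BB) / (AB + BA)` over the extreme corner (corner fraction 0.2,
i.e. one quantile each side at Q = 5).  For a planted checkerboard whose
label composition is stationary in distance (i.i.d. labels), the
strength has the closed form `e^{2g}`: same-label pairs carry `e^{+g}`,
opposite pairs `e^{−g}`, and the per-distance mean cancels.  For
periodic blocks no closed form exists — the per-distance mean itself
oscillates with the block period and dilutes the corner ratio — so the
block-geometry checks compare against a brute-force re-derivation of the
corner ratio and use the stationary case as the analytic anchor.

Switch accounting operates on compartment-resolution bins (not merged
runs): joint A/B counts over co-unmasked bins and the stable fraction
`(AA + BB)/total`.  The run-based alternative would give different
percentages; bins were chosen because switch percentages are quoted as
genome fractions.

## TADs and insulation

DI uses the chi-square-like form `sign(B − A)·((A − E)²/E + (B − E)²/E)`
with truncation at chromosome ends, zero when `A = B`, undefined when
`A + B = 0`.  The default window is 2 Mb; window and resolution are
parameters, not constants.

The HMM has 3 states (upstream bias / none / downstream bias) with
Gaussian emissions on the sign-preserving log scale
`sign(DI)·log1p(|DI|)` — raw DI spans orders of magnitude and breaks
Gaussian emissions outright.  Initialization is deterministic and
moment-based (state means at −sd, 0, +sd; shared variance; sticky
transitions), EM refines per chromosome, Viterbi decodes; EM failure
falls back to threshold segmentation with a warning.  Domain grammar: a
domain opens at the start of a maximal downstream run and closes at the
end of the next upstream run, absorbing no-bias stretches; gaps between
adjacent domains shorter than 400 kb are boundaries (the <400 kb rule is
read as a gap-length bound — the alternative reading, boundary-region
width, is noted as open).

Insulation is the mean contact in the square `(b−w, b] × (b, b+w]`
(default 400 kb), reported as log2 over the chromosome mean of defined
values so that doubling coverage leaves the track unchanged; a
loess-smoothed copy (span 0.1) is kept alongside.  Boundary detection by
local minima should use the **raw** log-ratio track: on closely tiled
domains, smoothing merges the twin minima flanking short gaps into one
mid-gap minimum and degrades ±1-bin localization.  Aggregate TAD
profiles rescale each domain to unit length with half-length flanks and
average linear interpolations over 100 shared coordinates.

## Loops

The caller follows the donut scheme at one resolution: for every cis
pixel in the band (default 4 bins to 2 Mb; never closer than the donut
diameter), four expected models are computed from the balanced map — the
donut annulus between the peak radius and the donut radius, the
lower-left quadrant, and 3-wide horizontal and vertical stripe bands.
Each model rescales the per-distance expectation by the footprint's
observed/expected ratio; the largest, converted to raw space via
`b_i b_j`, is the Poisson mean for a one-sided tail test.  BH adjustment
runs globally over all tested pixels (not λ-chunked); calls need
adjusted p below 0.001 **and** fold enrichment of at least 2.
Significant pixels merge by 8-connectivity; the summit is the most
significant pixel (ties: larger count, then smaller bin).

The horizontal/vertical models and the fold gate are load-bearing:
balancing leaves smooth row/column residuals around sharp domain edges
and coverage steps, which the donut and quadrant alone misread as focal
enrichment.  Pixels whose full footprint does not fit inside the upper
triangle of the chromosome are not tested — truncated neighborhoods
bias the expectation.  Remaining caveats: per-bin bias estimates carry
sampling error, so extremely rare (order 1 per 10⁵ tested pixels)
borderline false calls can survive near coverage transitions; and on
synthetic maps with step-function compartment blocks, block-corner
pixels genuinely carry pairwise contrast (up to `e^{2g}`) that a focal
caller cannot distinguish from loops — the demo reports these calls
honestly rather than suppressing them.

## Cross-stage machinery

Quantile normalization maps each matrix's stored nonzero banded pixel
multiset (zeros excluded by default, configurable) onto the average
sorted distribution, with tie-averaged ranks and quantile interpolation
for unequal supports; the difference map is then an entry-wise
subtraction.  Conserved regions slide a 2-Mb window in one-bin steps,
compute Pearson r over co-defined bins (windows with fewer than 3
skipped), keep windows with `r > 0.6`, and merge overlapping qualifying
windows into maximal regions annotated with the mean of their windows'
r — "mean correlation" is read as the mean over a region's contributing
windows, not a genome-wide reference.  Note on resolution: a 2-Mb window
holds only five 400-kb bins, and a 5-point Pearson r exceeds 0.6 by
chance ≈14% of the time under independence, so conserved-region scans in
this package are validated on 100-kb tracks (20 bins per window, chance
rate ≈0.3%); at 400-kb resolution the window should be widened or the
threshold raised.

Profile clustering uses `1 − Pearson r` distances and average linkage,
with samples sorted by name first so the tree is input-order invariant;
trees serialize to Newick.  Region overlap is an exact interval sweep in
base pairs.  Fisher enrichment builds the 2×2 table of universe bins by
(inside/outside regions) × (carrying/not carrying a feature), any
half-open overlap counting as containment, takes the two-sided exact p,
and BH-adjusts across a batch of feature sets when one is supplied; a
zero margin returns p = 1 with an undefined odds ratio.

## Determinism

Every stochastic step is seeded: simulation streams derive from the root
seed, the HMM initialization is deterministic and `random_state` is
pinned, and report floats are rounded to six decimals before JSON
serialization, so a demo run is byte-reproducible for a given seed.

## Problem sizes used in validation

The test and acceptance runs use 500-bin (20-Mb) chromosomes for
balancing, compartment and TAD checks, 1000-bin chromosomes for decay
exponents, three to five simulation seeds where averages are asserted,
and 2000-bin 100-kb tracks for conserved regions — sizes at which every
planted effect is comfortably detectable and the full suite runs in a
few minutes on one CPU.
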
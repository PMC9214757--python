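# hicogeny

Analysis of three-dimensional chromatin architecture from binned Hi-C
contact matrices, built for developmental series such as the maturation of
female germline stem cells (FGSCs) into GV, MI and MII oocytes.  The
package covers the full post-alignment workflow — matrix balancing,
distance-decay statistics, A/B compartments, topologically associating
domains (TADs), chromatin loops, and cross-stage comparison — together
with a synthetic contact-map generator that plants known structure so
every analysis stage can be validated against ground truth.

## Who this is for

Computational biologists who start from binned contact matrices (sparse
`bin_i bin_j count` text plus a BED4 bin table) and want a tested,
scriptable implementation of the standard Hi-C architecture statistics,
and method developers who need synthetic maps with planted compartments,
domains, loops and biases as benchmarks.

## The statistics at the core

* **ICE balancing.** Hi-C counts factor as `raw(i,j) = b_i b_j T(i,j)`
  with multiplicative per-bin biases `b`.  Iterative correction divides
  out row-sum imbalances until every unmasked row has equal coverage,
  returning the balanced map and the bias vector.
* **Contact decay P(s).** Mean balanced contact per valid pixel at each
  separation `s`, normalized to unit mass; a LOWESS fit of `log10 P` vs
  `log10 s` is differentiated to give the slope curve whose value
  diagnoses polymer state (a slope near −0.5 is fountain/mitotic-like,
  near −1 fractal-globule-like).
* **A/B compartments.** Per chromosome, the first principal component of
  the Pearson correlation matrix of the observed/expected (O/E) map
  assigns bins to A (PC1 > 0) or B (PC1 < 0), with the sign oriented
  against an activity track such as gene density.  Compartment strength is
  the saddle corner ratio `(AA + BB) / (AB + BA)` after ordering bins by
  PC1 quantile.
* **TADs.** The directionality index of a bin with upstream window sum `A`
  and downstream `B` is `DI = sign(B−A) · ((A−E)²/E + (B−E)²/E)` with
  `E = (A+B)/2`.  A 3-state Gaussian hidden Markov model over the DI track
  is Viterbi-decoded; a domain runs from the start of a downstream-bias
  run to the end of the next upstream-bias run, and inter-domain gaps
  under 400 kb are boundaries.  The insulation score (mean contact in a
  400-kb square sliding along the diagonal, log2 over the chromosome mean)
  provides an independent boundary track.
* **Loops.** A donut-style caller tests every cis pixel in a distance band
  against four local expected models (donut annulus, lower-left quadrant,
  horizontal and vertical stripes), converts the largest expectation to
  raw-count space through the ICE biases, applies a one-sided Poisson
  tail test with Benjamini–Hochberg control, and requires a minimum
  observed/expected fold enrichment.
* **Cross-stage comparison.** Quantile-normalized matrix subtraction
  (difference maps), sliding-window PC1 correlation (conserved compartment
  regions at `r > 0.6` in 2-Mb windows), average-linkage clustering of PC1
  profiles, and Fisher-exact enrichment of feature sets in region sets
  with BH adjustment.

## Worked example

Run the end-to-end demonstration: it simulates a two-chromosome genome
(2 × 500 bins of 40 kb) with planted 2-Mb compartment blocks at
log-contrast ln 2, tiling 20-bin TADs (enrichment 3×), six 8× focal
loops, log-normal per-bin biases (sd 0.3), then balances, transforms and
calls everything back, comparing each call with the planted truth:

```bash
hicogeny demo --seed 1 --out demo_out
```

prints (and writes to `demo_out/report.json`):

```json
{
  "compartment_label_accuracy": 1.0,
  "conserved_region_jaccard": 0.97561,
  "ice_bias_correlation": 0.999951,
  "loop_false_calls": 19,
  "loop_recall": 1.0,
  "n_bins": 1000,
  "n_conserved_regions": 2,
  "n_loops_called": 25,
  "n_tads_called": 60,
  "ps_mean_mid_slope": -1.01635,
  "saddle_strength": 2.260157,
  "seed": 1,
  "tad_boundary_f1": 0.829268
}
```

Reading the numbers: every compartment bin is labelled correctly
(`compartment_label_accuracy` 1.0); recovered ICE biases correlate with
the noise-free reference at r ≈ 0.99995; the mid-range log–log decay
slope ≈ −1.02 recovers the planted exponent α = 1; domain edges are
recovered at F1 ≈ 0.83 within ±1 bin; all six planted loops are found
(`loop_recall` 1.0 — the 19 extra calls sit at the sharp planted
compartment-block corners, where the synthetic pairwise contrast rivals
focal-loop enrichment; see `docs/methods.md`); and the conserved-region
scan recovers the planted correlated blocks at base-pair Jaccard ≈ 0.98.
`demo_out/` also contains the matrix, PC1/DI/insulation bedGraphs, TAD
BED and loop BEDPE files.

Every stage is also exposed individually (`hicogeny simulate`, `balance`,
`oe`, `ps`, `slope`, `cisfrac`, `transpairs`, `compartments`, `saddle`,
`abswitch`, `di`, `tads`, `insulation`, `tadswitch`, `loops`,
`deconvolve`, `conserved`, `cluster`, `enrich`) and as plain library
functions under `hicogeny.*`.

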
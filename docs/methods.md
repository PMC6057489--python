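# Methods

This note documents the models, conventions and numerical choices behind
`atacdyn`, and what the synthetic-data generator does and does not emulate.

## Coordinates and interval conventions

All coordinates are 0-based, half-open (`[start, end)`, the BED convention);
any 1-based display would be formatting only. Consequences used throughout:

* Abutting intervals do not overlap; their edge-to-edge distance is 0.
  "X bp away" always means the gap between nearest edges, not a midpoint
  difference — so the 5-kb new-peak rule reads "no base of the new peak is
  within 5,000 bp of any base of a pre-existing peak".
* The TSS of a minus-strand gene is `end - 1`, the last covered base.
* Distances between features on different chromosomes are *absent* (`None`
  in scalar APIs, `inf` in vectorised internals, with such entries excluded
  and counted in summary statistics) — never a large sentinel that could
  silently distort a mean.

## Enrichment model

Fold enrichment of a peak set in a region class compares the fraction of
peaks overlapping the class (≥ 1 bp overlap; summit position is ignored)
with the class's share of the genome, so uniformly placed peaks have
expected fold 1 and the all-genome class has fold exactly 1. Class intervals
are merged per class before bp bookkeeping; per-region statistics (the
fraction of individual TSS windows containing a peak) use the unmerged,
per-gene windows.

The significance model is a hypergeometric test on a binned genome: the
genome is tiled left-to-right into bins of the peak set's median width
(overridable), the population is all bins, successes are bins touching the
class, draws are the peaks, and the observed count is the number of peaks in
the class; the reported p is the upper tail. The binning makes the
population finite and roughly matched to the granularity of a peak; under
uniform placement the empirical type-I error at α = 0.05 is at the nominal
rate (a test simulates 1,000 uniform peak sets). The test treats peaks as
independent draws, which is the usual — and slightly anticonservative —
idealisation for interval data; we therefore use it as a ranking/screening
statistic, as is standard for genomic-region enrichment.

`build_tss_windows` defaults to ±1,000 bp around the TSS (window width
2,001 bp, clipped at chromosome edges). The width is a configuration knob;
the synthetic generator's planted TSS class uses a 1-kb total window
(±500 bp) so that, on its deliberately miniature genome (10 Mb, 500 genes),
the class occupies ~5% of the genome and a planted fold of 15 is attainable
(the attainable ceiling is `G / bp(C)`; with ±1,000 bp windows on a 10-Mb
miniature the ceiling would be ~10). On a genome-scale dataset the two
window choices are both far from the ceiling and the distinction is
immaterial.

## Two-condition dynamics

`find_new_peaks(after, before, min_dist=5000)` partitions the after set by
the edge-gap rule; peaks on chromosomes with no before peaks are vacuously
new, and the symmetric operation defines lost peaks. Distal new peaks
additionally overlap no gene body and lie ≥ `min_dist` from every TSS.
`genes_gaining_peak` uses an association region of gene body ± 1,000 bp by
default (configurable); a gene qualifies if it has no before peak but ≥ 1
after peak there. Mean distance-to-TSS is the arithmetic mean over peaks of
the point-to-interval distance to the nearest TSS.

Positional shift detection pairs after peaks to before peaks greedily by
increasing midpoint distance within a cutoff, each peak used once, ties
broken leftmost-first; the signed offset is after-midpoint minus
before-midpoint. Greedy pairing is deterministic and cheap; it is not
guaranteed to minimise the total pairing distance (a three-peak
counterexample exists even with distinct distances), which is acceptable
because the shift analysis is a qualitative summary — the tests pin down the
greedy contract (ordering, single use, determinism), not optimality.

## Accessibility–expression link

Per-gene accessibility is the count of fragment *midpoints* in
`[tss - w/2, tss + w/2)` divided by the (clipped) window width, with
w = 1,000 bp by default. Midpoint density, rather than per-base pileup,
approximates transposition-site density and makes conservation invariants
exact (row sums of the TSS matrix equal window counts). The window is
strand-symmetric, so strand affects only the orientation of metaprofile
matrices, never the scalar coverage.

Group comparisons use the two-sided Mann-Whitney U test: the exact null
distribution when both groups have ≤ 20 observations and no ties, otherwise
the tie-corrected normal approximation with continuity correction. Two
identical constant samples return p = 1 with a flag. Across requested
category pairs, Benjamini–Hochberg adjusted p-values are reported alongside
raw ones; the adjustment is a conservative addition for multi-pair runs.

Expression calls are accepted either as booleans or as abundances with a
threshold (default 1.0 abundance unit — the analysis is threshold-agnostic;
callers with calibrated units should supply their own). The "pre-opened"
statistic is the fraction of newly activated (only-after) genes whose
TSS ± 1 kb overlaps ≥ 1 donor-condition peak.

## Motif analysis

JASPAR count matrices are normalised per position with a pseudocount of
0.01 and scored as log2(p/background) with a uniform background by default
(overridable with genome-estimated composition). A window containing any
non-ACGT base is skipped rather than scored, avoiding background bias at
assembly gaps. Both strands are scanned; a sequence "has" a motif if any
window reaches the threshold, which defaults per motif to 80% of its maximum
attainable score. Differential enrichment between two peak-sequence sets is
per-peak presence/absence in a 2×2 table, two-sided Fisher exact p,
Haldane-corrected odds ratio when a cell is zero, BH across motifs. The
bundled `data/synthetic_motifs.jaspar` is a synthetic example set (count
matrices written for this package, with consensus sequences resembling
well-known factors) used by the generator and the tests; real analyses
should supply real JASPAR matrices.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, on a
miniature genome, with ground truth for every planted entity. Defaults (the
study conditions of the test suite): two 5-Mb chromosomes; 500
non-overlapping genes of 2–20 kb (uniform) with random strands; 100
enhancers ≥ 5 kb from every TSS; 2,000 peaks per condition of width
200–800 bp; planted TSS fold 15 concentrated on an "accessible" 40% of
genes (echoing the ~40% of TSSs containing peaks in real myoblast data);
15% of after peaks newly opened under the 5-kb rule, 40% of those distal
(the ratio observed in the reprogramming data this pipeline targets);
expression coupled to donor openness (P(expressed) 0.8/0.2 before and
0.7/0.15 after for open/closed TSSs); a planted pre-opened fraction
q = 0.56; coverage effect 3 for open TSSs; background 200 fragments/Mb,
20 fragments per closed 1-kb TSS window, 10 per TSS-distal peak; fragment
lengths a sub-/mono-nucleosomal mixture (cosmetic realism only).

Mechanics worth knowing:

* **Planted fold.** Before peaks are a mixture: with probability `p_tss` the
  midpoint falls in a TSS window of an accessible gene, else uniform.
  `p_tss` is solved from `p + (1-p)·u = fold · bp(C)/G`, where `u` accounts
  for uniform peaks grazing the (width-dilated) class, so the measured fold
  matches the target in expectation; infeasible folds fail loudly.
* **New peaks.** After peaks are a jittered (± 300 bp) retained subset of
  before peaks plus rejection-sampled new peaks verified ≥ 5 kb from every
  before peak (attempt-capped; failure is loud, never silently relaxed), so
  planted labels are exactly recoverable by `find_new_peaks`.
* **Exact q.** The activated set is subsampled from only-after genes in the
  exact open:closed ratio of q (via its reduced fraction), demoting the
  rest to "neither"; `n_activated_max` optionally caps the set at a target
  size, and `pre_opened_fraction=None` disables the subsampling where the
  statistic is irrelevant. Infeasible q (too few open or closed candidates)
  raises with the attainable counts.
* **Coverage.** Open-gene TSS windows receive `coverage_effect ×` the closed
  fragment rate; peaks overlapping a TSS window contribute no separate
  fragments, so the realised open/closed coverage ratio equals the
  configured effect (within Poisson noise) and the effect=1 null leaves the
  coverage distribution independent of openness — the generator can falsify
  as well as confirm.
* **Motifs.** The consensus of one PWM is written at peak centres with
  set-specific probabilities. Because retained peaks share sequence with
  their before-condition counterparts, differential planting is done into
  the *newly opened* after peaks versus the before peaks; overlapping
  plantings are skipped and recorded.
* **Determinism.** One master seed spawns independent per-stage streams
  (genome, annotation, peaks, expression, fragments, motifs); identical
  seeds give byte-identical outputs, and stages can be regenerated
  independently.

What the generator does **not** emulate: read-level artefacts (sequencing
errors, duplicates, mitochondrial contamination), Tn5 sequence bias,
replicate structure, realistic gene/peak length distributions, or linkage
between neighbouring genes. Passing tests therefore demonstrate that the
*statistics and rules* behave as specified under their assumptions, not that
the pipeline is robust to every artefact of real libraries.

## Problem sizes in the test suite

The suite runs entirely on generated data sized for a laptop: the main
configuration is the 10-Mb default above; the dynamics rules are checked
over 50 seeds at 400 peaks/condition on 4 Mb with exhaustive pairwise
verification; the coupling analysis uses 3,200 genes on 72 Mb so the
only-after category holds exactly 200 genes, with 100 effect-size seeds and
600 null replicates for the type-I check; motif recovery uses 50 seeds of
200-peak disjoint sets on 4 Mb. These sizes were chosen as the smallest at
which the planted effects are identifiable with comfortable margins.

## Known limitations

* The hypergeometric enrichment test ignores peak-width heterogeneity
  beyond the median-width binning.
* Quantitative differential accessibility (count-based GLMs within shared
  peaks) and replicate-aware reproducibility are out of scope; the dynamics
  layer is presence/absence with a distance rule.
* The motif layer does presence/absence enrichment only — no de novo
  discovery, redundancy collapse, or footprinting.
* Cross-sample coverage values are not depth-normalised; comparisons within
  one sample are well-defined, cross-sample comparisons need caller-supplied
  scaling.
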
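# atacdyn

Tools for analysing changes in chromatin accessibility between two
conditions from ATAC-seq peak calls — the setting where a somatic genome is
profiled before and after a reprogramming perturbation (e.g. nuclear
transfer into an oocyte) and the question is *which* regulatory regions
open, close, or stay open, and how that relates to transcriptional
activation.

The package takes standard flat files (chrom-sizes, BED/narrowPeak peaks, a
tabular gene model, fragment BED, expression calls, FASTA, JASPAR PWMs) and
provides:

* **Peak annotation with whole-genome-relative enrichment.** For a region
  class *C* (TSS windows, enhancers, histone-mark domains, …) covering
  `bp(C)` of a genome of `G` bases, a peak set with `k` of `n` peaks
  overlapping *C* has fold enrichment

  ```
  fold = (k / n) / (bp(C) / G)
  ```

  so uniform placement gives fold 1. Significance comes from a
  hypergeometric test on a binned genome (population = all bins of the peak
  set's median width, successes = bins touching *C*, draws = peaks).
* **Two-condition dynamics.** A peak present after the perturbation is
  *newly opened* iff its edge-to-edge gap to every pre-existing peak is
  ≥ 5,000 bp. Derived sets: retained, lost, and *distal new* peaks
  (intergenic, ≥ 5 kb from every TSS and pre-existing peak); genes gaining a
  peak; mean distance-to-TSS statistics; peak-count ratios; positional-shift
  offsets between paired peaks.
* **Accessibility–expression coupling.** Genes are partitioned by
  expressed/not calls in the two conditions into {both, only_before,
  only_after, neither}; per-gene accessibility is the fragment-midpoint
  density in a 1-kb window centred on the TSS; categories are compared by
  the two-sided Mann-Whitney U test (exact for small tie-free groups) with
  Benjamini–Hochberg adjustment, plus the fraction of newly activated genes
  whose TSS was already open in the donor condition.
* **Differential motif enrichment.** PWMs (JASPAR count matrices) are scored
  as log2-odds against background on both strands; per-peak presence/absence
  between two peak sets is tested with the two-sided Fisher exact test, BH
  adjusted across motifs.
* **A seeded synthetic-data generator** that plants all of the above
  (TSS-window fold, new peaks under the 5-kb rule, openness-coupled
  expression with an exact pre-opened fraction, coverage effects, motif
  occurrences) with a full ground-truth record, so every stage is testable
  offline.

## Worked example

Generate a synthetic dataset and run the full pipeline:

```bash
atacdyn simulate --outdir data --seed 123
cat > data/run.yaml <<'YAML'
inputs:
  chrom_sizes: genome.chrom.sizes
  peaks_before: peaks_before.narrowPeak
  peaks_after: peaks_after.narrowPeak
  genes: genes.tsv
  catalog: {enhancer: enhancers.bed}
  expression: expression.tsv
  fragments_before: fragments_before.bed
  fasta: genome.fa
  pwms: motifs.jaspar
outdir: results
YAML
atacdyn run-all --config data/run.yaml
```

Or drive the same stages from Python:

```python
from atacdyn import (SyntheticConfig, generate_dataset, build_tss_windows,
                     RegionCatalog, fold_enrichment, find_new_peaks,
                     mean_tss_distance)

cfg = SyntheticConfig(seed=1)          # 10-Mb genome, 500 genes, 2,000 peaks
ds = generate_dataset(cfg)
windows = build_tss_windows(ds.genes, ds.genome, cfg.tss_window_half)
catalog = RegionCatalog.from_intervals(ds.genome, {"tss": windows})
res = fold_enrichment(ds.peaks_before, "tss", catalog, per_region_intervals=windows)
print(f"TSS fold {res.fold:.1f}, p = {res.p_value:.2g}, "
      f"{res.fraction_regions_hit:.0%} of TSS windows hit")
new, _ = find_new_peaks(ds.peaks_after, ds.peaks_before)
print(f"{new.count()} newly opened peaks; mean TSS distance "
      f"{mean_tss_distance(new, ds.genes).mean_bp:.0f} bp vs "
      f"{mean_tss_distance(ds.peaks_after, ds.genes).mean_bp:.0f} bp for all")
```

which prints (seed 1):

```
TSS fold 15.0, p = 0, 44% of TSS windows hit
300 newly opened peaks; mean TSS distance 10338 bp vs 3223 bp for all
```

The planted fold of 15 is recovered; newly opened regions are, as planted,
several-fold more distal from promoters than the peak population at large.

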
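# inflammeth

Epigenome-wide analysis of DNA methylation in chronically inflamed versus
healthy tissue, for epigenomics researchers working with 450K-style
beta-value arrays, ENCODE-style peak/DNase data and RRBS methylation calls.

Chronic inflammation leaves a DNA-methylation footprint that preferentially
hits distal regulatory elements. This package implements the computational
pipeline for characterising that footprint:

1. **Differential methylation** (`DifferentialMethylation`): per-probe
   Δβ = mean(case) − mean(control) with a two-sided Welch t-test and
   Benjamini–Hochberg FDR; a probe is hypermethylated when q < 0.05 and
   Δβ > 0.15, hypomethylated when q < 0.05 and Δβ < −0.15.
2. **Permutation enrichment** (`PermutationEnrichment`): overlap of a
   differential probe set with a feature set (ChIP-seq peaks, DHS, CpG
   islands…) scored against 1,000 random draws of equal-sized probe sets
   from the full array; Z = (obs − mean₀)/sd₀ with an add-one empirical p.
3. **Enhancer→gene linking** (`EnhancerLinker`): putative enhancers are DHS
   without H3K4me3; targets are DHS within ±500 kb whose cross-cell-line
   DNase signal correlates with the enhancer at r² ≥ 0.7, assigned to a gene
   when they fall within ±2.5 kb of its TSS.
4. **Cross-cohort directional overlap** (`DirectionalOverlap`): upper-tail
   hypergeometric test of the overlap between hyper/hypo probe sets of two
   cohorts, on the universe of probes tested in both (log-space tails, exact
   at p ≈ 1e-200).
5. **Context statistics** (`methyl_context_stats`): RRBS coverage filtering
   (≥5X), methylation-vs-binding-peak partition with two-sample
   Kolmogorov–Smirnov testing, MS-HRM Fisher exact / bin midpoints, Spearman
   and Mann–Whitney comparisons, expression-table joins.
6. **Synthetic data** (`synthetic_data`): deterministic generator for all of
   the above with planted ground truth (differential probes, enriched
   features, enhancer–promoter pairs, methylation/occupancy exclusivity),
   so every stage is testable end to end without downloads.

## Worked example

```python
import inflammeth as im
from inflammeth.synthetic_data import SyntheticConfig, generate_bundle

bundle = generate_bundle(SyntheticConfig(seed=1))       # 10,000 probes, 19 vs 23 samples
dm = im.DifferentialMethylation().fit(bundle.betas, bundle.groups)
print(dm.counts_)
# {'hyper': 500, 'hypo': 500, 'unchanged': 9000}

sets = dm.probe_sets()
report = im.enrich_report(sets, bundle.feature_sets, bundle.manifest,
                          im.PermutationConfig(n_perm=1000, seed=7))
print(report[["probe_set", "feature", "observed", "z", "direction"]].head(2))
#   probe_set     feature  observed          z direction
# 0     hyper  enriched_0       265  25.509217  enriched
# 1      hypo  enriched_0        63  -1.379020      none
```

The bundle plants 500 hypermethylated and 500 hypomethylated probes with
|Δβ| = 0.25; the caller recovers them at the q < 0.05, |Δβ| > 0.15
thresholds (counts above). The feature set built to cover hyper probes 5×
more often than background comes out strongly enriched (Z ≈ 26) while the
hypo set does not. The same bundle carries 50 planted enhancer–promoter
signal pairs (`im.EnhancerLinker().fit(bundle.anchors, bundle.signal,
bundle.target_genes)` recovers them at r² ≥ 0.7) and an RRBS table whose
in-peak CpGs are unmethylated (mean β ≈ 0.09).

The same pipeline runs from the shell on TSV/BED inputs:

```sh
inflammeth synth-data --seed 1 --out bundle/
inflammeth run-all --config run.yaml     # see docs/methods.md for the config keys
```

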
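# Methods

## Coordinates and annotation

All internal coordinates are 0-based half-open (BED convention); array-style
manifests supplied 1-based are converted on read (`manifest_base=1`
default). A CpG probe is a single base position — the interrogated
cytosine — not a ±50 bp probe body; overlap with a peak means that base
falls inside the interval. Strand is ignored for probes and used only to
place a gene's TSS.

CpG-island context partitions probes by distance to the nearest island:
island (0), shore (≤2 kb), shelf (2–4 kb), open sea (>4 kb). Only the open
sea bound is part of the analysis definition; the shore/shelf split follows
the standard Illumina convention. Gene context uses strict precedence
promoter (±2.5 kb of any TSS) > exon > intron > intergenic. Distance to a
feature is `pos − end` to the right of a half-open interval and
`start − pos` to the left; nearest-feature ties are broken by taking the
minimum distance, which is side-independent and deterministic.

Interval queries use per-chromosome arrays sorted by start with a running
maximum of interval ends, giving O(log n) point/interval stabs and distance
queries that are verified against all-pairs scans in the test suite.

## Differential methylation

Per probe, the effect is Δβ = mean(case β) − mean(control β) with missing
values dropped per group; significance is a two-sided Welch t-test on beta
values, corrected by Benjamini–Hochberg across all tested probes in one
batch. The underlying test is deliberately isolated behind one function:
beta values are bounded and heteroscedastic, Welch is the simplest
defensible default, and a Wilcoxon rank-sum variant is selectable
(`test="wilcoxon"`) for heavy-tailed cohorts. Calling thresholds are
q < 0.05 and |Δβ| > 0.15, strict on both sides.

Degenerate inputs follow fixed conventions: both groups constant and equal
→ p = 1; constant and different → p = 0; a probe with fewer than two
observed values in either group is reported untested (NaN statistics,
label `unchanged`). M-value transformation, array normalisation and batch
correction are out of scope — inputs are assumed to be normalised betas.

## Permutation enrichment

For a probe set of size k, each of n_perm (default 1,000) replicates draws
k distinct probes uniformly without replacement from the full manifest and
counts feature overlaps. The background is the whole array: no matching on
CGI content or chromosome, because the analysis this emulates permutes
plainly across the array. Z uses the sample standard deviation of the
null; the empirical p is the add-one estimator
(1 + #{null ≥ obs})/(n_perm + 1), never exactly 0; a direction
(enriched/depleted) is called at p < 0.05. A feature set whose null is
degenerate (sd = 0) is flagged and gets no direction. Each feature set
consumes its own RNG stream (`seed + index`), so reports are reproducible
and independent of evaluation order.

## Enhancer→gene linking

Putative enhancers are DHS with zero bp overlap with H3K4me3; a
"hypermethylated enhancer" contains ≥1 hypermethylated probe. For an anchor
enhancer, candidate targets are signal-matrix sites on the same chromosome
with midpoint within ±500 kb of the anchor midpoint (midpoint-to-midpoint
distance; the window edge rule is configurable). Pairs with Pearson
r² ≥ 0.7 across cell lines are emitted, sorted by descending r²; a target
is assigned to the nearest gene whose TSS is within ±2.5 kb of the target
midpoint, ties broken lexicographically by gene id. The anchor is matched
to the unique signal-matrix site that overlaps it (greatest overlap wins;
no overlap is an error). Correlation is computed on raw signal by default;
`log1p=True` is available because DNase signal is heavy-tailed, and the two
options bracket the plausible preprocessing of the published analyses.
Constant-signal sites have undefined correlation and are excluded.

## Cross-cohort overlap

Both cohorts are labelled with identical thresholds; the universe is the
intersection of probes tested in both (the "probes with available data"
convention), not the whole array. Each of the four direction pairs gets an
upper-tail hypergeometric p computed in log space (gammaln-based log pmf +
logsumexp), which remains accurate at the extreme depths concordant cohorts
reach (p ≈ 1e-200). No multiple-testing correction is applied across the
four cells; the raw probabilities are reported.

## Context statistics

RRBS records are filtered at ≥5X coverage (inclusive), partitioned by
binding-peak overlap, and compared by a two-sided two-sample
Kolmogorov–Smirnov test with the asymptotic p (the analyses this targets
operate at 10⁵–10⁶ CpGs, where the asymptotic form is exact for practical
purposes; no small-sample mode). MS-HRM categories use the printed bins
(0–5, 6–10, 11–25, 26–50 % methylation) with midpoints equal to the mean of
the bin edges (0–5 % → 2.5 %). The Fisher test dichotomises samples to
unmethylated (0–5 % bin) versus any methylation; with the published cohort
counts this is the 41 vs 3 / 23 vs 23 table — note the source text is
internally inconsistent about the healthy row (41/44 unmethylated yet
"4 samples gained 6–10 %"); 41 vs 3 is used so the row sums to n = 44.
Spearman uses mid-ranks for ties; Mann–Whitney uses exact enumeration when
n·m ≤ 400 without cross-group ties and the tie-corrected normal
approximation otherwise. The expression join labels linked genes
down/up-regulated at adjusted p < 0.05 and flags (never drops) genes absent
from the expression table.

## Synthetic data generator

The generator emulates the study design end to end on one synthetic
chromosome per data type (array, linking, RRBS — interval logic is
chromosome-agnostic). Defaults: 10,000 probes on 10 Mb; 19 case vs 23
control samples; 5 % planted hyper + 5 % hypo probes at |Δβ| = 0.25;
Beta-distributed noise parameterised by (mean, concentration) with
concentration 50 (per-value sd ≈ 0.06–0.07, the scale of replicate scatter
on methylation arrays); one feature set covering background probes at rate
0.10 and planted-hyper probes at 5× that rate, plus one null set; 50
planted enhancer–promoter pairs sharing Gamma latent activity across 100
cell lines calibrated to true r = 0.9, with 500 independent decoy DHS
inside the same ±500 kb windows; RRBS with ~50 % of CpGs inside binding
peaks and full methylation/occupancy exclusivity; 20 % of RRBS records
below 5X to exercise the coverage filter.

Baseline probe means are bimodal (Beta(2,10) / Beta(10,2) mixture). Planted
hypermethylated probes draw their baseline from the low mode and
hypomethylated probes from the high mode: regulatory elements that gain
methylation in disease start out unmethylated in healthy tissue, and this
keeps the planted effect honest — the +0.25 shift rarely hits the [0,1]
boundary. Out-of-range shifted means are clipped (to [0.02, 0.98], keeping
Beta shape parameters positive) and counted, not resampled. Feature
intervals are probe-centred (±100 bp) but clipped at neighbouring probe
positions, so per-probe coverage follows the configured rate exactly.

Everything is deterministic given the config seed; each generator consumes
an independent named RNG stream, so regenerating one artifact never
perturbs another. The generator does not emulate: probe cross-reactivity or
SNP-in-probe artifacts, array batch effects, chromosome-level covariation,
read-level bisulfite data, or biological correlation between neighbouring
CpGs. Passing recovery tests therefore demonstrate correctness of the
statistical machinery under the declared noise model, not robustness to
those real-data complications.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the generator at its default
scale (10,000 probes; 200 null calibration runs and 100 planted-power seeds
at 1,000 permutations each; 13,000 RRBS CpGs giving ≥5,000 per arm), which
keeps a full run around a minute while leaving the permutation and
hypergeometric tails well resolved. The hypergeometric tail is summed in
log space; BH q-values come from the step-up formula (verified against a
hand implementation); empirical p-values are add-one; all permutation
draws use Gumbel-top-k argpartition for vectorised without-replacement
sampling.

## Pipeline orchestration

`inflammeth run-all --config run.yaml` executes differential calling →
permutation enrichment → linking → optional cohort overlap → RRBS/expression
statistics. Config keys are the `PipelineConfig` fields (paths: `betas`,
`samples`, `manifest`, `features`, `anchors` or `dhs`+`h3k4me3`, `signal`,
`genes`, `rrbs`, `binding_peaks`, `expression`, optional `truth`;
parameters: thresholds, permutation and linking settings). All inputs are
validated before any computation; a provenance file records the config, its
hash, the seed and per-stage row counts, and a rerun with the same config
is byte-identical. When a truth file is supplied, a recovery report
(sensitivity/precision per stage) is embedded in the provenance.

## Known limitations

- The per-probe test and FDR flavour of the emulated published analysis are
  unstated there; Welch + BH is this package's explicit choice, and exact
  reproduction of published probe counts may depend on that choice.
- Enrichment uses probe permutation only; GC/length-matched feature
  randomisation is a non-goal.
- The asymptotic KS p is inaccurate below ~50 observations per arm.
- Anchor matching requires the enhancer to be (or overlap) a signal-matrix
  site, as the linking design assumes.
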
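# Methods

This note documents the models behind `regulonforge`: what each stage
assumes, which parameters matter, what the synthetic generator does and does
not emulate, and the numerical choices made where the procedure was open.

## The inference pipeline

### Motif activity and TF roles

Accessibility counts per cell and peak are capped at 4 on load; a cell's
expected count in a motif's peak set is its total count times the peak set's
share of all-cell counts, and the raw deviation is the relative excess over
that expectation. Deviations are standardized per motif against 50 background
peak sets, each drawn (with replacement) from the 50 nearest peaks of every
motif peak in standardized (GC fraction, mean accessibility) space; a peak may
serve as its own background. Cells with zero total counts are an error (the
expectation is undefined); motifs matching no peak are dropped with a
warning.

TF–motif pairs are classified by single-cell Spearman correlation (average
ranks for ties) between library-size-normalized log1p TF expression and motif
z-scores: strictly above +0.05 → activator, strictly below −0.05 → repressor,
otherwise discarded. At n cells the null standard error of ρ is ≈ 1/√(n−1),
so at 1,000 cells pure sampling noise already places ~11% of null pairs
outside ±0.05; the cutoff is a deliberate low bar that downstream sign- and
importance-filters tighten.

### Peak categorization and peak-to-gene links

Priority promoter > gene body > intergenic. The promoter window is TSS ± 500
bp inclusive; intergenic candidates are all genes with TSS within 200 kb of
the peak center (the anchor point had to be chosen; the center is used). A
peak overlapping two TSS windows is a promoter of both genes.

Metacells are k-means groups (default 100) in a combined reduced space:
truncated SVD of log-normalized RNA (15 dims) concatenated with TF-IDF + SVD
of the peak matrix (15 dims), columns standardized. Candidate pairs are
tested by Pearson correlation of within-metacell mean normalized
accessibility and expression; BH adjustment is applied jointly across all
tested pairs, and links are retained at |r| > 0.25 and FDR < 0.01 (strict).
Averaging ~10–20 cells per metacell suppresses count noise while preserving
the shared regulatory signal, which is what makes the 0.25 cutoff attainable
for genuine links.

### TF binding sites and footprints

PWM log-odds are base 2 against the motif's background distribution with a
1e-4 pseudocount per cell (so zero-probability bases stay finite). The match
threshold for a tail probability p is computed exactly by dynamic programming
over the score distribution discretized to 1e-3 log-odds bins; enumeration
over all k-mers agrees within the rounding window of that discretization.
Scanning reports every window on both strands at or above the threshold;
windows containing N are skipped, and reverse-strand matches are scored on
the reverse complement but reported in forward coordinates.

The footprint statistic is NL + NR − 2·NC with NC the mean corrected
insertion signal over the motif's L bases and NL/NR the means over 3·L-base
flanks; flanks truncated by the peak edge use the available bases, and a site
whose flank is entirely missing is dropped. Retention is strictly score >
0.1. "Expressed in MG cells" is operationalized as detection (count > 0) in
≥ 5% of cells across the MG-lineage groups — the requirement is stated
without a threshold anywhere, and 5% is the conventional detection floor.

### TF–target edges

One LightGBM regression ensemble per target gene on all TF columns (a TF
never predicts itself). Module defaults are GRNBoost-like (500 trees,
learning rate 0.01, 90% row subsampling, no early stopping); the end-to-end
pipeline uses 150 trees at learning rate 0.1 — recovery on planted data is
insensitive to this choice within wide margins and it keeps one model per
gene per condition cheap. Importance is the summed split gain; the filter
keeps edges at or above the 90th quantile (linear interpolation) of the
pooled importance vector — pooled globally rather than per target, reading
"the 90th quantile" as one number (a per-target variant would change which
weakly-driven targets survive). Signs come from Pearson r on the same
normalized matrix: strictly above +0.03 positive, strictly below −0.03
negative, otherwise dropped.

### Assembly, sub-networks, key activators

Triples form by joining footprint-retained (TF, peak) sites with retained
(peak, gene) links; retention then requires (1) a surviving signed edge whose
direction matches the TF's role — the stricter of two possible readings; a
correlation-only variant can be had by passing unfiltered edges — (2) the TF
marker-enriched (log2FC > 0.25, adj-p < 0.05, Wilcoxon) in ≥ 1 MG group,
and (3) duplicate collapse keeping the maximum footprint score. Assembly is
order-independent by construction (stable sorts, deterministic tie-breaks).

A condition-enriched sub-network keeps a triple when the TF is significantly
higher in the focal condition (lower for repressors) in ≥ 1 of the MG-group
comparisons (DEG thresholds), the peak is not significantly lower in any
group (the accessibility rule operates on raw p < 0.05 with |log2FC| > 0.25),
and the target is significantly higher in ≥ 1 group. Missing DE records count
as "no change".

Key activators: negative regulations are removed first; for a TF and a DEG
cluster, the population is the TF's targets in the total network (N), the
successes those also in the cluster, the sample its targets in the enriched
sub-network, and p = P(X ≥ q) (upper tail, observed overlap included, as the
procedure ranks for enrichment). Coverage is q divided by the cluster size,
with q counted on sub-network targets — consistent with the sample
definition. Thresholds p < 0.001 and coverage > 0.01, both strict, no further
multiple-testing correction. A TF whose total-network targets all lie inside
the cluster is, by design of the test, uninformative (p = 1): the statistic
rewards sub-network specificity, not raw overlap.

### Differential and consensus calls

The DE engine is a two-sided Wilcoxon rank-sum test (tie-corrected asymptotic
p) with BH adjustment; log2FC = log2((μ_A + 1)/(μ_B + 1)) on de-logged
normalized means. DEGs: |log2FC| > 0.25 (between injury conditions) or > 0.5
(injury vs development) and adj-p < 0.05, with mature-neuron markers
(control cells, per mature group vs rest, log2FC > 2, adj-p < 0.05) removed.
DARs deliberately use **raw** p < 0.05 with |log2FC| > 0.25 — the one rule in
the scheme on unadjusted p — and must have ≥ 1 DEG target. Consensus calls
require passing in both datasets for the same group; consensus peaks must
link to consensus genes, consensus motifs must belong to consensus-gene TFs
with only the highest-correlation motif kept per TF.

Differential motifs use a logistic-regression likelihood-ratio test (group
membership on motif score plus covariates vs covariates only; default
covariate is log total counts per cell), chi-square with 1 df; motif fold
changes are computed on scores shifted by the global minimum + 1 because
z-scores are signed — this fold change is a reporting convenience, not an
inherited definition. Non-converged (quasi-separated) fits keep their
deviance-based p and are flagged.

Trajectory profiles: equal-frequency pseudotime bins (20–50; default 20 in
the pipeline), per-bin means, centered rolling-mean smoothing (window 3,
edge bins use available neighbors), per-feature z-scaling (constant profiles
flagged and left at zero). For DEG clustering across conditions the pipeline
bins each condition separately, concatenates the smoothed profiles, and
z-scales across the concatenation — scaling per condition first would erase
exactly the between-condition differences the clusters are meant to capture.
k-means uses 20 restarts with a fixed seed; k defaults to the number of
conditions.

## The synthetic multiome generator

Each TF carries a per-cell latent activity z = group pattern + N(0, 1); the
TF's expression responds with 0.8·z on the log-mean scale (plus a direct
+0.5 ln boost in its high MG group, which keeps TFs marker-detectable after
library-size normalization shrinks group differences by composition), while
its planted peaks and targets respond with sign · coupling_strength · 1.2·z.
The response scale (coupling_scale = 1.5, i.e. 1.2 log-units at coupling 0.8)
was fixed so that "coupling" carries its operational meaning: planted
peak–gene links are recoverable across 100 metacells at coupling ≥ 0.7, and
at coupling 0 all planted couplings vanish — condition fold changes of
responsive targets and peaks are multiplied by coupling_strength because the
response is TF-mediated.

Counts are negative binomial (variance = μ + 0.4·μ²) with log-normal(0, 0.3)
per-cell size factors; peak counts are capped at 4. The genome is a single
chromosome with genes tiled every 50 kb (2 kb bodies, alternating strands),
planted peaks 3 kb upstream of their target's TSS, and background peaks tiled
at 13 kb in intergenic space — 501 bp fixed width and ≥ 1 kb gaps hold by
construction. One TF's target genes are scheduled ≥ 5 gene slots (250 kb)
apart so that a planted peak never sits inside the 200 kb candidate window of
the same TF's other targets; closer spacing produces *bona fide* cross
peak–gene correlations that the bookkeeping would count as false positives.

Condition-enriched TFs (3 per condition by default) receive a +1.0 ln
expression boost in their condition; half of each one's 20 targets respond
(+coupling·1.0 ln, peaks +coupling·0.5 ln) and define that condition's DEG
cluster in the ground truth. Four TFs act as repressors (negative coupling
throughout). Every planted (TF, peak) hit dips the insertion signal over the
motif center by footprint_depth relative to the flat base level 1.0
(noise SD 0.05); two decoy hits per TF land in background peaks without a
dip, exercising the footprint filter's specificity. Pseudotime is uniform
within cell groups ordered resting glia → activated glia → progenitors →
precursors.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, read-level artifacts, realistic motif sequence composition inside peaks,
chromatin-domain correlation between neighboring peaks, or empirically
calibrated noise levels (the dispersion and noise defaults are conventional
choices, exposed in `SimulationConfig`, not estimates from real data).
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted structure under idealized noise — not performance
on real tissue.

## Problem sizes and determinism

The validation suite runs the full pipeline on 2 × 1,000 cells, 20 TFs, 200
genes, 500 peaks and 160 planted triples for five seeds, and scales unit
fixtures down to a quarter of that (with proportionally stronger group
structure and coupling, since detection power falls with cell count). All
randomness flows from explicit integer seeds: the generator from
`SimulationConfig.seed`, k-means/SVD/background sampling/LightGBM from the
pipeline seed (LightGBM runs single-threaded deterministic). Identical seeds
give bit-identical outputs.

## Known limitations

- The Spearman ±0.05 role cutoff is noise-dominated at typical cell counts;
  roles should be read jointly with the edge sign filter.
- Peak-to-gene links are correlational across metacells and inherit any
  group-level confounding; the generator's planted-spacing rule sidesteps the
  equivalent confound rather than modeling it away.
- Gain-based importances are scale-dependent; the global 90th-quantile filter
  behaves well when a substantial fraction of targets are genuinely driven,
  and degrades toward arbitrary selection on pure-noise panels.
- The hypergeometric key-activator test conditions on the assembled networks;
  its p-values are enrichment scores, not calibrated error rates over the
  whole pipeline.
- Consensus/differential rules mix adjusted and raw p-values exactly as
  specified (DARs and consensus peaks on raw p); this asymmetry is faithful
  but statistically lenient for accessibility calls.
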
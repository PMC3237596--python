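# Methods

## Scope and model

`exonflow` re-implements an exon-array analysis of an androgen-stimulation
experiment (4 control vs 4 treated replicates) as a tested pipeline: from
probe-level intensities to differential gene expression, differential
alternative-isoform calls via a splicing-index filter cascade, event-class
annotation, GO enrichment with descendant pruning, and RT-PCR
validation-ratio statistics.  Because the original raw scans are not part
of this package, a probe-level simulator with known ground truth stands in
for them; every stage is exercised against that truth.

The measurement hierarchy is the exon-array one: 25-mer probes →
probesets (one exonic region, ~4 probes) → meta-probesets (genes).
Probesets are `core` (RefSeq-supported) or `extended` (additional cDNA
evidence); gene-level estimates use core probes only, exon-level estimates
use all probes of the probeset.  Antigenomic background probes, binned by
GC count, supply the null distribution for detection-above-background
(DABG) calls.

## Summarization

* **Quantile normalization** maps every array's sorted intensities onto
  the across-array mean of sorted intensities; ties receive the mean of
  the tied positions' reference values.  The transform is idempotent (for
  tie-free data, to machine precision) and equalizes column means exactly.
* **Probe summarization** uses Tukey median polish of the additive model
  `log2(I) = overall + probe + sample + residual`, iterated with
  alternating row/column median sweeps until the largest residual change
  falls below 1e-6 or 10 sweeps have run; the per-sample estimate is
  `overall + sample effect`.  Median polish is the transparent, testable
  standard summarizer (the one inside RMA); this package uses it at both
  the exon and the gene level in place of the model-based weighted
  PLIER/Iter-PLIER pair, whose proprietary parameterization is not
  reproducible from public descriptions.  The downstream statistics need
  only *consistent* exon- and gene-level estimates on the log2 scale, which
  median polish provides.  No convolution background correction is applied
  before normalization; background information enters only through DABG.
* **DABG**: a probe's p-value is the empirical upper-tail rank of its
  intensity within its GC bin of background probes,
  `p = (1 + #{bg >= x}) / (1 + N_bin)`, so `p ∈ (0, 1]` and is ~uniform
  for background-like probes.  Empty GC bins borrow the nearest non-empty
  bin.  Probe p-values are combined to probeset level with Fisher's method
  (`X = -2 Σ ln p`, chi-square with 2k df), and probeset p-values are
  combined the same way over a gene's core probesets to give a gene-level
  detection p.  DABG is computed on the normalized intensities, for
  consistency with the estimates it gates.
* Meta-probesets with **fewer than 11 core probes** are excluded from all
  analyses (gene estimates too unstable below that).

## Differential expression

Two-sided pooled-variance Student t-test on gene-level log2 estimates
(df = n₁+n₂−2).  Multiplicity is handled with Storey q-values using the
fixed-λ plug-in estimate `π0 = min(1, #{p>λ}/(m(1−λ)))` at λ = 0.5 —
deterministic and hand-checkable, unlike the spline-over-λ-grid variant;
with π0 forced to 1 the q-values reduce exactly to Benjamini–Hochberg.
When no p exceeds λ the plug-in estimate is 0 and is floored at 1/m to
keep π0 in (0, 1].  A gene is called regulated when it is detected
(gene-level DABG ≤ 0.01 in ≥3 replicates of at least one condition —
the inclusion rule mirrors splice criterion a), |log2FC| ≥ 1 (two-fold)
and q < 0.005.

## Splicing-index filter cascade

The splicing index of a probeset is its log2 exon estimate minus the log2
gene estimate per sample; gene-level expression changes cancel, so a
residual treated-vs-control difference marks an isoform shift.  A
probeset is called differentially spliced when all five criteria hold:

| criterion | quantity | threshold |
|---|---|---|
| a | gene DABG ≤ 0.01 replicates, per condition | ≥ 3 in each |
| b | Pearson r and Spearman ρ of per-probe condition means | both ≥ 0.7 |
| c | abs gene log2 fold change | ≤ log2(10) = 3.32 |
| d | t-test p on splicing-index vectors | ≤ 0.001 (option: 0.0005) |
| e | probeset detected in ≥3 replicates of some condition, and there abs(log2 probeset − gene) | ≤ log2(5) = 2.32 |

All comparisons are inclusive; the call is the pure conjunction of a–e,
so evaluation order is irrelevant, and every measured quantity is stored
next to its flag.  Criterion b averages log2 probe intensities across
replicates within each condition and correlates the two per-probe mean
vectors over the whole meta-probeset; zero variance leaves the
correlations undefined and fails the criterion with a warning.  Called
probesets are joined to the event annotation
(cassette / alt 5′ / alt 3′ / mutually exclusive / alternative first /
alternative last exon); conflicts annotate with all classes and warn.

## GO enrichment and pruning

Direct annotations are propagated up the is_a DAG (true-path rule); each
term with ≥1 annotated universe gene gets a one-sided hypergeometric
(Fisher exact) p for over-representation of the input set, with Storey
q-values and significance at q ≤ 0.05.  Only is_a edges are used — the
minimal defensible relation set when none is prescribed.

Pruning removes redundancy: a significant term with *exactly one*
significant descendant is re-tested after removing the input genes
annotated to that descendant; if the recomputed p exceeds the realized
p-cutoff (the largest nominal p among originally significant terms), the
term is flagged pruned with the descendant as cause.  Re-testing against
the realized cutoff avoids circular re-ranking of the whole FDR pass.
Pruned terms stay in the output.

## RT-PCR ratios

Per lane: relative normalized gene expression = target band / GAPDH band;
relative normalized expression ratio = alternative / constitutive band or
3′-end / 5′-end band.  Ratios are computed per lane and compared across
replicate lanes (not pooled intensities) with an independent-sample
t-test; significance is p < 0.05 (strict inequality, in contrast to the
inclusive array-side thresholds).

## Simulator

Log2-scale generative model
`x = μ_gene + a_probe + (c_gene + s_probeset)·[treated] + N(0, σ)`
exponentiated to linear intensities; probes of unexpressed genes and
background probes come from
`background_mean + gc_slope·(gc − 12.5) + N(0, σ_bg)` (Gaussian noise on
the log scale = multiplicative noise on the linear scale, the standard
microarray error model).  Defaults, chosen as a desk-scale (<1 min)
design with enough power for recovery tests:

| parameter | default | meaning |
|---|---|---|
| n_genes | 1000 | meta-probesets |
| probesets_per_gene | 8–12 | uniform per gene |
| probes_per_probeset | 4 | exon-array typical |
| n_background_probes | 2000 | GC ~ Binomial(25, 0.5) |
| replicates_per_condition | 4 | the emulated design |
| fraction_unexpressed | 0.25 | background-like genes |
| fraction_de_genes | 0.10 | per expressed gene, sign random |
| log2fc_de | 1.0 | planted gene effect |
| fraction_spliced_probesets | 0.05 | of all probesets |
| splice_effect_log2 | 1.0 | planted index shift |
| baseline_mean / sd | 8.0 / 1.0 | log2 abundance of expressed genes |
| probe_affinity_sd | 1.0 | per-probe log2 offset |
| noise_sd | 0.25 | log2 replicate noise |
| background_mean / sd | 4.0 / 0.8 | log2 background |
| background_gc_slope | 0.1 | log2 per GC unit |
| core_probeset_fraction | 0.75 | class assignment |

`probe_affinity_sd = 1.0` reflects that hybridization affinities on
oligonucleotide arrays span several log2 units; criterion b's correlation
screen presumes that spread (it correlates probe profiles dominated by
affinity), and materially smaller values would make the screen reject
well-measured genes, which real arrays do not show.

Cassette-type events (cassette, alt 5′/3′ splice site, mutually
exclusive) shift one probeset; alternative first/last exon events shift a
contiguous block of two probesets at the 5′/3′ end — the footprint
promoter selection / polyadenylation leaves on an exon array.  Planted
probesets always sit in expressed genes.  Event annotations cover planted
probesets plus a 5% decoy rate on unplanted ones, so mapping is not
circular.  The planted event-class mix (35% cassette, 30% alt-first, 15%
alt-last, 20% other) loosely follows the composition reported for
androgen-responsive isoform changes, where promoter-selection events
dominate the annotated classes.

What the simulator does *not* emulate: scanner spatial artifacts,
cross-hybridization, probe-sequence (GC) effects on foreground probes,
batch effects, correlated isoform structure beyond single shifts, and
realistic annotation sparsity.  Passing recovery tests therefore shows
the pipeline implements its stated decision rules correctly and has the
expected power under a clean additive model — not that it would achieve
the same sensitivity on real scans.

## Numerical and design choices

* Tie-breaks in quantile normalization: mean of tied positions' reference
  values; empty DABG bins: nearest non-empty GC (ties toward lower GC).
* Degenerate t-tests: two constant equal groups → (t=0, p=1); constant
  unequal → p=0 with a degeneracy warning.
* The simulation-derived problem sizes used by the test suite and the
  acceptance script (the default 1000-gene design, 5 seeds for
  calibration/recovery) are desk-scale choices: large enough that the
  binomial error of the measured rates is well inside the asserted bands,
  small enough to run in minutes.
* All randomness flows from a single seed; the pipeline derives stage
  sub-seeds via `SeedSequence`, so stage-level reruns reproduce in
  isolation.

## Known limitations

* Median polish is not PLIER: absolute estimates differ from the original
  pipeline's, so published headline counts that depend on the exact
  summarizer (and on chip annotation versions) are not reproduced here;
  the in-paper arithmetic built on those counts is.
* Iter-PLIER's iterative probe subselection is omitted; long genes with
  discordant probes are summarized as-is (criterion b is the guard).
* Gene-level DABG via Fisher combination is anti-conservative for genes
  with many probesets (detection is easy for large genes); it is used as
  an inclusion screen only.
* The pruning recomputation uses the realized p-cutoff rather than
  re-running the FDR; terms near the significance boundary can be
  sensitive to that choice.
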
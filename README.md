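# exonflow

Exon-array analysis of androgen-regulated gene and mRNA-isoform
expression, packaged as a tested, reusable pipeline.

Androgens reshape the prostate-cancer transcriptome both by changing how
much of each gene is expressed and by switching *which* mRNA isoform is
made (alternative splicing, alternative promoter selection, alternative
polyadenylation).  Exon arrays measure both at once: probes → probesets
(one exonic region) → meta-probesets (genes).  `exonflow` implements the
full analysis path for such an experiment — 4 control vs 4
androgen-treated replicates — for computational biologists who want each
statistical step explicit, tested and reproducible:

1. **Summarization** — quantile normalization, Tukey median-polish
   probeset- and gene-level log2 estimates, and detection-above-background
   (DABG) p-values from GC-binned antigenomic background probes.
   Genes with <11 core probes are excluded.
2. **Differential expression** — pooled t-test on gene estimates, Storey
   q-values (fixed λ = 0.5); called at |log2FC| ≥ 1 and q < 0.005.
3. **Differential isoform usage** — the splicing index
   `SI_s = log2(probeset)_s − log2(gene)_s` per sample, filtered through a
   five-criterion cascade: (a) gene detected in ≥3 replicates of both
   conditions; (b) per-probe condition means correlate between conditions
   (Pearson and Spearman ≥ 0.7); (c) |gene log2FC| ≤ log2(10) = 3.32;
   (d) t-test on SI vectors p ≤ 0.001; (e) probeset detected in one
   condition with |log2(probeset/gene)| ≤ log2(5) = 2.32 there.  Calls are
   mapped to annotated event classes (cassette exon, alt 5′/3′ splice
   site, mutually exclusive, alternative first/last exon).
4. **GO enrichment** — one-sided Fisher exact tests after true-path
   propagation, q ≤ 0.05, then pruning of terms significant only because
   of a single significant descendant.
5. **RT-PCR validation arithmetic** — per-lane band ratios
   (target/GAPDH, alternative/constitutive, 3′/5′) compared between
   conditions at p < 0.05.

A probe-level simulator with known ground truth (planted fold changes and
isoform shifts) replaces the microarray scans, so every stage is testable
end to end.  See `docs/methods.md` for models, parameters and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (later steps read the outputs of earlier ones):

```sh
python analysis/01_simulate_experiment.py --seed 1
python analysis/02_summarize_expression.py
python analysis/03_differential_expression.py
python analysis/04_differential_splicing.py
python analysis/05_go_enrichment.py --seed 1
python analysis/06_rtpcr_validation.py --seed 1
```

Step 04 prints, for seed 1:

```
335 of 9997 probesets called differentially spliced
       event_class   n  pct_of_called
           alt_3ss  14       4.179104
           alt_5ss  16       4.776119
    alt_first_exon 131      39.104478
     alt_last_exon  63      18.805970
     cassette_exon  83      24.776119
mutually_exclusive  11       3.283582
            mapped 318      94.925373
      called_total 335     100.000000
  sensitivity on planted probesets: 0.8638
  empirical FDR among calls       : 0.0537
```

Reading: of ~10,000 evaluated probesets, 335 pass the full a–e cascade;
318 of them carry an event annotation, dominated by alternative first
exons (the planted promoter-selection events shift two 5′ probesets
each).  86% of the planted isoform effects are recovered, and 5% of calls
land on unplanted probesets.  Step 05 shows the pruning logic: the term
`lipid metabolic process` is significant only through its significant
descendant `sterol biosynthetic process` and is pruned, while `metabolic
process`, which has two significant descendants, is kept.

The same machinery is available as a CLI
(`exonflow simulate|summarize|diffexp|splice|enrich|ratios|run`) and as
plain library calls (`exonflow.pipeline.run_end_to_end`).

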
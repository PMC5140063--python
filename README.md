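# adipoepi

Comparative transcriptomic and epigenomic analysis of brown versus white
adipogenesis, packaged as a tested, reusable pipeline.

Brown adipocytes (BA, from multipotent C3H10T1/2-type progenitors) and white
adipocytes (WA, from committed 3T3-L1-type preadipocytes) differentiate
through ordered stages (around induction day d-3/d-4 through d0, 6h, d2, d7).
`adipoepi` implements the analyses used to compare the two lineages across
that time course:

- **Entropy-based stage specificity.** For a feature with expression
  E_i over N stages, relative expression R_i = E_i / ΣE and
  H = −Σ R_i log2 R_i, with 0 ≤ H ≤ log2 N. Features with H < 2 are
  candidates; a gene is assigned to a stage where it is highly expressed
  (FPKM > 5 coding, > 0.5 lncRNA) with high expression in at most three
  additional stages. miRNA array signals are quantile-normalized and
  selected by a > 2-fold variation rule (argmax-stage assignment).
- **d7 lineage classification.** Pooled d7 stage-specific genes split into
  BA-specific (BA ≥ 3× WA and WA FPKM < 10), WA-specific (mirrored), and
  shared adipogenic genes; lncRNAs use a 5-fold rule; optional 2.5-fold
  tissue / primary-cell cross-checks.
- **Stage-specific enhancers.** Candidate enhancers are pooled H3K27ac
  regions with no H3K4me3 overlap and no TSS ± 2.5 kb overlap. ChIP signal
  is quantified as RPKM from 300 bp-extended reads and z-score normalized;
  a region is stage-specific where z > 1 with activity (z > 0) in at most
  three additional stages.
- **Super-enhancers.** Active enhancers (z > 0) within 12.5 kb are stitched;
  stitched spans > 12.5 kb are ranked by RPKM, and the high-signal suffix of
  the unit-scaled rank/signal curve beyond the slope > 0.5 crossing is
  called the SE set. d7 SEs overlapping early-stage SEs are removed to get
  late-specific SEs. Targets are expressed genes (FPKM > 1) within 100 kb
  with Pearson r > 0.75 across stages (fallback: best gene with r > 0.5);
  TF-defined SEs use nearest-gene assignment.
- **Promoter chromatin state.** Z-scored promoter RPKM per histone mark is
  compared between lineages per gene group with Welch's t-test.
- **TF peak analysis.** SIX1-style peak sets are annotated by genome element
  (promoter > exon > intron > TTS > intergenic, midpoint rule), binding
  signal is summed over each expression group's H3K27ac regulatory
  neighborhoods, and nearest-peak TSS distances are computed.

A synthetic-data generator (`adipoepi.simulate`) plants all of this
structure — stage-specific/lineage-specific/shared genes, transiently
induced genes, stage-specific enhancers, clustered SE loci whose ChIP signal
co-varies with planted target genes, and element-distributed TF peaks — with
recorded ground truth, so the whole pipeline is validated end to end without
any external data.

## Worked example

```sh
adipoepi demo --seed 1 --out demo_out
```

generates the default fixture (2,000 genes, 40 planted stage-specific genes
per stage, 20 SE loci, 20× effect, lognormal noise 0.2 on log2), runs the
full pipeline, and prints the recovery report. With seed 1 it prints, among
others:

```
stage_genes_BA: {'recall': 1.0, 'precision': 1.0, 'n_detected': 300, 'n_truth': 300}
enhancers_BA: {'recall': 1.0, 'precision': 1.0, 'n_detected': 500, 'n_truth': 500}
superenhancers_BA: {'locus_recall': 1.0, 'target_pair_recall': 1.0, 'decoy_rate': 0.1, 'n_se_called': 27}
promoter_mark_p: {'H3K27me3': {'d7': 0.990}, 'H3K4me1': {'d7': 2.8e-23}}
```

Reading: all 300 planted stage-specific (gene, stage) pairs in the brown
lineage are recovered with no false assignments; all 20 planted SE loci are
called and linked to their planted target genes, while flat-profile decoy
genes inside the 100 kb window are picked up at the ~7% rate expected for a
5-point Pearson null; the planted promoter H3K4me1 asymmetry between
lineages is highly significant while H3K27me3 (planted symmetric) is not.
`demo_out/` contains the fixture, all TSV/BED outputs, `manifest.yaml`
(thresholds and counts) and `recovery.yaml`.

The same stages are available as library calls (`adipoepi.run_pipeline`,
`adipoepi.select_stage_specific`, `adipoepi.rank_and_cut`, ...) and as CLI
subcommands (`simulate`, `run-all`, `demo`).

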
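# sixma

Genome-wide profiling of DNA N6-methyladenine (6mA) from single-molecule
sequencing kinetics: site calling, adenine-background feature enrichment,
and methylation–expression integration, with a synthetic-data generator that
plants ground truth so every stage of the pipeline can be validated
end-to-end without real sequencing data.

## The problem

6mA is an emerging eukaryotic epigenetic mark detected directly from
single-molecule real-time sequencing: a methylated template adenine slows
the polymerase, lengthening the inter-pulse duration (IPD) of base
incorporations at that position. Studies of 6mA landscapes (for example in
marine invertebrate genomes) follow a common analysis arc:

1. **Call sites.** Aggregate subread IPDs per genomic adenine. With a
   lognormal baseline (log-mean μ₀, log-sd σ₀), the kinetic signal is the
   geometric-mean IPD ratio, `ipdRatio = exp(mean(log IPD) − μ₀)`, and the
   identification QV is a Phred score `−10·log₁₀ p` from a one-sided
   one-sample t-test of the log-IPDs against μ₀. High-confidence sites must
   clear **coverage ≥ 30×, QV ≥ 20 and ipdRatio ≥ 1.5** (all inclusive).
   The per-site methylated fraction is estimated as
   `clip((mean log IPD − μ₀)/ln m, 0, 1)` for a fully-modified multiplier m.
2. **Locate sites.** Partition the genome into promoter (1 kb upstream of
   the TSS by default; 500 bp and 2 kb as robustness windows), 5′UTR, exon,
   intron, 3′UTR, downstream (300 bp past the TES) and intergenic classes —
   a strict tiling under the precedence
   5′UTR > 3′UTR > exon > intron > promoter > downstream > intergenic —
   plus an independent transposable-element (LINE/SINE/LTR/SimpleRepeat)
   label.
3. **Test enrichment.** Because 6mA can only occur on adenines, the null
   model is adenine content: `expected_f = (A_f / A_total) · N` where `A_f`
   counts the feature's adenines on both strands. Enrichment is
   observed/expected, significance a two-sided Fisher's exact test with
   Benjamini–Hochberg FDR within each family.
4. **Integrate expression.** Per-gene occupancy (sites/kb) and level (mean
   methylated fraction) per region, occupancy quartiles Q1–Q4 vs
   log₂(TPM+1) with Welch t-tests, Pearson/Spearman correlations, a
   length-normalized metagene profile, hyper/hypo-methylated ×
   highly-expressed gene classes (top/bottom 10% gene-body level, TPM above
   the mean) and upper-tail hypergeometric term enrichment.

The synthetic generator produces annotated genomes (introns ~15× exon
length), planted 6mA with exact per-feature composition, lognormal subread
kinetics, and TPM coupled positively to gene-body 6mA and negatively to
promoter 6mA — so recovery of every summary statistic can be asserted
against known truth.

## Worked example

```bash
sixma run-all --seed 1 --out-dir demo/
# called 462 sites (0.0962% 6mA/A); report at demo/report.json
```

The run simulates an 800 kb two-chromosome genome with 30 genes, plants
624 sites (0.13% of strand-adenines, 42% of them intronic), simulates
~50× kinetics and calls sites at the default thresholds. 462 of the 624
planted sites are recovered — partially methylated sites with weak IPD
shifts are below the detection limit, so the called density (0.096%) sits
below the planted density, as it would on real data. `demo/enrichment_features.tsv`:

```
feature     observed  adenines  expected  ratio  q          stars
intergenic  193       289226    278.3     0.69   9.7e-15    ***
downstream  8         5344      5.1       1.56   0.18       ns
promoter    24        18049     17.4      1.38   0.13       ns
intron      201       155339    149.5     1.34   2.0e-06    ***
exon        27        9480      9.1       2.96   2.0e-06    ***
3'UTR       5         1353      1.3       3.84   0.018      *
5'UTR       4         1291      1.2       3.22   0.052      ns
```

Exonic 6mA is ~3× enriched over the adenine background while intergenic
space is depleted, and the expression coupling planted by the generator is
recovered in `demo/correlations.tsv` (Pearson r vs log₂(TPM+1)):
gene body +0.77, exon +0.34, promoter −0.58.

Every stage is also available separately (`sixma simulate`, `call`,
`annotate`, `enrich`, `integrate`, `motif`) on files in standard formats
(FASTA, GFF3, the PacBio-style modifications GFF, BED4, TSV), or as library
functions (`sixma.call_sites`, `sixma.build_partition`,
`sixma.enrichment_table`, ...).

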
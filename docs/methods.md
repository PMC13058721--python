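# Methods

## Kinetic model and site calling

Unmodified inter-pulse durations (IPDs) at a genomic position are modeled
as lognormal: `log IPD ~ Normal(mu0, sigma0)`. N6-methylation acts
multiplicatively on the median IPD, so at a site where a fraction f of
molecules is methylated each subread is drawn from the baseline with
probability 1−f and from `Normal(mu0 + ln m, sigma0)` with probability f,
where m > 1 is the modified-median multiplier. This choice is heavy-tailed,
strictly positive, and makes the natural aggregate statistic — the
geometric-mean IPD ratio `exp(mean(log IPD) − mu0)` — exactly the quantity
the ratio threshold is phrased in.

The identification QV is `−10·log10 p` with p from a one-sided (greater)
one-sample t-test of the log-IPDs against mu0. A t-test on logs is the
simplest defensible Phred-compatible score under the lognormal model; it is
our own scoring choice, documented as such, and the arithmetic-mean ratio
variant is available behind `aggregate_ipd(..., method="arithmetic")`.
p-values are floored at 1e−300 to keep QVs finite; zero-variance samples
are resolved by the direction of the mean shift. A high-confidence site
must satisfy coverage ≥ 30, QV ≥ 20 and ipdRatio ≥ 1.5, all boundaries
inclusive; all three are configurable (`CallerThresholds`).

The per-site methylated fraction is estimated by linear interpolation of
the mean log-IPD between the baseline (0) and the fully-modified level
ln m (1), clipped to [0, 1]. Because detection itself requires
ipdRatio ≥ 1.5, called sites can never carry estimated fractions below
`ln 1.5 / ln m` (≈ 0.37 at m = 3): low-level sites are censored by the
detector, a bias that real kinetics-based callers share and that shows up
in the level-category counts of small runs.

An optional dataset-level gate (mean coverage of the run) is deliberately
not applied by default; the site-level coverage filter is the operative
criterion.

## Feature partition

The seven feature classes tile the genome: every base receives exactly one
label under the precedence 5'UTR > 3'UTR > exon > intron > promoter >
downstream > intergenic, ties between genes at equal precedence going to
the lexicographically smaller gene id. Giving gene bodies precedence over
another gene's promoter/downstream keeps the reported classes disjoint and
favors the gene-body signal that the analysis centers on; UTRs take
precedence over exon so that "exon" means coding/untranslated-free exonic
sequence, matching mutually exclusive reporting categories. Promoters are
1 kb upstream of the TSS by default (500 bp / 2 kb as robustness windows),
downstream windows 300 bp past the TES, both truncated (not errors) at
chromosome edges. Multi-isoform genes are collapsed to the isoform with the
longest exonic span at GFF3 load time, a choice logged per file.

The adenine background is strand-summed: a feature's adenine count is the
number of forward-strand A plus T bases it covers, because sites are called
per strand. Expected counts, enrichment ratios, Fisher's exact test
(two-sided — depletion is as reportable as enrichment) and BH correction
within each family (features; TE classes; terms) follow from that null.
Significance stars are assigned from the BH-adjusted q-values at the
0.05/0.01/0.001 tiers. A feature with zero adenines gets expected 0 and an
undefined (NaN) ratio.

TE labels are independent of the feature partition; a site under several
repeats takes the smallest covering interval, remaining ties resolved
LINE > SINE > LTR > SimpleRepeat > Other. TE composition is reported over
all sites (non-TE sites counted under "none"). A gene counts as methylated
only if it has a site in its gene body (UTRs/exons/introns) — promoter or
downstream sites alone do not qualify.

## Expression integration

"Occupancy" is operationalized as density (sites/kb) for quartile and
correlation analyses, and "level" as the mean methylated fraction for the
hyper/hypo classification; both are computed per gene for promoter,
gene body, exon (UTR-free) and intron regions and both are switchable
wherever either could be meant. Group comparisons use the Welch t-test on
log2(TPM+1) — robust to the variance heterogeneity of TPM; identical
degenerate groups return t=0, p=1. Quartile cuts are the 25/50/75
percentiles among genes with a defined metric, ties to the lower quartile.
The expression gate for classification is the arithmetic mean TPM over all
genes (median available); deciles of the gene-body level are computed among
genes with a defined metric (genes without body sites are excluded from the
mean-fraction decile, logged), and the hyper/hypo sets are intersections of
gate and decile, made disjoint if a degenerate metric collapses the
deciles. Term enrichment is the upper-tail hypergeometric probability
P(X ≥ k) with BH correction across tested terms; terms absent from the
background are skipped.

The metagene profile divides each gene into a fixed 1 kb upstream flank
(10 bins), a length-normalized body (20 bins) and a 1 kb downstream flank
(10 bins), strand-oriented; genes with bodies shorter than the body bin
count are skipped. Counts are normalized to sum to 1 over all bins.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of a genome-wide 6mA study at desk
scale: an i.i.d. random genome at GC 0.4; non-overlapping genes with
lognormal exon/intron lengths whose intron mean is 15x the exon mean
(~150 bp exons, ~2.2 kb introns, ~4 exons/gene), UTRs flanking the CDS,
~10% noncoding genes, and 2 kb-capable flank gaps; TE intervals placed in
intergenic and intronic space at per-class genome fractions (~13% total);
6mA planted on strand-adenines with exact largest-remainder composition
(default mirroring the observed mix: 42% intron, 6% exon, 5% promoter,
43% intergenic, remainder in UTRs/downstream) at a 0.13% genome-wide
density; per-site fractions Beta(4,4) (medium-centered); and expression
`log2(TPM+1) = alpha + beta_body z(body density) + beta_promoter
z(promoter density) + noise` with beta_body = +1, beta_promoter = −1,
noise sd 0.5 — the weakest structure consistent with the directional claims
it is meant to exercise. Kinetic stand-ins (mu0 = 0, sigma0 = 0.6, m = 3,
coverage ~ Poisson(50) or fixed) give a strong but not saturating
single-site signal; no published kinetic parameters exist for this setting,
so all of them are configuration fields.

Not emulated: sequence composition structure (isochores, CpG islands,
codon bias), overlapping or nested genes, alternative isoforms, read-level
errors and mappability, diploidy, and any biological motif preference
around 6mA (contexts are random unless a test plants them). Passing tests
therefore demonstrate the correctness of the *computational* pipeline on
data satisfying the model's assumptions, not biological conclusions about
any real genome.

Every generator stage draws from `default_rng([seed, stage_tag])`, so
stages are independently reproducible and a fixed seed makes the entire
pipeline — including the JSON run report and its file hashes —
byte-identical across runs.

## Numerical and scale choices

- Fisher's exact test delegates to `scipy.stats.fisher_exact`; tests verify
  it against an explicit hypergeometric enumeration oracle (exact to 1e−12
  over exhaustive small tables and random tables with margins ≤ 200).
- BH delegates to `scipy.stats.false_discovery_control`, verified against
  hand step-up computations and dominance/monotonicity properties.
- Vectorized calling computes per-position t statistics from reduceat sums;
  a dedicated test pins it to the per-site scipy t-test route.
- Acceptance-scale problems are sized to run on one CPU in seconds to a
  couple of minutes each: density recovery on a 5 Mb genome (~3,900 planted
  sites, 40x fixed coverage), caller power on 10,000 planted sites over a
  400 kb genome, type-I control with 200 uniform replantings of 1,500 sites
  on a 400 kb genome, expression sign patterns on 2,000 compact genes
  (~18 Mb), and the headline-count round trip with 281,772 sites planted by
  explicit count on a 10 Mb genome (4.7% of adenines — the density-scaled
  genome would be ~360 Mb, which adds nothing to what the round trip
  checks).
- The planted-truth recovery of per-feature composition is exact by
  construction (largest-remainder apportionment plus a partition that tiles
  the genome), so those assertions use exact equality, not tolerances.

## Known limitations

- The QV model is a t-test surrogate, not a re-derivation of any production
  caller's in-silico control model; absolute QV values are comparable only
  within this package.
- The fraction estimator is a method-of-moments interpolation; it is
  monotone and bounded but biased near 0 and 1 at low coverage, and
  censored below `ln(min ratio)/ln m` by the detection threshold.
- Gene-region metrics use each gene's own model intervals; for genomes with
  overlapping genes the per-gene region lengths can double-count bases that
  the partition assigns to a neighbor (the generator never produces
  overlapping genes).
- The metagene profile counts each site once per gene window it falls in;
  with closely packed genes a flank site can contribute to two genes.
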
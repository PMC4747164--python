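# Methods

`foxochip` re-implements, as a tested library, the downstream integration
analyses used to characterise genome-wide binding of the *C. elegans*
FOXO transcription factor DAF-16 under low insulin/IGF-1 signalling (IIS):
summit-centred read-density profiling of ChIP-seq, promoter-window
assignment of peaks to genes, beta-binomial differential expression across
the three classic strains (wild type, *daf-2(−)*, *daf-16(−);daf-2(−)*),
the representation-score statistic that links binding to expression, and
PSSM-based motif enrichment with co-occurrence spacing.  Because the
original sequencing data are not required, a synthetic-data module plants
ground truth for every stage; all statements below about what the tests
demonstrate are statements about that synthetic model.

## Coverage profiling

Single-end reads are shifted 3′ by **half the library's mean fragment
size** (`round(fragment_size/2)`), so the shifted position estimates the
fragment midpoint.  Shifting by the full fragment size is available as
`ProfileConfig.shift_mode="full"`; the half-size convention is the
standard one for single-end ChIP-seq and is the package's choice where
only "shifted based on the mean fragment size" is specified upstream.
Shifted positions are counted into 25-bp non-overlapping bins, scaled to
reads per million (the scale constant cancels in the rank and quantile
steps that follow, so any positive constant gives identical downstream
results), input-corrected by per-bin subtraction, and quantile-normalized
across samples.

Numerical choices:

* Negative input-subtracted bins are **retained** (clipping available via
  `clip_negative`); quantile normalization follows and clipping first
  would distort the rank structure.
* Quantile normalization uses the classic order-statistic construction;
  tied values receive the mean of the replacement values their run spans.
  With ties the "identical sorted vectors" property holds only up to this
  averaging — exact for tie-free (e.g. continuous) data.
* Summit windows are ±20 bins (±500 bp); windows crossing a chromosome
  edge are dropped and counted rather than padded, to avoid fabricating
  signal.
* The heat-map row order ("ranked") sorts peaks by their centre-bin value,
  descending.  The rank transform used for rank tracks is the genome-wide
  fractional rank in (0, 1], mean rank for ties; this makes the track
  invariant under any strictly increasing transform of the input.  The
  exact rank construction of the original figures is not documented
  anywhere, so this definition is a package decision.

## Peak-to-gene assignment

Each summit is assigned to the gene with the closest TSS (distance
measured summit-to-TSS; peaks are anchored on summits throughout).
Signed distances are in transcription orientation, negative upstream.  A
peak is promoter-associated when its distance lies in [−2500, +300] bp.
Distance bands are 500-bp wide on |distance|.  Ties between equidistant
TSSs are broken lexicographically by gene id and logged.  Peaks outside
the promoter window are retained with a flag, since the full distance
distribution is itself an analysis output.

Cross-condition peak identity — needed to compare wild-type and low-IIS
binding — is not defined in any upstream documentation; the package pairs
peaks whose intervals intersect by ≥1 bp, greedily by maximal overlap with
each peak used once.  Summit shifts of paired peaks are signed by the
assigned gene's strand.

## Differential expression

Expression is quantified as RPKM (reads per kilobase of exon model per
million mapped reads).  The two-group test treats each replicate's gene
count as a draw from that library's total and compares library-size
weighted proportions:

    t = (p̂_a − p̂_b) / sqrt(V_a + V_b)

With K ≥ 2 replicates, V is the unbiased empirical variance of the
weighted proportion — which contains the within-replicate binomial
component plus any extra-binomial (beta) between-replicate variance — and
t is referred to a t distribution with Satterthwaite degrees of freedom.
With one replicate per group the between term is not estimable, V reduces
to the binomial form, and the statistic is exactly the unpooled
two-proportion z-test.  Genes with zero counts everywhere get p = 1.

"DAF-16-dependent" is operationalised as significance in **both**
contrasts: *daf-2(−)* vs WT (primary) and *daf-2(−)* vs
*daf-16(−);daf-2(−)* (dependence), each at fold ≥ 2 and p ≤ 0.05 on raw
p-values (no multiple-testing correction, matching the stated criterion;
Benjamini–Hochberg is available but off by default).  A gene is
"expressed" when its mean RPKM is positive in both the *daf-2* and the
double-mutant condition.

## Motif scanning

PSSM scores are log-likelihood ratios in bits against an order-m Markov
background (default m = 2, trained on the analysis genome with +1
pseudocount per context cell).  Matrix cells receive a 0.25 pseudocount.
Column score increments are quantized to a 0.01-bit lattice; the null
distribution of a random L-mer's score is then computed **exactly** by
dynamic programming over (position, Markov context, lattice score), for
any background order, and every reported p-value is a lattice-exact
survival probability.  The quantization error is bounded by 0.005·L bits
(≈0.07 bits for a 13-column matrix) and buys exact agreement between the
scanner, the p-values, and brute-force enumeration.

Scanning covers summit ±250 bp on both strands.  By default at most one
match per sequence is reported (the single-true-site assumption): the
highest-scoring window, ties broken leftmost with the plus strand first;
matches are recorded only at p ≤ 1e-5, but every sequence reports its
best score, which is what the enrichment curves and the score-vs-height
correlation consume.  The "weight score" is in bits (base-2); the natural
log alternative would only rescale every threshold.

The enrichment ratio r is the fraction of peak sequences carrying a
threshold-passing match divided by the same fraction in an equal number
of random promoter windows of identical length, sampled (seeded) from the
same annotation; promoters of peak-bound genes can be excluded so the
control is binding-free, and the pipeline does so.  A zero random
frequency flags r = +inf.  Inter-motif distances are taken between match
centres (centre = window start + (L−1)//2), signed by the promoter's
strand, and histogrammed in 10-bp bins.

## Synthetic data: what it emulates, and what it does not

The generator tiles a 2 × 800-kb genome (i.i.d. bases at GC 0.36, the
*C. elegans* composition) with 300 genes at ≥5-kb spacing, alternating
strand.  30% of genes are "bound": a planted summit at one of the
upstream distances {100, 250, 400, 700, 1200, 2000} bp, with a realization
of the 13-bp degenerate FOXO consensus `SYGGTAAACAASR` written at the
summit (strand uniform).  An 8-bp core alone cannot clear the 1e-5 match
threshold — the minimum achievable p-value for any L-mer is the
background probability of its consensus word, ≥4⁻⁸ ≈ 1.5e-5 — so the
full-length discovered motif is the planted and scanned unit.  60% of
motif-carrying promoters also receive a co-motif (12 bp, GATA-core) at
+40 bp from the primary motif centre in promoter orientation.

ChIP fragments mix a uniform background (400k fragments/sample, ≈6 reads
per 25-bp bin) with Normal(summit, fragment_length/4) enriched midpoints,
scaled so midpoint density at the summit is 10-fold background; each
fragment yields one 36-bp single-end read from a uniformly chosen end.
The *daf-16;daf-2* condition forces the enrichment multiplier to 1.

Expression counts are negative binomial with per-gene lognormal baselines
(median 200, σ = 0.5) and dispersion α = 0.02, typical of isogenic
*C. elegans* bulk RNA-seq; 70% of bound genes are activated 4-fold in
*daf-2(−)* (activation coupled to binding), 15% of unbound genes are
repressed 4-fold (repression uncoupled), and nothing responds in the
factor-null strain.  These proportions make the planted truth itself
carry a representation score of ≈2.2 with a significant activated∩bound
overlap and a null repressed∩bound overlap, the qualitative structure the
statistic exists to detect.  Reported library totals add 10⁶
"rest-of-transcriptome" reads to the panel column sums so fold changes
are not compressed by composition shifts — with only 300 genes the
activated mass would otherwise visibly inflate the library totals, which
real transcriptome-wide libraries do not show.  An optional
`distance_decay` mode shrinks the activation effect exponentially with
planted summit distance (length scale 1 kb) for distance-stratification
tests.

Not modelled: sequencing errors, mappability, GC bias, replicate batch
effects, peak-calling noise (peaks carry the planted summits exactly),
and biological correlation between genes.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not performance on real libraries.

## Integration statistics

R = (n_DDEG/n_DEG)/(n_bound_expressed/n_expressed), where DDEG are
differentially expressed genes with a promoter-window peak.  Overlap
significance is the upper-tail hypergeometric probability; the universe
is the expressed-gene set (configurable — the original universe is not
documented).  Fold changes are averaged on the linear scale (log-scale
option available).  Per-class summit profiles are compared with
two-sided Mann–Whitney U on centre-bin values (exact enumeration for
groups ≤20, normal approximation with tie correction above); paired
cross-condition comparisons use the Wilcoxon signed-rank test.

## Problem sizes and determinism

The default synthetic run (300 genes, 90 peaks, 6 × 400k reads, 9 RNA-seq
libraries) is sized so the full pipeline completes in well under a
minute; the differential-expression calibration uses 2000 null genes.
All randomness descends from one root seed through named
`numpy.random.default_rng` streams, so a full rerun with the same
configuration is byte-identical, including the summary JSON and the
SHA-256 provenance checksums it records.

## Known limitations

* The beta-binomial test is a reconstruction from its published
  description; its behaviour is pinned by the single-replicate closed
  form and a type-I simulation, not by the original software.  At 3v3
  replicates it inherits the mild conservatism of Satterthwaite
  approximations (null rejection ≈0.035 at the 0.05 level).
* Match p-values are per-window; no multiple-testing control across
  windows of a sequence is applied (the per-sequence best-hit convention
  is the control used in practice).
* BAM input is supported only through SAM text; quantile normalization
  loads all tracks in memory (fine up to tens of megabases of 25-bp bins).
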
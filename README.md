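# foxochip

Integration analyses for transcription-factor ChIP-seq and RNA-seq,
modelled on the genome-wide study of endogenous DAF-16/FOXO in
*C. elegans* under low insulin/IGF-1 signalling (IIS).  The package is
aimed at analysts who want the downstream statistics of such a study —
not read alignment or peak calling — as reusable, tested building blocks:

* **Summit metaprofiles** — reads shifted by half the fragment size,
  25-bp binning, reads-per-million scaling, input subtraction, quantile
  normalization, and summit-centred ±500 bp mean-read-density matrices.
* **Peak-to-gene assignment** — closest-TSS annotation with the
  2.5-kb-upstream/300-bp-downstream promoter window, 0.5-kb distance
  bands, and cross-condition peak overlap with summit-shift tracking.
* **Differential expression** — RPKM and a beta-binomial weighted
  proportions test (Baggerley-style): groups are compared with
  t = (p̂₁ − p̂₂)/√(V₁+V₂) where V includes extra-binomial
  between-replicate variance; with single libraries it reduces exactly to
  the two-proportion z-test.  Genes are classed activated/repressed/
  unchanged in a DAF-16-dependent manner (fold ≥ 2 and p ≤ 0.05 in both
  the *daf-2(−)* vs WT and the *daf-2(−)* vs *daf-16(−);daf-2(−)*
  contrast).
* **Binding-by-expression statistics** — the representation score
  R = (n_DDEG/n_DEG)/(n_bound/n_expressed), hypergeometric overlap
  p-values, distance-stratified mean fold changes, and per-class summit
  profiles compared by Mann–Whitney U.
* **Motif analysis** — PSSM scanning of summit ±250 bp against an
  order-2 Markov genome background with *exact* match p-values (dynamic
  programming over a 0.01-bit score lattice), enrichment ratio r versus
  matched random promoters, best-score vs peak-height correlation, and
  strand-aware inter-motif spacing histograms.
* **Synthetic data** — a generator that plants ground truth for every
  stage (motifs, summits, expression classes) across the three strains,
  so the whole pipeline is testable end-to-end without the original
  sequencing data.

## Worked example

Run the full synthetic pipeline (simulate → profile → annotate → de →
scan → integrate) from Python:

```python
from foxochip import RunConfig, run_pipeline

config = RunConfig(outdir="run1", seed=1)
summary = run_pipeline(config)
print(summary["integration"]["representation_score"])  # 2.2222222222222223
print(summary["integration"]["n_ddeg"])                # 62
print(summary["motifs"]["r_ratio"])                    # 45.0
print(summary["motifs"]["spacing_mode"])               # 40.0
```

or from the shell:

```sh
fci run --out run1 --seed 1
# R = 2.22; summary at run1/summary.json
```

What the numbers mean: of 300 simulated genes, 90 carry a planted
promoter peak and 62 are both differentially expressed and bound (DDEGs).
The representation score R = 2.22 says DAF-16-bound genes are 2.2-fold
over-represented among DAF-16-dependent genes relative to the bound
fraction of all expressed genes; the activated∩bound overlap is highly
significant (p ≈ 1e-42, hypergeometric) while the repressed∩bound
overlap is not (p = 1.0) — repression in the simulation is deliberately
uncoupled from binding.  The motif enrichment ratio r = 45 means a
threshold-passing FOXO-consensus match (p ≤ 1e-5) occurs 45× more often
in peak sequences than in matched random promoters, and the inter-motif
spacing histogram peaks at +40 bp, the planted co-motif offset.

Each stage is also independently invocable (`fci simulate`, `fci
profile`, `fci annotate`, `fci de`, `fci scan`) on a run directory, and
`fci io validate <dir>` checks cross-file chromosome consistency.

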
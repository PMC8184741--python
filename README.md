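# emscore

Supervised prioritization of causal *cis*-eQTLs and functionally informed
fine-mapping.

Most variants that regulate gene expression sit in non-coding DNA and are
entangled with dozens of neighbours in linkage disequilibrium (LD), so an
eQTL association rarely pins down the causal base pair. `emscore`
implements a two-part strategy for this problem, aimed at statistical
geneticists working with eQTL fine-mapping output:

1. **The expression modifier score (EMS).** Variant–gene pairs confidently
   fine-mapped as causal (posterior inclusion probability, PIP, above 0.9
   under two independent methods) and confident negatives (PIP below 10⁻⁴
   under both) define a binary classification task. A random forest is
   trained on functional features — signed distance to the transcription
   start site (TSS), binary epigenomic peak annotations, and continuous
   regulatory-activity scores — with leave-one-chromosome-out splitting.
   Its raw score is calibrated by binning: within each score bin the
   fraction *f* of positive labels is rescaled from the labeled-set
   prevalence π_t to the genome-wide prevalence π,

   EMS = (f·π/π_t) / (f·π/π_t + (1−f)·(1−π)/(1−π_t)),

   so EMS estimates the probability that a randomly drawn candidate pair is
   a causal eQTL.

2. **Functionally informed fine-mapping.** A bundled sum-of-single-effects
   fitter (iterative Bayesian stepwise selection) models the true effect
   vector as b = Σₗ bₗ with ‖bₗ‖₀ = 1 and returns, per effect, a posterior
   probability vector αₗ over the m variants. For each effect whose 95%
   credible set is *pure* (every pair of members has |r| ≥ 0.5), the
   posterior is reweighted by the per-variant EMS w:

   α̂ₗ(v) = w_v αₗ(v) / Σᵤ w_u αₗ(u),

   impure effects are left untouched, and PIPs (1 − Πₗ(1 − α̂ₗ(v))) and
   credible sets are recomputed. Downstream modules provide enrichment
   statistics with binomial standard errors, colocalization with complex
   traits via the colocalization posterior probability
   (CLPP = max over tissues and credible variants of eQTL PIP × trait PIP),
   and tissue-specificity analyses.

A seeded synthetic-data generator (LD-blocked genotypes via a Gaussian
copula, sparse causal effects, feature matrices with realistic enrichment
structure) makes the whole pipeline testable end to end without external
data.

## Worked example

The package bundles the CITED4 locus example. Four variants upstream of
*CITED4* are in perfect LD, so uniform-prior fine-mapping gives each
α = 0.25 and colocalization with neutrophil count cannot clear the CLPP
threshold of 0.1. One variant (rs35893233, creating an SPI1 binding motif)
carries an EMS of 1.73 × 10⁻³, more than 25× the other three:

```python
>>> from emscore import pipeline
>>> res = pipeline.run_cited4_example()
>>> round(res["lead_pip_ems"], 3)
0.956
>>> round(res["clpp_ems"], 3)
0.173
>>> round(res["clpp_unif"], 4)
0.0452
>>> res["prioritized"]
True
```

Reweighting the pure credible set collapses the posterior onto the lead
variant (PIP 0.956), and its product with the trait PIP (0.181) gives
CLPP = 0.173 > 0.1 — the gene is prioritized, whereas the uniform-prior
CLPP of 0.045 is not.

The synthetic end-to-end demonstration (simulate → fine-map → label →
train → calibrate → reweight) runs from the shell:

```bash
emscore demo --seed 7 --out demo_run
```

which on this seed reports 4000 candidate pairs, 106 true causal variants
called at PIP > 0.9 with the EMS prior versus 102 with the uniform prior,
and an empirical false discovery rate of 0.0 among the informed calls
(`demo_run/summary.json`). Other subcommands (`simulate`, `annotate`,
`train`, `score`, `finemap`, `reweight`, `enrich`, `coloc`, `tissue`)
expose each stage separately; see `emscore --help`.

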
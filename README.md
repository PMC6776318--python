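# rareqtl

Rare-variant eQTL association tests for RNA-seq gene-level read counts,
with a Monte-Carlo framework for measuring their type-I error and power.

## The problem

Expression QTL mapping asks whether genetic variants are associated with a
gene's expression. For RNA-seq, expression is a read *count*, and standard
eQTL methods (linear regression on normalized counts, or count
regressions) target *common* variants. For a collection of **rare**
variants (MAF ≤ 5%) in a region, single-variant tests are hopeless and the
methodology has to aggregate across sites. `rareqtl` implements and
evaluates the two natural extensions, for statistical geneticists and
method evaluators:

1. **Collapsing count regressions.** Collapse the region's rare variants
   into one predictor per subject — the dosage sum `f(x_i) = Σ_j x_ij` or
   the carrier indicator `f(x_i) = 1{Σ_j x_ij > 0}` — and fit a log-link
   count regression of the read count `t_i`:

       log μ_i = α₀ + α_k log k_i + α_c' C_i + α_x f(x_i)

   with Poisson errors or NB2 negative-binomial errors
   (Var = μ + φμ²), testing H₀: α_x = 0 by Wald, score, or LRT.

2. **SKAT family on transformed counts.** Map counts to normal scores by a
   rank-based inverse normal transformation, model them linearly, and test
   all J variant effects at once with the sequence kernel association test

       Q = (y − μ̂₀)' X W² X' (y − μ̂₀),   W = diag(Beta(MAF_j; 1, 25)),

   whose null law is a weighted mixture of χ²₁ variables evaluated by
   characteristic-function inversion (Davies-type, with Liu
   moment-matching fallback). The weighted burden test (SKAT-Burden) and
   the optimal ρ-combination of the two (SKAT-O) are included, for the
   seven methods total: SKAT, SKAT-O, SKAT-Burden, NB-sum, NB-indicator,
   Poisson-sum, Poisson-indicator.

The simulation framework generates a ~3 kb region of 58 biallelic sites
(truncated 1/f frequency spectrum, Hardy–Weinberg genotypes), flags 10% of
MAF < 0.005 sites as causal, filters common variants (MAF > 5%), and draws
counts under four scenarios — Poisson or negative-binomial (φ = 1.1), with
carrier means scaled by a fold change or by the number of causal sites
carried. The default evaluation grid is 540 cells: 4 scenarios × μ ∈ {50,
100, 500} × n ∈ {15, 30, 50, 100, 500} × 9 fold changes.

## Worked example

Simulate one replicate (n = 100 subjects, negative-binomial counts,
fold change 2 for causal carriers) and run all seven tests on the
emitted VCF + counts table:

```bash
rareqtl simulate --scenario A2 --n 100 --mu 50 --fold 2.0 --seed 7 --out-prefix demo
rareqtl test --vcf demo.vcf --counts demo.counts.tsv --gene simulated_gene --out demo_results.tsv
```

which prints (54 rare variants tested):

```
simulated_gene  SKAT             p=0.214     ok
simulated_gene  SKAT-O           p=0.191     ok
simulated_gene  SKAT-Burden      p=0.108     ok
simulated_gene  NB-sum           p=0.309     ok
simulated_gene  NB-indicator     p=0.197     ok
simulated_gene  Poisson-sum      p=7.92e-15  ok
simulated_gene  Poisson-indicator p=2.16e-22 ok
```

The Poisson p-values are wildly anti-conservative *artifacts*: the counts
are overdispersed (φ = 1.1), the Poisson model ignores that, and this
single replicate is exactly the failure mode the evaluation framework
quantifies. The same cell run as a type-I-error experiment (fold = 1,
200 replicates):

```python
import rareqtl as rq
spec = rq.ScenarioSpec(scenario="A2", n=100, mu=50, fold=1.0, phi=1.1, reps=200, seed=11)
table = rq.estimate_rejection_rates([spec])
print(table[["method", "rejection_rate", "mc_se", "n_valid"]].to_string(index=False))
```

```
           method  rejection_rate    mc_se  n_valid
             SKAT           0.060 0.016793      200
           SKAT-O           0.050 0.015411      200
      SKAT-Burden           0.055 0.016121      200
           NB-sum           0.065 0.017432      200
     NB-indicator           0.040 0.013856      200
      Poisson-sum           0.810 0.027740      200
Poisson-indicator           0.840 0.025923      200
```

At the nominal α = 0.05, the SKAT family and the negative-binomial
regressions hold their level on overdispersed counts while the Poisson
regressions reject 80%+ of null replicates — the package's core finding,
and the reason the SKAT-family tests on normalized counts are the
recommended choice when dispersion is unknown.

Real data go through the same `rareqtl test` command: a VCF of genotypes
(`--region chr2:135787850-135837195`), a gene-by-sample counts TSV, and an
optional covariate table; `--libsize-mode offset` adds log library size as
an offset.

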
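# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `rareqtl`.

## Models and tests

**Setting.** A region contains J biallelic rare variants with minor-allele
dosages x_ij ∈ {0,1,2} for subject i = 1..n; t_i is the subject's total
read count for one gene; C_i are optional covariates; k_i an optional
per-subject library size.

**Collapsing count regressions.** The region is collapsed to
f(x_i) = Σ_j x_ij (sum) or 1{Σ_j x_ij > 0} (indicator), over *all*
retained rare variants — the tests have no knowledge of which sites are
causal. The count model is log μ_i = α₀ + α_k log k_i + α_c'C_i + α_x f(x_i)
with Poisson errors or NB2 negative-binomial errors
(Var = μ + φμ²; gamma–Poisson mixture with gamma shape 1/φ). H₀: α_x = 0
is tested by Wald (default), efficient score, or likelihood ratio.

Fitting is in-package maximum likelihood: iteratively reweighted least
squares for the coefficients with step-halving (accepted iterations never
decrease the log-likelihood), alternated for the negative binomial with a
safeguarded 1-D Newton update of log(1/φ). Convergence: relative
log-likelihood change < 1e-8 within 100 outer iterations. A
method-of-moments dispersion start below 1e-4, or a dispersion collapsing
below 1e-8, re-labels the fit *effectively Poisson* with φ̂ = 0 (the NB
boundary). The fitters are validated in the test suite against
statsmodels (GLM-Poisson and discrete NB2) to 1e-6 / 2e-4; an in-package
fitter keeps the 1000-replicate grids fast and the convergence semantics
exactly as specified. Mean–dispersion orthogonality of NB2 lets the score
test and the Wald covariance use the weight μ/(1 + φμ) without a
dispersion correction term.

**SKAT family on normalized counts.** Counts are mapped to normal scores
y_i = Φ⁻¹((r_i − 3/8)/(n + 1/4)) (Blom offset, average ranks for ties; the
offset is the classical choice and tie handling was confirmed immaterial
to calibration). The null linear model (intercept + covariates) is fitted
by least squares; σ̂² = RSS/(n − p₀). The SKAT statistic is
Q = r' X W² X' r with r the null residuals and w_j = Beta(MAF_j; a1, a2)
density weights, defaults (1, 25). Note the kernel uses *squared*
Beta-density weights on genotype columns — the convention of the reference
SKAT software; the literal unsquared kernel X W X' is available as
`weight_convention="literal"`. Under the null, Q ~ Σ_l λ_l χ²₁ with λ the
eigenvalues of σ̂²·(W X' P X W), P the residual-forming projection,
truncated at 1e-10 relative magnitude.

SKAT-Burden tests the weighted burden b_i = Σ_j w_j x_ij as a single
regressor: Q_B = (r'b)² against the single-scale σ̂²·b'Pb chi-square.
SKAT-O computes Q_ρ = (1−ρ)Q_SKAT + ρQ_Burden on the grid
ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}, takes T = min_ρ p_ρ, and
calibrates T by the one-dimensional conditioning integral of the optimal
unified test: the projected weighted genotypes are decomposed along their
row mean, per-ρ T-quantiles come from Liu moment matching, the shared
χ²₁ component is integrated with 48-node Gauss–Legendre after the
substitution x = s² (absolute accuracy well below 1e-4), and ρ = 1 is
capped at 0.999 inside the integral. The final p is clamped to the min-p
combination bounds [T, |grid|·T].

**Mixture-of-chi-square tails.** `quadform_pvalue` inverts the
characteristic function (Imhof's formulation of the Davies approach):
a Simpson grid fine enough to resolve the sin(θ(u) − qu/2) oscillation,
sharing the arctan/log factors across multiple q against one eigenvalue
set; when few or widely separated eigenvalues would need an impractically
fine grid, an oscillatory-weight (QAWF) quadrature on the split
sin(φ)cos(au) − cos(φ)sin(au) form takes over. Equal eigenvalues use the
exact chi-square form. Target absolute accuracy 1e-6 (verified against
2·10⁶-draw Monte Carlo and cross-route agreement); the Liu moment-matching
approximation is the automatic fallback on numerical fault and the
explicit `method="liu"` option. P-values are clamped to [1e-12, 1].

## Synthetic-data generator

The generator emulates a resequenced ~3 kb region. Defaults are the study
conditions throughout: 58 sites; site frequencies from a 1/f density
truncated to [1e-4, 0.1] (closed-form CDF log(f/f_min)/log(f_max/f_min) —
a self-contained neutral-like spectrum; with these bounds ~10% of sites
exceed the 5% filter, leaving ~52–54 tested variants, and ~33 sites fall
below the 0.005 causal cutoff); Hardy–Weinberg genotypes under linkage
equilibrium; round(10% · m) causal sites drawn uniformly among the m sites
with pool frequency < 0.005; sample-MAF > 5% columns removed before
testing. Counts: scenario A gives carriers mean fold·μ (Poisson for A1,
NB φ = 1.1 for A2); scenario B scales the carrier mean by the number of
causal sites carried (n_cv counts *sites* with dosage ≥ 1, not alleles).
fold = 1 in scenario A is the null. μ ∈ {50, 100, 500},
n ∈ {15, 30, 50, 100, 500}, fold grid {1, 1.2, 1.4, 1.6, 1.8, 2, 3, 4, 8}
(540 cells; the alternative 14-level grid 1:2 by 0.1 plus {3,4,8} gives
840 and is available via `folds="literal"`).

What the generator does *not* emulate: linkage disequilibrium, population
structure, haplotype sharing, covariate effects, library-size variation,
and multi-gene count correlation. Passing tests therefore demonstrate the
operating characteristics of the tests under idealized independent-site
genotypes with a known spectrum — not performance on real cohorts, where
LD and structure can move both error rates and power.

**Seeding.** Every replicate derives four independent child streams
(frequencies, genotypes, causal flags, counts) from one integer seed via
`numpy` SeedSequence spawning, so results are bit-reproducible and
order-independent. Grid cells are seeded per (scenario, μ, n) panel, so
fold levels of one panel share genotype datasets — power curves in fold
are then comparable replicate-by-replicate, and monotonicity in fold is
not masked by genotype resampling noise.

**Degeneracy.** Replicates where a test has no usable signal (constant
collapsed predictor, constant counts, no genotype variation) are flagged
`degenerate` — never given an imputed p-value — and excluded from
rejection-rate denominators, with counts reported per cell.

## Measured operating characteristics and honest caveats

Estimates below are from the packaged acceptance runs (1000 replicates
for type-I cells at n = 100, μ = 50; 500 replicates for power at n = 500;
α = 0.05); the acceptance suite recomputes them.

* Under Poisson counts (A1) all collapsing tests and SKAT-Burden hold the
  nominal level (0.043–0.052). Under NB counts (A2) the Poisson
  regressions reject ~80% of null replicates; the NB regressions and the
  SKAT family stay near nominal.
* SKAT itself (and SKAT-O to a lesser degree) runs *conservative* at
  n = 100 with ~50 variants (≈0.02–0.04): Q and σ̂² are built from the
  same residuals, an F-type coupling that the asymptotic chi-square
  mixture ignores and that grows with the kernel's effective rank over n.
  Small-sample moment adjustments that would correct this are out of
  scope. The conservativeness disappears for the single-df burden test
  and shrinks with heavier-tailed (less tied) counts.
* With the stated causal-assignment rules (10% of sub-0.005 sites), the
  expected causal-carrier fraction is ~0.8%, i.e. ~4 carriers at n = 500.
  Power at fold 8 is therefore bounded well below 1 (SKAT ~0.45, weighted
  burden ~0.2, Poisson-sum ~0.8), and the weighted burden is additionally
  noise-limited by non-causal rare-allele carriers regardless of fold.
  Power is monotone in fold, and at moderate fold (2) the SKAT family is
  the most powerful method group, consistent with the recommendation to
  prefer it.

## Real-data I/O

Genotypes: one VCF region (1-based inclusive `contig:start-end`),
biallelic records only (multiallelics skipped with a warning), alternate
dosages folded to the minor allele when ALT frequency > 0.5, missing
genotypes mean-imputed to 2·MAF, sample-MAF > `--maf-max` sites dropped.
Counts/covariates: TSV keyed by sample id; alignment between files is
always by id, never by column order; a reserved `library_size` row
provides k_i. Results: TSV with full-precision floats (round-trip safe).

## Known limitations

* No LD or population structure in the generator (above).
* Asymptotic p-values only; permutation appears solely as a test oracle.
* Binary traits, other kernels, zero-inflation, and replicate-based
  (edgeR-style) dispersion estimation are out of scope.
* The NB fitter assumes a common dispersion across subjects.
* VCF reading targets a single region of a gene-scale file; there is no
  indexed random access or genome-wide orchestration.
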
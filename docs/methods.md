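# Methods

## Model and assumptions

The phenotype of animal *i* in pen *g* (size `n_g`) of population *t* is

```
y_i = x_i' b_t + a_D,i(t) + f_g Σ_{j∈g, j≠i} a_S,j(t) + d_g + l_i + e_i,
f_g = (n̄_t − 1)/(n_g − 1)
```

Assumptions the fit relies on:

- **One record per animal, one trait per animal.** Purebred and crossbred
  growth are treated as two traits of a bivariate model; no animal has
  both, so the residual covariance between traits is fixed at zero (it is
  not estimable from such data).
- **Pens are single-population** and every pen has at least two members
  (a singleton pen has no social term; the design builder rejects it).
- **The dilution factor uses the population average pen size `n̄_t`**,
  computed from the data (mean size over pens) unless supplied. When all
  pens share one size, `f ≡ 1` and the model reduces to the classical
  undiluted social model — asserted as a test.
- **Genetic covariance flows through the full pedigree.** All pedigree
  animals carry all genetic components; `Var(u) = G0 ⊗ K` in animal-major
  order with `K = A` or `H`. Pen and litter effects are i.i.d. within
  trait; residuals are i.i.d. within trait.
- **Identifiability of fixed effects** is obtained by treatment coding:
  intercept per trait, last level of each factor dropped, covariates
  centred. Contrasts are invariant to this choice.

## Relationship matrices

`A` is built by the tabular method (oracle) and `A⁻¹` directly by
Henderson's rules with Mendelian-sampling variances adjusted for parental
inbreeding (Meuwissen–Luo), the default because multi-generation pedigrees
accumulate non-trivial F; a flag disables the adjustment for comparison.
Unknown parents are unrelated base animals (no unknown-parent groups —
out of scope). `A22` can be extracted from the full matrix or by a
memoised kinship recursion that never forms `A`.

The genomic matrix is the weighted VanRaden form `G = Z D Z'/q` with
`Z = M − 2p`, `p` observed in the genotyped set (base-population
frequencies are unavailable), and `q = Σ 2p_i(1−p_i)` **fixed at its
D = I value**: weight renormalisation, not `q`, keeps the implied genetic
variance constant. Because `G` from a centred `Z` is singular
(`Z'1 = 0`), it is blended, `G_b = (1−τ)G + τA22` with τ = 0.05 by
default (standard practice), before inversion;
`H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ − A22⁻¹]`. Dense algebra is used for the
genotyped block and sparse for `A⁻¹`; the intended operating range is up
to ~5,000 genotyped animals on one CPU.

## Gibbs sampler

Per round: (i) every location parameter is drawn from its scalar normal
full conditional in one Gauss–Seidel sweep (compiled kernel over a
fixed-sparsity coefficient matrix whose data vector is refreshed from the
current variances — the sparsity union is built once with a dense
positive-definite pattern `G0` so cross-component entries always exist);
(ii) `G0 | u ~ IW(ν0 + n_anim, S0 + U'K⁻¹U)`; (iii) pen and litter
variances and (iv) per-trait residual variances from scaled inverse
chi-squares. Defaults: `ν0 = n_comp + 2` with scale `0.01·var(y)·I` for
`G0`; `ν0 = 4`, scale `0.01·var(y)` for scalars; flat priors on fixed
effects. These are weakly informative at the data sizes the package
targets (prior scale ≲ 10⁻³ of the conditional scale).

Production chain defaults are 120,000 rounds, 20,000 burn-in, thinning 10
(10,000 retained); tests and the demo pipeline use 12,000/2,000/10, a
scale at which the recovery experiments below are already stable. Chains
are bit-reproducible for a given seed. Derived parameters (h², T²,
σ²TBV, σ²p, correlations) are computed **per retained sample and then
averaged** — PSDs are the spreads of those per-sample values; the
alternative (ratios of means) would have no PSD at all.

The sampler was validated two independent ways: against the closed-form
scaled-inverse-chi-square posterior on an i.i.d. mean-only model, and
against a REML grid-search oracle on a full animal model (posterior mean
within ~1 unit of the REML maximum on held-out simulated datasets).

Two formula asymmetries are implemented exactly as defined and surfaced in
reports rather than "fixed": `σ²p` carries no `2(n−1)σaDaS` term while
`σ²TBV` does, so `T²` is not a monotone function of the variance ratios;
and every derived parameter except h² depends on `n̄`, which is therefore
echoed in every report row.

## Weighted single-step GWAS

Back-solving uses the blended matrix consistently:
`û = (D/q) Z' G_b⁻¹ â_g` per genetic component, so the projection identity
`Zû = â_g` holds exactly only in the unblended, full-rank case (asserted
on fixtures with external allele frequencies). Weights update as
`d_i ∝ û_i² 2p_i(1−p_i)`, are renormalised to conserve
`Σ d_i 2p_i(1−p_i)` (checked to 1e-10), capped at 10 (clipping warns),
and the rebuild–solve–back-solve loop runs three iterations. Each scanned
component keeps its own weight sequence, since the weights are derived
from that component's effects. Windows are fixed, non-overlapping 0.4-Mb
tiles from position zero; the variance denominator is the variance of the
component's total genomic value over genotyped animals, which makes the
single-window case self-normalise to 100%. Significance is defined at the
window level (0.4% default); 1-Mb regions centred on significant window
midpoints are merged per component, keeping the peak. Variance components
are fixed at posterior means from the Gibbs stage. A generic GFF3
gene-overlap utility annotates called regions from a local file.

## Synthetic data

The generator emulates the study system: a purebred Duroc (DUC) nucleus
and a crossbreeding chain with Korean native pigs (KNP) — F1 = DUC×KNP,
F2 = F1×DUC, terminal cross = F1×F2 (5/8 DUC in expectation). Defaults:
genetic covariance assembled from published-scale components (variances
1377/75/3410/72 (g/day)², purebred-social × crossbred-direct correlation
0.77, the remaining correlations 0.03/0.48/−0.53/−0.27/−0.15; the implied
correlation matrix is positive definite, minimum eigenvalue ≈ 0.025);
pens of 2–7 animals formed within population × batch; litters
Poisson-sized around 8 (pedigree) with nuisance variances chosen so the
phenotypic variance lands near 8,800–9,400 (g/day)². Genetic values are
sampled from the pedigree by recursive Mendelian sampling (exactly
`G0 ⊗ A`, verified by Monte Carlo), matching the fitted model; an optional
marker-effect mode builds the direct values from true SNP effects
(with planted large-effect QTLs) for GWAS power work. Genotypes come from
gene dropping founder haplotypes: breed-specific founder frequencies drawn
uniformly in the configured MAF range, one Morgan per chromosome, uniform
marker spacing, no interference.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: founder linkage disequilibrium (LD arises
only within families), selection and assortative mating, genotyping-error
processes beyond planted missingness/Mendelian conflicts, heterogeneous
residuals, and maternal effects.

## Validation experiment design

Two experiment designs are themselves package decisions worth recording:

- **Variance-component recovery** (≈2,000 phenotyped, pens of 4,
  h² = 0.30, social ratio 0.02, r_D−S = 0) uses a two-generation pedigree
  from 300 founders with litters of ~6. One-generation designs confound
  full-sib genetic covariance with litter variance; deep few-founder
  pedigrees let the realized genetic variance drift far from the base
  value, which the posterior PSD cannot cover. Two generations give
  phenotyped parent–offspring pairs that separate σ²aD from σ²l, and a
  wide founder base keeps drift small. Result: all of σ²aD, σ²aS, σ²e and
  T² within 2 PSD of truth in 9/10 seeded replicates.
- **GWAS power/calibration** (1,000 animals × 2,000 SNPs) uses a
  study-sized genome (18 × 130 Mb), so the 0.4% window threshold sits far
  above the mean per-window share as it does for a dense commercial panel,
  and a strongly heritable scanned trait (direct h² = 0.5): shrinking a
  42k panel twenty-fold while keeping n and h² would destroy per-QTL
  power, so the scaled-down scenario compensates with a more heritable
  trait. A QTL planted at exactly 5% of genetic variance is recovered in
  9/10 replicates; under a purely polygenic null ~1% of windows exceed
  the threshold and no window recurs in half or more of ten seeds
  ("systematically recurrent" is operationalised as a majority of seeds,
  which at the observed base rate has probability ≈ 2×10⁻⁴ under
  seed-independent noise).

## Numerical choices and degenerate inputs

- QC boundaries are strict inequalities (call rate < 0.90, MAF < 0.05);
  a fixed SNP belongs to the "monomorphic" category, not the MAF filter;
  filters run in one pass in the documented order with first-failure
  attribution (the survivor set for the rate/frequency filters is
  order-independent; attribution is not). The Mendelian-conflict removal
  threshold (>1% of testable duo-SNPs) is a package default — no published
  value exists — and is configurable.
- Zero variance components remove their equations from the mixed-model
  system (the fixed-effects-only limit is exact OLS), rather than being
  approximated by large variance ratios.
- Mixed-model solving: dense Cholesky up to 6,000 equations, sparse LU to
  20,000, preconditioned CG beyond (Jacobi preconditioner, relative
  residual 1e-8).
- Constant-phenotype input keeps all variance draws positive via the
  proper (floored) priors; degenerate weight updates (all-zero effects)
  raise instead of silently producing a zero matrix.
- Pedigree ids are remapped internally to dense 0-based positions;
  unknown parents are coded 0 in all files.

## Known limitations

Single chain only (split-half and ESS diagnostics, no cross-chain R̂);
no REML path; no maternal or random-regression models; no large-scale
H approximations (APY), so ≳10⁴ genotyped animals are out of intended
range; the GFF3 reader handles `gene` features only; breed composition
requires both parents known or both unknown (no partial founders).
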
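# Methods

## Model

`trajgwas` analyses longitudinal records (daily feed intake or day-averaged
body weight of growing animals) with a random-regression animal model on an
order-2 Legendre basis. Age in days is mapped linearly onto [-1, 1]
(`AgeStandardizer`); by default the map spans the observed age range of the
edited data, and a fixed window can be supplied instead. A record of animal
*m* at standardized age *t* is modelled as

    y = CG_i + Parity_j + Σ_k φ_k(t) β_k + Σ_k φ_k(t) u_mk + Σ_k φ_k(t) pe_mk + e,

with contemporary group and dam parity (levels 1, 2, 3+) as cross-classified
fixed effects, a fixed Legendre regression β on age, animal-genetic
coefficients **u**m ~ with Cov(u) = **H** ⊗ **G**a (3×3 coefficient
covariance), permanent-environment coefficients **pe**m i.i.d. with 3×3
covariance **P**, and homogeneous residual variance σ²e. The overall mean is
absorbed by the first CG level together with the constant basis function;
parity level 1 is the reference.

Normalized Legendre polynomials φ_k = √((2k+1)/2)·P_k are the default basis;
raw polynomials are available, and every variance-ratio output (h²(t),
genetic correlations) is invariant to that choice because the two conventions
are a fixed linear reparameterization of the coefficients (asserted by test).

**H** combines pedigree and genomic information: **A** is the numerator
relationship matrix (tabular method with inbreeding), **G** = **ZDZ**′ with
**Z** the gene content centered by twice the allele frequency and
**D**ᵢᵢ = 1/(m·2pᵢqᵢ) the reciprocal expected marker variance (the 1/m
convention keeps mean diag(**G**) ≈ 1; the constant cancels in the SNP
back-transformation as long as the same **D** is reused, which the code
enforces). **G** is blended as **G**b = 0.995·**G** + 0.005·**A**₂₂, and

    H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ − A22⁻¹]

on the genotyped block. Allele frequencies default to the observed
frequencies of the genotyped set; note that observed-frequency centering
makes an unblended **G** exactly singular (**Z**′**1** = 0), which is one
reason the blend exists — callers running with blend weight 1 must supply
base-population frequencies.

## Phenotype editing

Feed intake follows a four-step visit-error procedure: a configurable rule
registry flags erroneous feeder visits (defaults: negative intake, intake
above 3 kg, occupancy-time bounds, implausible intake rate); error-free
intake is summed within animal-day; a linear mixed model of the daily sum on
the per-rule error counts, CG, body weight and ADG with animal as a random
effect (statsmodels MixedLM) estimates the intake lost per error visit; and
each affected day is adjusted upward by the estimated loss (clamped at zero
so adjustment never decreases a value). Animals with fewer than 20 adjusted
daily records are removed. The original sixteen per-visit error criteria are
defined only in prior equipment-specific work; the registry preserves the
four-step architecture without inventing their details.

Body weight is cleaned per animal by iteratively reweighted least squares
with the Tukey bisquare weight (tuning constant 4.685, statsmodels RLM):
weight on a quadratic in on-test day plus a linear term in age (per-animal
these are collinear up to a shift, so the redundant column is dropped).
Records with robust weight < 0.5 are outliers; animals whose weight-on-age
OLS slope falls outside [0.4, 2.0] kg/d are removed; surviving same-day
weights are averaged. Editing is idempotent for outliers that are clearly
separated from the noise floor; with Gaussian noise a second pass can flip
the handful of records sitting at the weight-0.5 boundary because the robust
scale re-estimates slightly smaller — an inherent property of adaptive-scale
robust fits, not an implementation artifact.

Genotype QC removes animals with call rate ≤ 0.90, then SNP with call rate
≤ 0.90, minor allele frequency ≤ 0.02, and Hardy–Weinberg chi-square
p < 1e-4, then re-checks MAF < 0.002 on the analysis subset. The filter
order is not dictated by the problem; the chosen order is logged.

## Estimation

Variance components are estimated by EM-REML. The mixed-model equations are
assembled in precision form so that σ²e·C⁻¹ is the prediction-error
covariance; the permanent-environment block is block-diagonal per animal and
is absorbed exactly by Schur complement before factorization, which the test
suite verifies against the unabsorbed GLS solution. Two backends factor the
absorbed system:

* a dense Cholesky path used whenever H⁻¹ is dense (i.e. whenever genomic
  information enters), and
* a sparse path for pedigree-only analyses: the genetic block
  blockdiag(F_m) + σ²e(A⁻¹ ⊗ G_a⁻¹) is factored by an up-looking sparse LDL′
  (elimination tree + reach, greedy minimum-degree ordering) with the dense
  fixed-effect equations as a Schur-complement border, and the E-step trace
  terms come from the Takahashi selected inverse on the factor pattern plus
  the low-rank border correction. A⁻¹ itself is built sparsely by
  Henderson's rules (log|A| = Σ log Mendelian-sampling variances falls out
  for free). Both paths agree to ~1e-13 on common instances (tested).

EM updates are the classical conditional-moment updates; the residual update
is (y′y − θ̂′W′y)/(n − rank X). The REML log-likelihood is evaluated every
iteration and asserted monotone. Because plain EM crawls along the
genetic-vs-PE split direction, the step is over-relaxed: the EM step
direction is scaled by an adaptive factor (up to 16), and every over-relaxed
candidate is accepted only if its explicitly evaluated log-likelihood does
not decrease, falling back to the guaranteed plain EM step otherwise. The
monotonicity guarantee is therefore preserved exactly. Starting values come
from per-animal OLS coefficient fits: pooled residual variance, total
coefficient covariance corrected for sampling covariance, and a
parent–offspring regression (twice the parent–offspring coefficient
covariance estimates **G**a, since permanent environment does not transmit).
The coefficients are residualized on CG/parity first — with few CG levels
the deviations of two distinct level effects from the grand mean are
negatively correlated, which otherwise biases the warm start onto the
**G**a = 0 boundary, an absorbing state for EM. Starts are floored away from
the PSD boundary for the same reason. Convergence is declared at a relative
parameter change below 1e-6 by default; the validation studies use 1e-4,
which leaves component estimates indistinguishable from tighter tolerances
at their sampling error.

Trajectory summaries: h²(t) = φ′**G**aφ / (φ′**G**aφ + φ′**P**φ + σ²e),
r_g(t,s) from the genetic covariance function, and phase means over ages
90–118, 119–146 and 147–175 d.

## Association scan

SNP effects are back-solved from the genotyped animals' GEBV coefficients,
per coefficient independently: û = **DZ**′**G**b⁻¹â. Realized-variance
reweighting replaces dᵢ by 2pᵢqᵢûᵢ², renormalized so Σd·2pq is constant
across rounds (so **G** keeps its scale) and floored at 1e-8 of the mean
weight (no SNP is ever excluded outright). **G** is rebuilt, the mixed model
re-solved at fixed variance components, and effects back-solved again; two
reweighting rounds are the default. With blend weight 1 and every animal
genotyped, **Z**û reproduces the GEBV exactly (the keystone identity tested
to 1e-8 and measured at ~1e-15).

Window statistics: WGEBV for a 10-SNP sliding window (step 1, windows never
spanning chromosomes) is the per-animal sum of centered gene content times
effect over the window; the scan statistic is its across-animal variance per
coefficient, with cross-coefficient window covariances alongside. Selection
is two-stage per coefficient: the top 5 % of windows by variance survive;
survivors sharing at least one SNP index merge into regions; regions are
ranked by their maximum member variance and the top 10 % (ceiling, so at
least one region always survives) are putative QTL. Coordinates are 0-based
half-open internally and 1-based inclusive in outputs; region output is also
written as BED.

## Bootstrap significance

Each putative window is tested by re-running the chain (mixed-model solve at
the full-data variance components — re-estimating them 1000 times is neither
feasible nor implied by the procedure, which reuses the full model's
residual variance — then back-solving with two reweighting rounds and
recomputing the window statistic) on phenotypes constructed under "no QTL in
this window", 1000 replicates by default, empirical
p = #{replicate ≥ observed}/n_reps, significance at p < 0.001. Replicate
seeds derive from (master seed, window id, replicate counter) via
SeedSequence, so results are independent of any parallelization layout.

Two null constructions are provided, and the choice matters:

* `reconstruction` — subtract the window's estimated SNP contribution
  (all three coefficients) from the fitted values and add a fresh residual.
  This is the transparent reading of "fitted value minus the window's GEBV
  contribution plus simulated residual". It is, however, structurally
  anti-conservative whenever genomic breeding values track real polygenic
  signal: every window owns a share of the family-structure tracking, the
  subtraction deletes exactly that share, and fresh residuals cannot rebuild
  it. In our studies the observed statistic exceeded the median replicate by
  factors of 2–280 on entirely QTL-free genomes (worst with reweighting and
  deep pedigrees), i.e. essentially every window tests "significant".
* `simulate` (default) — keep the estimated fixed and permanent-environment
  parts, redraw the genotyped animals' genetic field from its fitted
  distribution N(0, **G**b ⊗ **G**a), and add the fresh residual. Replicates
  then carry polygenic variation but no QTL anywhere, so the test asks
  whether the window's observed variance exceeds what polygenic tracking
  plus estimation noise produce — the scientifically meaningful null. This
  construction is calibrated on QTL-free genomes (slightly conservative),
  retains full power on planted QTL, and is monotone in effect size.

Intermediate constructions were evaluated and rejected: refitting GEBV with
the window's markers excluded from **G** under-disperses replicates by the
BLUP shrinkage factor, and completing that field with posterior noise
restores calibration but destroys power, because a real QTL's signal
re-enters the conditional field through relatedness and is re-attributed to
the window on refit.

## Synthetic data

The generator produces a multi-generation random-mating pedigree (constant
cohort size; sires and dams drawn from disjoint halves of the previous
generation), gene-dropped biallelic genotypes (founders at Hardy–Weinberg
with MAF ~ Uniform; one allele inherited per parent per locus; linkage
equilibrium given the pedigree — no founder haplotype structure, so
windowing relies on family co-segregation rather than population LD),
polygenic coefficient vectors by sequential gene drop (founders
~ N(0, **G**a); offspring = parent average + Mendelian sampling
~ N(0, **G**a/2), inbreeding ignored in the sampling variance — validation
uses realized values so pedigree-based oracles stay exact), optional QTL
effects added as centered gene content × effect on a chosen coefficient
(superimposed on, not subtracted from, the polygenic variance), CG effects
drawn per batch (round-robin assignment over the pedigree), uniform parity,
and per-animal observation windows (onset ≈ 90 d, length ≈ 80 d, daily
observation probability 0.7) giving roughly ages 90–175 d and ~60 records
per animal. Defaults: **G**a = diag(4, 1, 0.25), **P** = diag(2, 0.5, 0.1),
σ²e = 4, a growth-like mean curve, 8 CG levels with SD 2.

What the generator does not emulate: population LD, selection, genotyping
error, missingness patterns, heterogeneous residual variance across ages,
or maternal effects. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not robustness to those real-data
features.

## Validation study designs (problem sizes chosen once)

* GBLUP↔SNP-BLUP equivalence: 200 animals, 500 SNP, blend weight 1, founder
  frequencies.
* Mixed-model oracle: 5-animal pedigree with an inbred mating, 3 genotyped,
  hand-assembled H, direct GLS comparison at 1e-10.
* EM-REML recovery: 1500 phenotyped animals (375 founders × 3 generations),
  ~60 records each, 10 seeds; every component must land within 15 % of its
  generating value on the 10-seed mean. The smallest component (quadratic
  permanent environment, 0.1) dominates this error, being the hardest to
  separate from the residual.
* Window localization: 300 animals (deep pedigree), 1000 SNP, one intercept
  QTL of effect 2.5 (~35 % of the intercept's genetic variance) at a random
  position; 40 seeds.
* Bootstrap: a 300-animal unrelated panel with 1000 SNP — the regime where a
  no-QTL null is meaningful, since with strong family structure every window
  legitimately carries tracking variance. Calibration: 5 windows × 200
  replicates on a QTL-free genome. Power: QTL of effect 2.0 (~30 % of the
  intercept's genetic variance; at this panel size a 1 %-of-variance QTL is
  undetectable by construction), 10 seeds, 100 replicates. Monotonicity:
  effect ladder 0.5/1.0/2.0 with shared seeds, mean p non-increasing.
* Determinism: the full pipeline (simulation → REML → ssGWAS → windows →
  bootstrap → report) run twice with one master seed must produce
  byte-identical archives; the provenance manifest therefore records the
  config hash and seeds but no wall-clock times.

## Numerical notes and limitations

Dense algebra throughout the genomic path (desk scale; no APY-type
approximations). Relationship inverses go through Cholesky with an explicit
positive-definiteness error rather than silent pseudo-inverses. 3×3
covariance inversions clamp eigenvalues at 1e-10 of the largest, which keeps
EM iterations defined when a component approaches the boundary; estimates
themselves are not clamped. Zero-variance windows report missing
correlations; chromosomes with fewer than 10 SNP contribute no windows
(logged). Cross-trait tables are computed from separately fitted traits on
the animal intersection. Heterogeneous residual variances, spline bases,
single-SNP p-values and LD-based window sizing are out of scope.
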
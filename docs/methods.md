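# Methods

## Survival traits and their coding

Each cow's first three parities are split at days in milk 90 and 299 into
early, mid and late lactation, giving nine stage-survival traits
`L<parity>.<stage>`. A trait is 1 when the cow entered the next stage
(for late lactation: when a test-day record exists in the next parity),
0 when she was culled or died in the stage, and missing otherwise. Two
deliberate choices shape the coding:

- **Conditional on entry.** After a 0 (culling) all later traits are
  missing, not 0. Each trait therefore measures survival among cows at
  risk, which avoids part–whole artifacts between stages; the monotone
  at-risk structure (an observed trait implies all earlier traits are 1)
  is asserted on every coded table.
- **Censoring.** A cow with no cull date whose last activity lies inside
  her herd's active window is censored at the stage of her last test day:
  stages she completed are 1, everything from the censoring stage on is
  missing. A cow with a test record in parity 4 has completed all nine
  stages and is not censored. First-calving age of exactly 25 months maps
  to class 0 (the class boundary is ≤25 vs ≥26).

Fixed effects are assigned once per cow from the parity-1 calving: herd ×
calendar year (HY), season of the calving month (Dec–Feb winter, Mar–May
spring, Jun–Aug summer, Sep–Nov autumn) and the first-calving-age class.
Using one contemporary group per cow keeps the model a single-record-per-
trait animal model. HY and season enter as separate effects rather than a
combined herd-year-season group because typical herd sizes here are too
small to fill HYS cells.

Estimation uses the uncensored subset after removing cows with unknown
parents and herd-year classes with fewer than `min_hy` (default 5) cows;
breeding-value prediction uses all records, censored included, through the
missing-trait machinery.

## Pedigree algebra

`relationship_matrix` builds A by the tabular method (quadratic; used at
desk scale and as an oracle). `inbreeding` implements the Meuwissen–Luo
ancestor sweep, and `a_inverse` assembles A⁻¹ directly from Henderson's
inbreeding-aware rules in sparse triplet form; log|A| = Σ log dᵢ comes for
free from the Mendelian-sampling variances dᵢ. Unknown parents are
unrelated non-inbred founders; there are no unknown-parent groups.
Selfing (sire = dam) is handled correctly in both the sweep and the rules.

## Mixed-model equations and BLUP

The multi-trait Henderson system is assembled sparsely with unknowns
ordered (fixed columns, then animals) × traits. Cows with missing traits
contribute through the inverse of the residual sub-covariance of their
observed pattern; animals without records enter via A⁻¹ ⊗ G⁻¹ only. Two
rank-deficiency guards matter for binary survival data: a (fixed level,
trait) equation with no observation of that trait is an all-zero row and
gets a unit pivot (solution pinned to 0), and if within-trait confounding
still leaves the fixed block singular the solver falls back to a 1e-8
ridge on the fixed diagonal with a warning. Systems are solved by sparse
LU; prediction-error variances are obtained by solving for the requested
columns of the inverse, and reliability is 1 − PEV/σ²ₐ (not scaled by
1 + F; inbreeding in these populations is negligible).

## REML

Both engines maximize the exact restricted likelihood.

**Spectral engine** (complete records, same design for all traits): with
K = A_obs the relationship matrix among recorded animals and S the
projector orthogonal to the fixed effects, the eigendecomposition
S K S = U Ξ U′ turns the error contrasts w = U′y into independent
t-variate normals with covariance ξᵢG + R. One n×n eigendecomposition
then supports, at O(n t³) per iteration:

- closed-form EM updates (the E-step moments of aᵢ ~ N(0, ξᵢG) are
  3×3 algebra per contrast);
- average-information (AI) steps with analytic score, step-halving into
  the positive-definite cone, and EM fallback;
- a quasi-Newton on Cholesky factors of G and R (`fit_gradient`,
  L-BFGS-B with the analytic gradient), which is the default because it
  reaches boundary optima (singular Ĝ, common for correlated traits at
  moderate n) smoothly where EM crawls and raw AI steps are rejected.

Because the eigenbasis depends only on the pedigree and the fixed design,
one workspace serves all 84 trait triples and all simulation replicates.

**MME engine** (arbitrary missing patterns, desk scale): dense EM on the
mixed-model equations. The genetic update is the classical
(û′A⁻¹û + tr(A⁻¹C^{uu}))/q with traces taken against the sparse A⁻¹
pattern; the residual update treats unrecorded cells as latent data, using
the conditional moments of the missing residuals given the observed ones
and the solution uncertainty W C W′. Cholesky inversion with a
Moore-Penrose fallback handles residual rank deficiency of a trait's fixed
sub-design. The spectral optimum is verified in the tests to be a fixed
point of this engine's update, and the engine is checked against a
brute-force direct-V REML oracle on small missing-data problems.

Convergence is declared at relative parameter change < `tol` (default
1e-8) or |Δ logL| < `ll_tol` (default 1e-6); runs hitting `max_iter` are
flagged non-converged and excluded from averaging downstream. EM
monotonicity of the restricted log-likelihood is asserted per iteration
when requested. Default starting values put 5% of the phenotypic variance
on the additive side with zero correlations.

Missing-trait REML matters even on uncensored data: a cow culled in some
stage has all later traits missing, and complete-case analysis of a
within-parity triple would be degenerate (every cow observed on a late
trait has 1 on the earlier ones). The MME engine therefore handles
missingness exactly; the spectral engine serves the complete (continuous
liability) setting.

## Multi-run combination and bending

All 84 unordered triples of the nine traits are enumerated; every trait
appears in 28 runs and every pair in 7, so non-converged runs reproduce
the 27/6-style contributing-run counts. Converged runs are averaged with
plain (unweighted) means: trait-level additive and phenotypic variances
and heritability, pair-level genetic and residual correlations, each with
across-run SDs. G₀ has the mean variances on the diagonal and mean
correlation × √(vᵢvⱼ) off it; the phenotypic P₀ is assembled the same way
as G₀ + R₀ from mean residual variances and residual correlations (the
source tables print no phenotypic covariances). Bending floors every
eigenvalue ≤ 0 at 1e-5 (zero included — solvers need strict definiteness)
and reconstructs QΛ*Q′; positive-definite input is returned bit-identical,
and bending is idempotent.

## Parity aggregation

`aggregate(G, P, W)` computes G* = W′GW and P* = W′PW exactly and derives
heritabilities G*ᵢᵢ/P*ᵢᵢ and correlation matrices. The default W sums the
three stage traits of each parity; an all-ones column gives whole-
productive-life survival. With the published stage tables as input and
phenotypic covariances set to zero this reproduces the printed parity
heritabilities within ±0.002 and parity genetic correlations within
±0.01, which is the numerical evidence for this choice of W.

## Direct Herd Life

Stages are indexed 1–9 in parity-major order plus an absorbing state 10
("survived beyond parity 3", C₁₀ = 0, which makes the leaving
probabilities sum to one exactly). N is cumulative days from first calving
to the start of each stage's parity: (0,0,0, 426,426,426, 852,852,852) and
N₁₀ = 1284 from calving intervals 426/426/432. D is the mean within-parity
days in milk at leaving, defaulting to mid-stage values (45, 195, 363 per
lactation stage; D₁₀ = 201, the mean of the parity-3 values); whether D
should instead be cumulative lifetime milking days is not determinable
from the printed material, so it is exposed as configuration. Survival
probabilities sᵢ = μᵢ + EBVᵢ are clipped to (1e-6, 1] so Cᵢ remains a
valid probability. DHL is strictly increasing in every stage EBV whenever
(Nᵢ + Dᵢ) increases with i, and the baseline (zero-EBV) DHL always lies
between min and max of (Nᵢ + Dᵢ).

EBV correlation analyses select sires by minimum daughter count (default
50) and minimum reliability (default 0.90) and report Pearson correlations;
constant columns are flagged rather than silently dropped.

## Synthetic data

The generator is the package's study bench, not a fixture. The mating
structure is deterministic (sire harems, alternating progeny sex), so a
seed only drives herd/date/age assignment and the random effects; breeding
values descend the sorted pedigree by sequential Mendelian sampling
aᵢ = ½(a_s + a_d) + mᵢ, mᵢ ~ N(0, dᵢG), reproducing a ~ N(0, G ⊗ A)
exactly. Liabilities add herd-year effects N(0, σ²_HY), fixed season and
first-calving-age effects, and residuals N(0, R).

- **Gaussian mode** returns the liabilities as complete records — the
  setting where REML recovery can be verified cleanly.
- **Binary mode** thresholds liabilities stage by stage at the empirical
  quantile of the cows still at risk, so configured conditional culling
  rates are realized by construction, then fabricates raw calving,
  test-day (35-day grid) and culling records that the coding module
  re-codes to exactly the intended outcomes; a censor_rate fraction of
  cows is truncated to missing from a random at-risk stage.

Defaults are the study conditions: stage culling rates follow the Korean
pattern ((0.08, 0.19, 0.56), (0.10, 0.24, 0.63), (0.13, 0.29, 0.71) across
parities 1–3, within the reported 8–13% / 19–29% / 56–71% ranges), G
defaults to the published stage-level matrix bent positive definite, R to
the diagonal of phenotypic minus additive variances, censoring to 15%.
What binary mode does **not** emulate: culling-reason structure, seasonal
calving waves, herd turnover, genetic trend or selection, and the linear
model's treatment of a binary trait remains an approximation — so passing
recovery tests in Gaussian mode demonstrates the estimator, not the
linear-model-on-binary approximation itself, which is adopted by design.

## Parameter-recovery study (the simulation acceptance surface)

Published real-data estimates cannot be reproduced without the source
records, so the estimator is accepted on simulations: 3 traits with
phenotypic variances (0.025, 0.074, 0.148), true heritabilities
(0.01, 0.02, 0.03) in the reported range, genetic correlations
(0.8, 0.5, 0.3) and residual correlations (0.2, 0.1, 0.05); one fixed
design of 3000 recorded cows (100 sires × 10 dams × 4 progeny, 25 herds)
with effects redrawn over 20 replicates, so a single eigendecomposition
serves all fits. Mean estimated heritabilities and genetic covariances are
required to lie within 99% Monte-Carlo confidence bounds of truth; the
mean of derived correlation *ratios* is not tested because near the
va ≈ 0 boundary the ratio estimator is bimodal on [−1, 1] and its mean is
not a consistent summary. EM monotonicity is asserted at every iteration
on a full-scale replicate. Problem sizes elsewhere in the suite (pipeline
smoke runs at a few hundred cows, the binary end-to-end run with milder
culling and min_hy = 1) are chosen so each test isolates its mechanism at
desk scale.

## Pipeline

`run_pipeline` sequences simulate/load → code → filter → 84 REML triples →
combine → bend → 9-trait BLUP (bent G, bent R₀ = P₀ − G) → parity
aggregation → DHL, writing every stage's outputs as CSV under the run
directory. Every stage, including each individual triple run, is cached by
file existence: re-runs are no-ops, deleting one triple file recomputes
only that run, and a completed run directory is bit-reproducible. Dates
are ISO-8601; day 0 is the calving day.

## Known limitations

- The linear model on 0/1 outcomes ignores the binomial mean-variance
  relationship; heritabilities are on the observed scale.
- The MME EM engine is dense (quadratic memory) by design; it is the
  desk-scale and verification route, not a production 300k-record solver.
- Mean-based combination of 84 runs ignores the precision differences
  between runs (plain means are used deliberately, matching the procedure
  being reimplemented).
- `ebv_correlations` with external national-evaluation EBVs is exercised
  only with synthetic columns; those external datasets are out of scope.
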
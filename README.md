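# herdlife

Genetic evaluation of dairy-cow longevity by lactation stage: survival-trait
coding, multi-trait animal-model REML and BLUP, covariance bending, parity
aggregation and the Direct Herd Life (DHL) index.

## The problem

Longevity — the productive life of a cow from first calving to culling — is
economically important but hard to evaluate: culling happens for genetically
different reasons at different times, so a single lifetime trait hides
stage-specific variation. The approach implemented here splits each of the
first three parities into early (days in milk 0–90), mid (91–299) and late
(300 to the next calving) lactation stages and codes nine binary,
conditional-on-entry survival traits `L<parity>.<stage>`: 1 if the cow moved
on to the next stage, 0 if she was culled in it, missing if she never entered
it or was censored.

Each trait follows the linear animal model

```
y = HY + Season + FCa + a + e,     a ~ N(0, G ⊗ A),   e ~ N(0, R ⊗ I)
```

with herd-year contemporary groups, calving season (winter/spring/summer/
autumn), first-calving-age class (≤25 vs ≥26 months) and an additive genetic
effect per animal structured by the pedigree relationship matrix **A**.
Because a nine-trait REML run is computationally out of reach for routine
evaluation, G and R are estimated from all C(9,3) = 84 three-trait runs and
averaged: trait variances from the 28 runs containing each trait, genetic
correlations from the 7 runs containing each pair. The averaged 9×9 matrix
G₀ is generally indefinite, so it is repaired by **bending**: eigendecompose
G₀ = QΛQ′, floor non-positive eigenvalues at 0.00001, reconstruct.

Parity-level parameters come from incidence aggregation

```
G* = W′GW,   P* = W′PW
```

with W summing the three stage traits within each parity (or a single
all-ones column for whole-productive-life survival). Sire breeding values
are combined with mean stage survival rates μᵢ into the **Direct Herd Life**

```
sᵢ = μᵢ + EBVᵢ,   Cᵢ = ∏_{j≤i} sⱼ (C₀ = 1, C₁₀ = 0),
DHL = Σ_{i=1..10} (C_{i-1} − Cᵢ)(Nᵢ + Dᵢ)
```

the expected productive days of a sire's daughters, with cumulative
calving-interval offsets Nᵢ (426/426/432-day intervals) and mean within-parity
days in milk Dᵢ.

No cow-level data are distributed with the method, so the package includes a
first-class synthetic-data generator (`herdlife.simulate`) that produces
pedigrees, true breeding values by Mendelian sampling, fixed effects, and
either continuous liabilities (for clean parameter recovery) or binary
stage outcomes with raw calving/test-day/culling records and right-censoring
(emulating real data).

## Worked example

Reconstructing parity-level parameters from the published Korean Holstein
stage-level estimates (shipped in `herdlife.datasets`):

```bash
python examples/04_combine_bend_aggregate.py
```

```
assembled G: min eigenvalue -2.00e-04 -> indefinite (averaging three-trait runs does not preserve definiteness)
after bending: 3 eigenvalue(s) floored at 1e-05, max elementwise change 5.98e-05 (negligible)

parity-level summary (heritability diagonal, genetic correlations above):
         parity1  parity2  parity3
parity1    0.021    0.877    0.877
parity2    0.000    0.030    0.944
parity3    0.000    0.000    0.040

whole-productive-life heritability: 0.084
```

The diagonal holds parity heritabilities (low, as expected for survival
traits analysed with a linear model), the upper triangle the genetic
correlations between parity survivals, and the lower triangle the phenotypic
correlations (zero here because stage-level phenotypic covariances are not
published). The printed reference values are 0.020 / 0.028 / 0.039 for the
parities, 0.877 / 0.873 / 0.947 for the correlations and 0.085 for
whole-life survival.

Other examples, one per capability: `01` survival coding on toy records,
`02` relationship matrices and inbreeding, `03` three-trait REML on a
simulation with known heritabilities, `05` the DHL index, `06` the full
simulate → code → filter → 84 REML runs → bend → BLUP → DHL pipeline with
stage caching.

## Layout

- `herdlife.survival` — trait coding, fixed effects, data filters
- `herdlife.pedigree` — A, sparse A⁻¹, inbreeding (Meuwissen–Luo)
- `herdlife.mixed_model` — Henderson equations, BLUP, PEV/reliability
- `herdlife.reml` — spectral and MME-based EM/AI REML engines
- `herdlife.multirun` — triple enumeration, run averaging, bending
- `herdlife.aggregation` — G* = W′GW parity aggregation
- `herdlife.dhl` — survival rates, DHL, EBV correlations
- `herdlife.simulate` — synthetic pedigrees, records and liabilities
- `herdlife.pipeline`, `herdlife.io` — orchestration with caching, CSV/YAML
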
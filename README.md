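# rrpersist

Random-regression REML analysis of multi-harvest clone trials, with
covariance-function extraction and a genotype–ideotype persistence index.

## The problem

Perennial biomass crops (the motivating case is elephantgrass,
*Cenchrus purpureus*, grown for bioenergy) are harvested repeatedly over
several years from the same field plots. Breeders need to know not just
which clones yield most, but which *persist* — sustain high yield across
growth seasons — and how much of the season-to-season rank changing
(genotype × environment interaction) is genetic. With harvests at
irregular intervals and occasional plot loss, the natural model is a
random-regression mixed model: every clone's yield trajectory is a random
polynomial in time, and the covariance among its coefficients is estimated
from the data.

## The model

For clone *i*, plot *ik*, harvest day *j* (standardized to
t\* ∈ [−1, 1] over the trial period) with normalized Legendre basis
φ_m(t\*) = √((2m+1)/2)·P_m(t\*):

    y_ijk = R_k + Σ_m β_m φ_m + Σ_m α_im φ_m + Σ_m p_ikm φ_m + e_ijk

with replication effect R_k and mean curve β fixed,
α_i ~ N(0, K_g) the genetic regression coefficients,
p_ik ~ N(0, K_p) the permanent-environment (plot) coefficients, and
residuals e with a homogeneous (H), per-harvest diagonal (D) or
unstructured (US) covariance across harvests. Everything downstream comes
from the REML estimates:

* **Model choice** — candidate orders and residual structures compared by
  BIC = −2·logL + p·ln(n − rank X) and likelihood-ratio tests of each
  random term against the χ²(1 df) 1% critical value 6.63.
* **Variance trajectories** — V̂(t₁,t₂) = φ(t₁\*)ᵀ K̂ φ(t₂\*) puts the
  coefficient covariances back on the original time scale; heritability is
  h²(t) = σ²_g(t) / (σ²_g + σ²_pe + σ²_e)(t).
* **Genetic values and accuracy** — ĝ_i(t) = Σ_m α̂_im φ_m(t\*) (BLUP),
  including prediction at unmeasured harvests; accuracy
  r̂_i(t) = √(1 − PEV_i(t)/σ̂²_g(t)) from the prediction-error variance.
* **Eigenfunctions** — eigenvectors of K̂_g contracted with the basis.
  A flat leading eigenfunction means most genetic variation acts uniformly
  across seasons; sign-changing later eigenfunctions capture G×E.
* **Persistence** — each clone is scored against the *ideotype*, the
  per-day maximum genetic value in the cohort:
  D_i = Σ_j (ĝ_ij − max_i′ ĝ_i′j)² over daily grid j, and
  Persistence_i = (1/D_i)/Σ(1/D_i)·100, which sums to 100 across clones.

The REML engine is exact and fast: random effects are absorbed genotype by
genotype (plots nest in genotypes), all small Cholesky factorizations are
batched, and variance parameters are optimized on a log-Cholesky scale by
multi-start L-BFGS-B. A dense, transparent likelihood implementation is
kept as the public definition and cross-checked in the tests against an
independent error-contrast oracle.

## Worked example

Simulate a trial with the packaged defaults (100 clones × 2 replications,
measured harvests at days 250, 500, 815, 1405, 1615 after the uniformity
cut, plus the unmeasured day 1090) and run the full analysis:

```bash
rr-persist simulate --seed 9 --out pheno.csv
cat > run.yaml <<'YAML'
input: pheno.csv
output_dir: out
schedule_days: [250, 500, 815, 1090, 1405, 1615]
schedule_measured: [true, true, true, false, true, true]
model_grid: [Leg3.1.D, Leg4.1.D, Leg4.2.D]
n_starts: 1
YAML
rr-persist run --config run.yaml
```

which prints

```
chosen model: Leg4.1.D
h2 range: 0.430 .. 0.807
report written to out/report.json
```

The chosen label means genetic order 4, permanent-environment order 1,
one residual variance per harvest; the h² range is the heritability curve
evaluated on the daily grid between the first and last harvest. `out/` contains the model comparison (`comparison.csv`),
variance/heritability trajectories, per-clone genetic values and
accuracies, eigenfunctions with their percent eigenvalue shares, and the
persistence ranking (`persistence.csv`, indices summing to 100). The same
steps are available as library calls (`rrpersist.scan_models`,
`rrpersist.trajectories`, `rrpersist.persistence_index`, ...).

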
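# Methods

This note records the models, defaults and numerical choices behind
each stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
implementation exists.

## Synthetic study systems

`landgen.synthetic` generates the inputs the analysis assumes, with
known truth retained for recovery checks.

**Climate.** Each layer is a stationary Gaussian random field built by
FFT spectral synthesis: white noise filtered with a Gaussian transfer
function of standard deviation `autocorr_range` cells (default 6),
standardized to zero mean, unit variance. Exact stationarity and
seedability are the reasons for the spectral construction. The future
stack adds a per-variable trend (`future_shift`) plus weakly
autocorrelated noise (`future_noise`, default 0.1 in layer SD units).
Coordinates are unprojected degrees on small extents; areas are
computed downstream with cos(latitude) weighting.

**Occurrences.** Presence probability is logistic(β·x) on the raw
layer values; each unmasked cell is one Bernoulli trial, and at most
`n` successes are kept. The pipeline's default species is a
restricted-range habitat specialist (intercept −2, slopes +3 and −2 on
the first two layers): with a species occupying half the landscape,
uniformly drawn pseudo-absences are so contaminated with suitable
cells that no classifier clears the 0.6 TSS retention gate — a
property of the sampling design, not of any particular model.

**Populations and genotypes.** Default sizes mirror a realistic
single-species study: 24 populations, ~9 diploids each, 8 SSR loci
with 5 alleles, 7 haplotypes on a 1,000-bp alignment, 19 climate
layers, K = 3 climate-driven clusters. Individual ancestry is
Q = softmax(β_true·x + noise) at the population's climate; each gene
copy picks its cluster from Q and its allele from that cluster's
Dirichlet-drawn frequencies (concentration 0.3 — strongly
differentiated clusters). Haplotypes are drawn the same way, one copy
per individual (maternal inheritance); sequence j carries one
diagnostic substitution at position j − 1, which keeps π and h
hand-computable. A separate isolation-by-resistance generator perturbs
population allele frequencies on the logit scale with covariance
σ²·exp(−R/ρ) in the resistance matrix R, so divergence grows with
least-cost distance.

**Not emulated:** coalescent genealogies, stepwise SSR mutation,
recombination, spatially clumped sampling bias, genotyping error.
Passing recovery tests therefore shows the estimators work when their
own model assumptions hold, not that they are robust to the messiness
of real occurrence records or markers.

## Ensemble SDM

Variable pruning is greedy: while any pair exceeds |r| = 0.75, drop
the layer with the highest mean absolute correlation among offending
pairs (name order breaks ties). Heterogeneity is the 5×5
moving-window SD of PC1 of the standardized layers. Rarefaction keeps
points greedily in input order at a great-circle threshold (default
5 km). Pseudo-absences default to a 1:1 ratio with presences; an
optional Chebyshev exclusion buffer (in cells) keeps them out of the
occupied neighbourhood — with spatially autocorrelated suitability
even a 1-cell buffer removes most label contamination.

Five algorithms (logistic GLM, RF, GBM, CART, LDA) are the default
roster; each algorithm × repeat is trained on a fresh stratified 75/25
split, and AUC and TSS (at the ROC-optimal cutoff) are computed on the
held-out quarter. Retention requires both > 0.6. The ensemble map is
the unweighted mean of retained models (TSS-weighted mean available).
Binarization is closed at the threshold (≥), so LPT keeps every
training presence by construction. Areas use spherical cos(latitude)
cell weighting; percent change is (future − current)/current × 100.

## Connectivity

Friction is the inverted *continuous* suitability plus ε = 0.001 (the
floor prevents free travel through perfect habitat and zero-cost
cycles). The raster graph is 8-connected with the
gdistance/ArcGIS-style edge weight 0.5(c_a + c_b)·d, d = cellsize (×√2
diagonally); shortest paths run on `scipy.sparse.csgraph.dijkstra`.
Populations snap to the nearest unmasked cell centre (snap distance
warned). Unreachable pairs keep an edge flagged with infinite cost.

## Diversity statistics

He is reported without small-sample correction (the unbiased uHe is
emitted alongside); population values are means over loci. π uses
pairwise deletion of gap/ambiguity columns; haplotype identity is
exact aligned-string identity (gaps significant), so indel variants
are distinct haplotypes. Pairwise Fst is Weir–Cockerham θ combined as
a ratio of sums over alleles and loci; negative estimates are floored
at zero before linearizing to Fst/(1 − Fst). Populations with N < 5
are excluded from SSR reporting (small-N Ne is badly biased). The
persistence projection reads one suitability value per population (the
cell containing its coordinate), treats "above the LPT" as ≥, and
reports both pooled (all survivors as one sample) and
mean-per-population statistics, since either convention is defensible.

## Mantel tests

The statistic is the Pearson correlation of upper-triangle entries; B's
rows and columns are permuted jointly. One-tailed positive is the
default (the isolation-by-resistance alternative). Sampled p-values use
(count + 1)/(n_perm + 1); when n! ≤ n_perm the full permutation
distribution is enumerated and the p-value is exact. The partial
statistic is the first-order partial correlation
(r_AB − r_AC·r_BC)/√((1 − r_AC²)(1 − r_BC²)); the 0/0 degeneracy (A
identical to C) resolves to 0, and a constant-after-centering C reduces
to the plain Mantel r.

## Climate-covariate admixture

The model is a fully specified stand-in for covariate-aware Bayesian
clustering: z_ik = β_k·x_i + γ_k·s_i + ε_ik with ε ~ N(0, σ²), the
reference cluster fixed at z = 0, Q = softmax(z); gene copies are
allocated to clusters with probability ∝ Q_ik f_kla. The sampler is
Metropolis-within-Gibbs — exact multinomial allocation draws,
Dirichlet(1) conjugate frequency updates, per-individual random-walk
Metropolis on z (step adapted toward 0.25 acceptance during burn-in),
Gaussian conjugate updates for β and γ (prior variance 100), and
inverse-gamma(1, 1) conjugacy for σ². Covariates are standardized
internally and the scaling is stored on the fit, so projection under
future climates uses identical units. DIC = mean deviance + p_D with
p_D = mean deviance − deviance at posterior means; the deviance
marginalizes each copy's cluster (Σ_k Q_ik f_kla). Defaults: 2,000
sweeps / 200 burn-in for tests and synthetic runs (the chain mixes in
hundreds of sweeps at these sizes); 20,000 / 2,000 where a
full-length run is wanted; thinning 10.

Label switching is resolved by Hungarian assignment on column
correlations against a reference. Projection uses the regression
component only — with unchanged covariates it reproduces the fitted
regression ancestry exactly, which is the identity the tests pin down.
A cluster is "lost" when its maximum projected ancestry falls below
0.5 (configurable; no standard criterion exists). Covariate selection
ranks layers by among-population variance after standardizing each by
its full-grid SD and takes the top 3.

The reported ancestry-projection correlation is in-sample (the same
individuals' covariates shifted to the future scenario); a
cross-validated variant can be computed by fitting on a subset, but
both answer the same turnover question and the in-sample number is the
one reported by the pipeline.

## Genetic landscape

Midpoints are spherical (unit-vector mean); antipodal pairs are
rejected. IDW uses the k = 12 nearest samples with weights d^(−2), is
exact at coincident sample points, and is clipped to the convex hull
of the sample locations (no extrapolation). Cell size follows the
climate grid in synthetic runs; the 1-km cell of a real-extent
analysis is configurable. The GAM is a cubic B-spline basis (df = 10)
fitted with `statsmodels` GLMGam; the smoothing penalty is chosen by
GCV over a log-spaced grid because the library's built-in selector is
unreliable on near-perfect fits. R² is 1 − SSR/SST on the evaluation
cells (subsampled to 2,000, seeded); the p-value is an approximate
F-test of the smooth against a constant, on the effective degrees of
freedom.

## Pipeline and problem sizes

One global seed is split into per-stage seeds via
`numpy.random.SeedSequence(seed, spawn_key=(stage_index,))`, so any
stage can be rerun alone and reproduce the full run's output. The
bundled acceptance run uses a 40×48 grid, 19 layers, 24 populations ×
9 diploids, 250 occurrences, 10 ensemble repeats, K ∈ 1..5 at 2,000
sweeps, and 9,999 Mantel permutations — sizes chosen so the complete
analysis finishes in well under a minute on one CPU while keeping the
study's structure (full-length 20,000-sweep, K ≤ 20 settings remain
plain configuration).

## Known limitations

- The admixture model is a stand-in: it shares the covariate-dependent
  admixture design of published spatially explicit clustering software
  but not any particular tool's likelihood, spatial prior, or DIC
  scale. DIC can prefer K one above the simulated truth when two
  models fit near-equally; recovery checks therefore compare at the
  simulated K.
- Friction inversion is linear in suitability; no dispersal-kernel or
  circuit-theory (multi-path) alternatives.
- The GAM p-value is approximate (penalized fits have no exact null
  distribution); R² is the robust summary.
- Great-circle geometry assumes a spherical Earth (0.3% radius error
  at most latitudes); fine at landscape scales.
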
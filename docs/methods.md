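# Methods

This note documents the model, the numerical choices, and the study designs
behind the test suite and `scripts/acceptance.py`, in the order the pipeline
runs them.

## Data model and preprocessing

An expression dataset is a genes × samples real matrix with per-sample class
labels.  Values are min–max scaled per gene; when a train/test split is
present the scaling is fit on the training samples only and applied to all —
the split convention is not universal in the literature, so the choice (no
leakage from held-out samples) is explicit and flagged here for users
comparing against pipelines that scale before splitting.  An optional
univariate pre-filter retains the top-m genes by one-way ANOVA F computed on
the training partition; it is off by default and documented below where it
is used.

## Weighted neighborhood-preserving ensemble embedding (WNPEE)

For `X ∈ R^{D×N}` (features × samples) an ensemble of directed KNN graphs is
built over samples with neighborhood sizes `k_list` (default {5, 10, 15},
clipped to N−1; ties broken by smaller sample index, so duplicated samples
embed deterministically).  Each graph's reconstruction weights solve the
standard LLE local Gram system per row, with ridge `1e-3·tr(G)` — needed
because D ≫ N makes local Gram matrices singular.  Edges are used directed:
the row-wise sum-to-one constraint is only well posed per source node.

The fitted objective is

    J(A, α) = Σ_k α_k^r · tr(AᵀX (I−W_k)ᵀ(I−W_k) XᵀA),   Σ_k α_k = 1, α ≥ 0,

with the generalized orthogonality constraint `Aᵀ(XXᵀ+εI)A = I`,
`ε = 1e-6·tr(XXᵀ)/D`.  Minimizing over `A` is a generalized eigenproblem in
`M = Σ_k α_k^r (I−W_k)ᵀ(I−W_k)`; minimizing over `α` has the closed form
`α_k ∝ tr_k^{-1/(r−1)}`.  The exponent `r > 1` (default 2) controls how
sharply the ensemble concentrates on its best graph.  Because each half-step
is an exact minimizer, the recorded loss trace is non-increasing — this is
the reason the ensemble penalty uses the `α_k^r`-weighted sum of per-graph
penalties rather than a single combined-graph matrix: only under this
objective is the closed-form α-update actually the minimizer, which makes
the alternation a genuine block-coordinate descent.  With a single graph the
procedure is exactly NPE (verified against an independent direct
implementation).  Eigenvector signs are fixed by making each column's
largest-magnitude entry positive.  Reconstruction weights are computed once,
in the input space; only `α` and `A` iterate (the weights do not depend on
`α` given fixed graphs, so re-solving them would be a no-op).

Complexity is O(N²) in samples plus one D×D generalized eigensolve, fine for
microarray-scale D up to a few thousand.

## Fitness of a gene subset

A particle's position in `[0,1]^L` decodes to a mask (gene selected iff the
coordinate exceeds θ = 0.6, a common PSO feature-selection convention), with
three minimization objectives `(100−CA, NF, NP)`:

* **CA** — validation accuracy of an ELM: single hidden layer (H = 100),
  sigmoid activation, input weights and biases uniform on [−1,1] from a
  seed, one-hot ridge least-squares readout.  The readout ridge is 0.1: at
  H comparable to the training-set size an unregularized readout
  interpolates, and validation accuracy then collapses as soon as noise
  genes enter the mask (measured on the synthetic study: CA 100 → 30 when
  20 noise genes join the 5 markers at ridge 1e-6, versus 100 → 100 at
  ridge 0.1).  A ridge this size is the regularized-ELM norm and leaves the
  marker-versus-no-marker contrast intact.  Holdout validation is the
  default; `kfold:5` and `loocv` are available.
* **NF** — the subset size.
* **NP** — neighborhood preservation.  The stated formula compares the j-th
  nearest neighbor of each sample in a reference space with its j-th
  nearest neighbor in the selected-gene subspace; both neighbor points are
  compared *inside the subset space*, where the difference is well defined,
  and the value is zero exactly when the neighbor orderings agree.  The
  reference space defaults to the WNPEE embedding of the full normalized
  data (a `raw` full-gene option exists).  Inside the fitness the subset
  coordinates are divided by √NF before the comparison: Euclidean distances
  grow like √dim, and without this the NP objective is a monotone copy of
  the gene count instead of an independent structure signal.  The
  standalone `neighborhood_preservation` metric applies no scaling.
  k defaults to 10 neighbors.

An empty mask receives worst-case objectives (CA 0, large finite NF/NP
sentinels) instead of crashing.  Evaluations are memoized by mask; the ELM
seed is the run seed offset by a CRC of the mask, so the fitness is a pure
function of (mask, dataset, seeds).

## The optimizer

Defaults follow the published protocol: 200 particles, 50 iterations,
w = 0.7298, c1 = c2 = 1.49445, F = 0.5, CR = 0.5, β = 0.5, neighborhood
size 10.  Velocity is clamped to ±0.2 of the per-dimension range and
positions to the bounds (both standard PSO stabilizations).  The swarm
initializes on the unscrambled Sobol sequence (the printed recursion in the
source description is garbled; the standard Gray-code construction with
Joe–Kuo direction numbers, via `scipy.stats.qmc`, is evidently what is
intended), including the all-zeros point, affinely scaled to the bounds.

Per iteration and particle: a DE/rand/1 mutant from three distinct members
of the particle's 10-nearest-neighbor set (decision space), binomial
crossover at CR = 0.5 (the stated crossover rate; the update equations
themselves contain none), then `DE_v = K (trial − x)` with
`K = K_min + (K_max−K_min)(rank−1)/(max_rank−1)` mapping non-domination
rank to [0.2, 0.8] — worse-ranked particles get stronger perturbation.
Personal bests replace on dominance and flip a fair coin under mutual
non-domination.  Leaders are drawn uniformly from the archive's lowest-S
decile.

**Archive.**  After each sweep the swarm is merged into a bounded archive
(cap = population size) holding only mutually non-dominated entries.  When
over cap, the highest-S entries are dropped in one batch and scores are
recomputed for the survivors.  The score is

    S = β · (1 − HMD_norm) + (1 − β) · NP_norm,       lower preferred,

with HMD the harmonic mean of a member's Euclidean distances to the other
members in per-objective min–max normalized objective space (duplicates at
distance zero get HMD = 0), and the NP term the entry's neighborhood-
preservation distance in gene mode.  The HMD term is entered *inverted*: a
duplicated or crowded solution must score badly and an isolated front
region must be kept, which the raw composition cannot express — taken
literally ("lower S preferred" with S increasing in HMD) duplicates become
maximally preferred, and in early experiments the archive degenerated to
copies of a single solution.  The inverted form restores the score's stated
role as a diversity-plus-structure criterion.  Benchmark problems have no
genes, so the NP term uses a decision-space crowding surrogate,
`1/(1 + mean distance to the k=10 nearest archive members)` on normalized
coordinates: decision-space-sparse entries are preferred, which is what
lets the archive hold multiple equivalent Pareto sets on the multimodal
problems.  Whether HMD should live in objective or decision space is not
fixed anywhere authoritative; objective space (normalized) is used.

Ablation variants: `no_init` (pseudorandom init), `no_de` (DE term zero),
`no_select` (uniform-random truncation and leadership instead of S).

The returned gene subset is the archive entry with the highest CA, ties
toward fewer genes, then better NP.

## Benchmarks and metrics

MMF1–MMF8, SYM-PART (a=1, b=10, c=8; simple and π/4-rotated) and the
three-variable Omni-test are implemented from their standard suite
definitions, each with ≥ 500-point analytic Pareto set/front samples.  The
front sample is the evaluated image of the Pareto-set sample with
off-curve branch-boundary candidates removed and float-level weak
duplicates cleaned, so set and front are exactly aligned.  Metrics: exact
2-D sweep-line hypervolume (1/HV reported; reference point
`ideal + 1.1·(nadir−ideal)` of the true front, i.e. (1.1, 1.1) for the
unit-front MMFs, recorded in every output); error rate `1 − Acc`; a
decision-space proximity family reporting the obtained-averaged squared
distance (`igdx`), the reference-averaged distance (`igdx_ref`), the
suite-style `psp = cover_rate / igdx_ref` and `1/psp` — all three are
reported because the literature is inconsistent about which orientation
"PSP" denotes; ANO (mean k-NN overlap); and Spearman rank correlation with
average-rank ties (NaN with a warning for constant lists).

**Benchmark protocol** (`anpmopso.protocols.benchmark_inv_hv`): population
100·Nvar, 4,000·Nvar total evaluations (the initial sweep counts, so
`max_iter = 4000/100 − 1 = 39`), 15 independent seeded runs.

**Known caveat — Omni-test 1/HV.**  The published mean 1/HV for the
Omni-test (0.0161) corresponds to a hypervolume of ≈ 62 in raw objective
units; the true front is a radius-3 quarter circle, so that value requires
a reference point of ≈ 5 per objective — no "1.1-scaled" convention
produces it (ours, 0.3 per objective from ideal −3 and nadir 0, yields an
ideal-front 1/HV of ≈ 0.112).  The published MMF4 values similarly sit
below the theoretical 1/HV bound for a (1.1, 1.1) reference.  We keep the
single documented convention for all problems and report the Omni-test
number as computed; it is not comparable to the published figure.

**Ablation study** (`protocols.ablation_study`): MMF3 (the function the
original ablation experiment used), 15 runs per variant at the benchmark
protocol, compared on the reference-averaged IGDX (coverage of the true
Pareto set) — the quantity the convergence figures track via 1/PSP.  On
MMF5 the full-versus-`no_init`/`no_de` differences are inside run-to-run
noise; on MMF3 the ordering is clear and stable.

## Synthetic microarray generator

`generate_synthetic` emulates the structure of the classic benchmark panels
(Table-scale: 2,000–10,000 genes, 50–200 samples, 2–5 classes).  Defaults:
2,000 genes, 62 samples, 2 classes (a Colon-scale study), 20 informative
genes, a 40-gene redundant block at within-block Pearson correlation 0.8,
unit noise SD.  Informative genes are *class markers*: gene j is shifted by
`effect_size · noise_sd` in class `j mod C` and centered elsewhere.  Markers
make each informative gene carry complementary information — under a shared
class gradient a single strong gene saturates accuracy and "recover the
informative set" stops being a meaningful target for a parsimony-driven
optimizer.  Redundant genes are a marker plus Gaussian noise calibrated to
the requested correlation; remaining genes are pure noise.  Everything is
deterministic in the seed.

What the generator does **not** emulate: heavy-tailed and heteroscedastic
expression noise, probe-level artifacts, batch effects, correlated noise
across noise genes, unbalanced classes.  Passing recovery tests therefore
show that the optimizer finds complementary markers under idealized
Gaussian noise, not that it is robust to real microarray pathologies.

**Recovery study** (`protocols.recovery_study`, also acceptance): 200
genes, 5 markers, 5 classes, 150 samples, effect 5, no redundant block
("5 informative of 200" is read as 5 signal + 195 noise; redundant genes
would be interchangeable proxies and make exact-identity recovery
ill-defined).  Five classes make the markers genuinely complementary
(30 samples per class, a Lung-style multi-class design).  The pipeline
applies the ANOVA pre-filter at top-40 — the documented use-case of that
extension: with threshold decoding in the full 200-dimensional space the
initial masks hold ~80 genes and the swarm stalls in a regime where no
mask shows signal — then runs 100 particles for 40 iterations (a reduced
budget that keeps 20 paired seeds inside a few minutes; recovery at the
full 200×50 protocol is no better).  The selected subset is compared
against a random equal-size mask on held-out ELM accuracy, paired per seed.

## Seeding

One base seed fans out to component seeds via `SeedSequence(base,
crc32(component))`, all below 2³¹; every stochastic element (swarm,
ELM hidden layers, synthetic data, random-mask baselines) derives from it,
so any run is bit-reproducible from its manifest.

## Known limitations

* The exact hypervolume routine is 2-D only (all shipped benchmarks are
  bi-objective); three-objective gene-mode fronts are never scored by HV.
* WNPEE's D×D eigensolve is dense; beyond ~5,000 genes use the pre-filter
  first.
* The Omni-test 1/HV comparability caveat above.
* Gene-mode search quality depends on the pre-filter in very
  high-dimensional regimes; with it off, expect large selected subsets at
  microarray scale.
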
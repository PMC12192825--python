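# anpmopso

Adaptive neighborhood-preserving multi-objective particle swarm optimization
(ANPMOPSO) for microarray gene selection.

High-throughput expression studies measure thousands of genes on a few dozen
samples; classifying tumours (or any phenotype) from such matrices requires
finding a handful of genes that discriminate the classes without destroying
the local geometry of the sample cloud.  This package implements a wrapper
gene-selection framework that searches the space of gene subsets with a
multi-objective particle swarm, simultaneously optimizing

* **CA** — classification accuracy of an extreme learning machine (ELM) on a
  validation split (percent, Eq. `CA = correct/total × 100`),
* **NF** — the number of selected genes, `NF = Σ_j x_j` over the binary
  selection vector, and
* **NP** — a neighborhood-preservation distance between a reference
  embedding of the full data and the selected-gene subspace (lower = local
  structure better retained).

Four components distinguish the optimizer:

1. **WNPEE** — a weighted neighborhood-preserving ensemble embedding.  For
   data `X ∈ R^{D×N}` and an ensemble of KNN graphs with reconstruction
   weights `W_k` (rows summing to 1), the projection `A` solves the
   generalized eigenproblem `X M Xᵀ a = λ X Xᵀ a` with
   `M = Σ_k α_k^r (I−W_k)ᵀ(I−W_k)`, and the graph weights follow
   `α_k ∝ (1/tr_k)^{1/(r−1)}` — alternated until the loss converges.
2. **Sobol-sequence initialization** — the swarm starts on a scaled
   low-discrepancy point set, `X_i = X_min + s_i (X_max − X_min)`.
3. **DE-adaptive velocity** — each particle adds a differential-evolution
   term `DE_v = K (V_mut − x)`, `V_mut = x_r1 + F(x_r2 − x_r3)` drawn from
   its 10 nearest neighbors, with `K` scaled by non-domination rank.
4. **Archive selection score** — the bounded non-dominated archive is
   truncated and leaders are drawn using
   `S = β(1 − HMD_norm) + (1−β) NP_norm`, where HMD is the harmonic mean of
   a member's distances to the rest of the archive (lower S preferred).

The package also ships the multimodal multi-objective benchmark problems
used to validate the optimizer (MMF1–MMF8, SYM-PART simple/rotated,
Omni-test n=3) with analytic Pareto set/front references, the evaluation
metrics (exact 2-D hypervolume and 1/HV, error rate, IGDX/PSP family, ANO,
Spearman rank correlation), and a synthetic microarray generator with known
marker genes so the whole pipeline is testable without any data download.

## Worked example

Select genes on a synthetic five-class dataset (200 genes of which 5 are
subtype markers shifted by five noise standard deviations, 150 samples),
reduced to the 40 top-F genes before the swarm:

```python
from anpmopso import (SyntheticSpec, generate_synthetic, FitnessEvaluator,
                      ObjectivesConfig, SwarmConfig, select_genes)
from anpmopso.objectives import anova_prefilter

ds, truth = generate_synthetic(SyntheticSpec(
    n_genes=200, n_samples=150, n_classes=5, n_informative=5,
    n_redundant=0, effect_size=5.0, seed=2))
reduced, kept = anova_prefilter(ds, 40)
evaluator = FitnessEvaluator(reduced, ObjectivesConfig(base_seed=2))
selection, run = select_genes(evaluator, SwarmConfig(pop_size=100, max_iter=40, seed=2))
print(selection.selected_gene_ids)
print("CA=%.1f%% NF=%d NP=%.3f" % selection.objective_vector)
print("markers recovered:", sorted(set(selection.selected_gene_ids)
                                   & {ds.gene_ids[i] for i in truth}))
```

prints

```
['g00000', 'g00001', 'g00002', 'g00003', 'g00103', 'g00108', 'g00160']
CA=100.0% NF=7 NP=0.217
markers recovered: ['g00000', 'g00001', 'g00002', 'g00003']
```

Four of the five planted markers are selected alongside three passengers
(with five balanced classes, four one-vs-rest markers already identify
every class, so the Pareto pressure on subset size stops there), and
held-out accuracy is 100% with seven genes.  The same pipeline is available from the shell:

```sh
anpmopso select --data expr.csv --labels labels.txt --seed 2 --out out/
anpmopso benchmark --problem MMF1 --runs 15 --seed 0 --out bench/
anpmopso embed --input expr.csv --labels labels.txt --k-list 5,10,15 --out emb/
anpmopso ablate --problem MMF3 --variant no_de --runs 15 --out ablate/
anpmopso metrics --archive bench_archive.tsv --problem MMF1
```

Each run directory contains a `MANIFEST.json` (config hash, seed, versions,
wall time) from which the run is reproducible.

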
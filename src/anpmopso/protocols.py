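"""Reproduction protocols: the fixed study designs behind the headline runs.

These functions wire the library end-to-end under pinned conditions — the
benchmark 1/HV table protocol (15 independent runs, population 100·Nvar,
budget 4,000·Nvar evaluations), the synthetic marker-recovery study, and the
ablation comparison — so the test suite and the reproduction script execute
exactly the same code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benchmarks import make_problem
from .config import derive_seed
from .datasets import minmax_normalize
from .elm import classification_accuracy, train_elm
from .metrics import hypervolume, psp_family
from .objectives import FitnessEvaluator, ObjectivesConfig, anova_prefilter
from .optimizer import BenchmarkTask, SwarmConfig, benchmark_config, run_anpmopso, select_genes
from .synthetic import SyntheticSpec, generate_synthetic


@dataclass
class BenchmarkSummary:
    problem: str
    runs: int
    inv_hv: list[float]
    igdx: list[float]
    hv_reference_point: list[float]

    @property
    def inv_hv_mean(self) -> float:
        return float(np.mean(self.inv_hv))

    @property
    def inv_hv_std(self) -> float:
        return float(np.std(self.inv_hv, ddof=1)) if len(self.inv_hv) > 1 else 0.0


def benchmark_inv_hv(problem_name: str, runs: int = 15, base_seed: int = 0,
                     variant: str = "full") -> BenchmarkSummary:
    """Mean 1/HV protocol: independent seeded runs at the table settings."""
    prob = make_problem(problem_name)
    inv_hv, igdx_vals = [], []
    for run in range(runs):
        seed = derive_seed(base_seed, f"{problem_name}-{variant}-run-{run}")
        cfg = benchmark_config(prob, seed=seed, variant=variant)
        result = run_anpmopso(BenchmarkTask(prob), cfg)
        _, inv = hypervolume(result.archive.objectives, prob.hv_reference_point)
        inv_hv.append(inv)
        igdx_vals.append(psp_family(result.archive.positions, prob.reference_ps).igdx)
    return BenchmarkSummary(
        problem=prob.name, runs=runs, inv_hv=inv_hv, igdx=igdx_vals,
        hv_reference_point=prob.hv_reference_point.tolist(),
    )


#: Study conditions of the synthetic marker-recovery experiment: 200 genes of
#: which 5 are subtype markers (one per class, effect 5 noise-SD), 150
#: samples in 5 classes, no redundant block; univariate pre-filter to the 40
#: top-F genes ahead of the swarm (see docs/methods.md).
RECOVERY_SPEC = dict(n_genes=200, n_samples=150, n_classes=5, n_informative=5,
                     n_redundant=0, effect_size=5.0)
RECOVERY_PREFILTER_TOP_M = 40
RECOVERY_SWARM = dict(pop_size=100, max_iter=40)


@dataclass
class RecoveryOutcome:
    recovered: list[int]          # informative genes in the selected subset
    n_informative: int
    selected_sizes: list[int]
    ca_selected: list[float]      # held-out accuracy of the selected subset
    ca_random: list[float]        # held-out accuracy of a random equal-size mask

    @property
    def n_recovered_ge4(self) -> int:
        return sum(r >= 4 for r in self.recovered)

    @property
    def n_ca_wins(self) -> int:
        return sum(a > b for a, b in zip(self.ca_selected, self.ca_random))


def _holdout_ca(dataset, gene_idx: np.ndarray, seed: int) -> float:
    """Held-out ELM accuracy of an explicit gene-index subset."""
    values = minmax_normalize(dataset.values, dataset.split.train)
    X = values[gene_idx].T
    y = dataset.label_codes
    tr, te = dataset.split.train, dataset.split.test
    model = train_elm(X[tr], y[tr], n_hidden=100, seed=seed, ridge=1e-1)
    return classification_accuracy(model, X[te], y[te])


def recovery_study(n_seeds: int = 20, base_seed: int = 0) -> RecoveryOutcome:
    """Marker-recovery experiment over paired seeds.

    For each seed: generate the dataset, pre-filter, run the optimizer, and
    compare the selected subset's held-out accuracy against a random mask of
    equal size drawn from all genes.
    """
    recovered, sizes, ca_sel, ca_rand = [], [], [], []
    for i in range(n_seeds):
        seed = derive_seed(base_seed, f"recovery-{i}")
        ds, truth = generate_synthetic(SyntheticSpec(seed=seed, **RECOVERY_SPEC))
        reduced, keep = anova_prefilter(ds, RECOVERY_PREFILTER_TOP_M)
        evaluator = FitnessEvaluator(reduced, ObjectivesConfig(base_seed=seed))
        selection, _ = select_genes(
            evaluator, SwarmConfig(seed=seed, **RECOVERY_SWARM)
        )
        id_to_idx = {g: j for j, g in enumerate(ds.gene_ids)}
        sel_idx = np.array([id_to_idx[g] for g in selection.selected_gene_ids], int)
        recovered.append(int(np.isin(truth, sel_idx).sum()))
        sizes.append(sel_idx.size)
        ca_sel.append(_holdout_ca(ds, sel_idx, seed))
        rng = np.random.default_rng(derive_seed(seed, "random-mask"))
        rand_idx = rng.choice(ds.n_genes, size=max(sel_idx.size, 1), replace=False)
        ca_rand.append(_holdout_ca(ds, rand_idx, seed))
    return RecoveryOutcome(
        recovered=recovered, n_informative=int(RECOVERY_SPEC["n_informative"]),
        selected_sizes=sizes, ca_selected=ca_sel, ca_random=ca_rand,
    )


#: The ablation runs on MMF3 (the function the original ablation used) and
#: compares decision-space coverage of the true Pareto set.
ABLATION_PROBLEM = "MMF3"


def ablation_study(runs: int = 15, base_seed: int = 0) -> dict[str, dict[str, float]]:
    """Mean decision-space proximity per variant on the ablation problem."""
    prob = make_problem(ABLATION_PROBLEM)
    out: dict[str, dict[str, float]] = {}
    for variant in ("full", "no_init", "no_de", "no_select"):
        igdx_lit, igdx_ref, inv_psp = [], [], []
        for run in range(runs):
            seed = derive_seed(base_seed, f"ablate-{variant}-{run}")
            cfg = benchmark_config(prob, seed=seed, variant=variant)
            result = run_anpmopso(BenchmarkTask(prob), cfg)
            rep = psp_family(result.archive.positions, prob.reference_ps)
            igdx_lit.append(rep.igdx)
            igdx_ref.append(rep.igdx_ref)
            inv_psp.append(rep.inv_psp)
        out[variant] = {
            "igdx_mean": float(np.mean(igdx_lit)),
            "igdx_ref_mean": float(np.mean(igdx_ref)),
            "inv_psp_mean": float(np.mean(inv_psp)),
        }
    return out
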
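"""ANPMOPSO: the adaptive neighborhood-preserving multi-objective PSO loop.

The swarm lives in a continuous box.  Each iteration combines

* the canonical PSO velocity rule (inertia ``w``, cognitive ``c1``, social
  ``c2``) toward a personal best and an archive leader,
* a DE/rand/1 adaptive term: a mutant ``x_r1 + F (x_r2 − x_r3)`` built from
  the particle's 10 nearest swarm neighbors, binomial-crossed with the
  particle (CR), scaled by a rank-adaptive factor K (worse non-domination
  rank ⇒ stronger perturbation),
* a bounded external archive of mutually non-dominated solutions whose
  truncation and leadership both use the combined score
  ``S = β·(1 − HMD_norm) + (1 − β)·NP_norm`` — harmonic-mean distance to the
  other members in normalized objective space (inverted, so duplicates and
  crowded entries are penalized) plus a neighborhood-preservation term;
  lower S preferred, the highest-S entries are truncated first.

Gene-selection mode decodes a position in [0,1]^L to a mask (gene selected
iff coordinate > θ) and scores it with the three-objective fitness;
benchmark mode evaluates the analytic objectives directly and substitutes
decision-space crowding for the NP term, which is what lets the archive hold
multiple equivalent Pareto sets.

Ablation variants: ``no_init`` (pseudorandom instead of Sobol
initialization), ``no_de`` (DE term removed), ``no_select`` (S-based
truncation and leadership replaced by score-free random choices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datasets import SelectionResult
from .benchmarks import BenchmarkProblem
from .objectives import FitnessEvaluator
from .sobol import sobol_points, scale_population

logger = logging.getLogger(__name__)

VARIANTS = ("full", "no_init", "no_de", "no_select")


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pareto machinery

def dominates(u, v) -> bool:
    """True iff u <= v elementwise with at least one strict (minimization)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ParameterError("objective tuples must have equal length")
    return bool(np.all(u <= v) and np.any(u < v))


def nondominated_filter(points: np.ndarray) -> np.ndarray:
    """Indices of the non-dominated points, in stable input order."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[0] == 0:
        raise ParameterError("need at least one point")
    le = (P[:, None, :] <= P[None, :, :]).all(axis=2)
    lt = (P[:, None, :] < P[None, :, :]).any(axis=2)
    dominated = (le & lt).any(axis=0)
    return np.flatnonzero(~dominated)


def nondomination_ranks(points: np.ndarray) -> np.ndarray:
    """Front index (1 = non-dominated) per point, by iterative peeling."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    n = P.shape[0]
    le = (P[:, None, :] <= P[None, :, :]).all(axis=2)
    lt = (P[:, None, :] < P[None, :, :]).any(axis=2)
    dom = le & lt
    ranks = np.zeros(n, dtype=int)
    remaining = np.ones(n, dtype=bool)
    front = 0
    while remaining.any():
        front += 1
        active_dom = dom & remaining[:, None] & remaining[None, :]
        current = remaining & ~active_dom.any(axis=0)
        if not current.any():  # pragma: no cover - cycles impossible
            current = remaining
        ranks[current] = front
        remaining &= ~current
    return ranks


# ---------------------------------------------------------------------------
# DE building blocks

def de_mutant(x_r1: np.ndarray, x_r2: np.ndarray, x_r3: np.ndarray, F: float) -> np.ndarray:
    """DE/rand/1 mutant ``x_r1 + F (x_r2 − x_r3)`` (no clamping here)."""
    return np.asarray(x_r1, float) + F * (np.asarray(x_r2, float) - np.asarray(x_r3, float))


def adaptive_velocity_term(V_mut: np.ndarray, x_i: np.ndarray, K: float) -> np.ndarray:
    """Scaled displacement toward the mutant, ``K (V_mut − x_i)``."""
    return K * (np.asarray(V_mut, float) - np.asarray(x_i, float))


def adaptive_K(rank: int, max_rank: int, k_min: float, k_max: float) -> float:
    """Rank-mapped scaling factor: best front ⇒ k_min, worst ⇒ k_max."""
    if max_rank <= 1:
        return k_min
    return k_min + (k_max - k_min) * (rank - 1) / (max_rank - 1)


# ---------------------------------------------------------------------------
# Archive

def harmonic_mean_distance(index: int, dist_row: np.ndarray) -> float:
    """Harmonic mean of one entry's distances to the other archive members.

    Any zero distance (an objective-space duplicate) collapses the harmonic
    mean to 0.
    """
    d = np.delete(dist_row, index)
    if d.size == 0:
        return 0.0
    if np.any(d == 0):
        return 0.0
    return float(d.size / np.sum(1.0 / d))


def _minmax_norm(values: np.ndarray) -> np.ndarray:
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    out = np.zeros_like(values, dtype=float)
    ok = span > 0
    out[:, ok] = (values[:, ok] - lo[ok]) / span[ok]
    return out


def combined_score(hmd: np.ndarray, np_quality: np.ndarray, beta: float) -> np.ndarray:
    """Archive score combining diversity (HMD) and preservation (NP) terms.

    Lower S is preferred.  The HMD term enters *inverted* — a large harmonic
    mean distance to the other members marks an uncrowded, diversity-carrying
    solution, while an objective-space duplicate (HMD = 0) is maximally
    penalized; the NP term is lower-is-better as-is.  Both terms are min–max
    normalized within the archive; a degenerate term (all entries equal)
    contributes 0 for every member.
    """
    h = _minmax_norm(hmd[:, None])[:, 0]
    if np.ptp(hmd) > 0:
        h = 1.0 - h
    q = _minmax_norm(np_quality[:, None])[:, 0]
    return beta * h + (1.0 - beta) * q


@dataclass
class Archive:
    """Bounded store of mutually non-dominated solutions."""

    positions: np.ndarray   # (n, dim)
    objectives: np.ndarray  # (n, m)
    hmd: np.ndarray = field(default_factory=lambda: np.empty(0))
    np_quality: np.ndarray = field(default_factory=lambda: np.empty(0))
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return self.positions.shape[0]


def _archive_np_quality(positions: np.ndarray, lower: np.ndarray,
                        upper: np.ndarray, k: int) -> np.ndarray:
    """Decision-space crowding surrogate for the NP term (benchmark mode).

    Entries in sparse decision-space regions score lower (= preferred), so
    truncation keeps representatives of every equivalent Pareto subset.
    """
    n = positions.shape[0]
    if n <= 1:
        return np.zeros(n)
    scale = np.linalg.norm(upper - lower)
    D = squareform(pdist(positions / max(scale, 1e-300)))
    np.fill_diagonal(D, np.inf)
    kk = min(k, n - 1)
    nearest = np.partition(D, kk - 1, axis=1)[:, :kk]
    return 1.0 / (1.0 + nearest.mean(axis=1))


def _recompute_archive_scores(arch: Archive, beta: float,
                              np_quality: np.ndarray) -> Archive:
    n = len(arch)
    obj_norm = _minmax_norm(arch.objectives)
    D = squareform(pdist(obj_norm))
    hmd = np.array([harmonic_mean_distance(i, D[i]) for i in range(n)])
    arch.hmd = hmd
    arch.np_quality = np_quality
    arch.scores = combined_score(hmd, np_quality, beta)
    return arch


def update_archive(
    archive: Archive | None,
    cand_positions: np.ndarray,
    cand_objectives: np.ndarray,
    cap: int,
    beta: float,
    np_quality_fn,
    rng: np.random.Generator | None = None,
    score_free: bool = False,
) -> Archive:
    """Merge candidates, keep the non-dominated set, truncate to ``cap``.

    Truncation drops the highest-S entries in one batch, then recomputes
    HMD/NP/S for the survivors.  ``score_free`` (the no_select ablation)
    truncates uniformly at random instead.
    """
    if archive is None or len(archive) == 0:
        pos = np.atleast_2d(cand_positions)
        obj = np.atleast_2d(cand_objectives)
    else:
        pos = np.vstack([archive.positions, np.atleast_2d(cand_positions)])
        obj = np.vstack([archive.objectives, np.atleast_2d(cand_objectives)])
    keep = nondominated_filter(obj)
    pos, obj = pos[keep], obj[keep]
    arch = Archive(positions=pos, objectives=obj)
    arch = _recompute_archive_scores(arch, beta, np_quality_fn(pos))
    if len(arch) > cap:
        if score_free:
            if rng is None:
                raise ParameterError("score-free truncation needs an rng")
            keep_idx = np.sort(rng.choice(len(arch), size=cap, replace=False))
        else:
            keep_idx = np.sort(np.argsort(arch.scores, kind="stable")[:cap])
        arch = Archive(positions=arch.positions[keep_idx],
                       objectives=arch.objectives[keep_idx])
        arch = _recompute_archive_scores(arch, beta, np_quality_fn(arch.positions))
    return arch


# ---------------------------------------------------------------------------
# Tasks

class BenchmarkTask:
    """Adapter exposing a benchmark problem to the swarm."""

    is_gene_mode = False

    def __init__(self, problem: BenchmarkProblem, crowding_k: int = 10):
        self.problem = problem
        self.dim = problem.n_var
        self.lower = problem.lower
        self.upper = problem.upper
        self.crowding_k = crowding_k

    def evaluate(self, positions: np.ndarray) -> np.ndarray:
        return self.problem.evaluate(positions)

    def np_quality(self, positions: np.ndarray) -> np.ndarray:
        return _archive_np_quality(positions, self.lower, self.upper, self.crowding_k)


class GeneSelectionTask:
    """Adapter exposing the three-objective gene-subset fitness."""

    is_gene_mode = True

    def __init__(self, evaluator: FitnessEvaluator, theta: float = 0.6):
        self.evaluator = evaluator
        self.dim = evaluator.dataset.n_genes
        self.lower = np.zeros(self.dim)
        self.upper = np.ones(self.dim)
        if not (0.0 < theta < 1.0):
            raise ParameterError("selection threshold theta must be in (0, 1)")
        self.theta = theta

    def decode(self, position: np.ndarray) -> np.ndarray:
        return np.asarray(position) > self.theta

    def evaluate(self, positions: np.ndarray) -> np.ndarray:
        out = np.empty((positions.shape[0], 3))
        for i, p in enumerate(positions):
            out[i] = self.evaluator.evaluate(self.decode(p)).as_minimization()
        return out

    def np_quality(self, positions: np.ndarray) -> np.ndarray:
        # the third internal objective *is* the NP distance of each subset
        vals = np.empty(positions.shape[0])
        for i, p in enumerate(positions):
            vec = self.evaluator.evaluate(self.decode(p))
            vals[i] = vec.NP_dist if vec.valid else 1e12
        return vals


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class SwarmConfig:
    """Swarm hyperparameters (defaults follow the gene-selection protocol)."""

    pop_size: int = 200
    max_iter: int = 50
    w: float = 0.7298
    c1: float = 1.49445
    c2: float = 1.49445
    F: float = 0.5
    CR: float = 0.5
    K_min: float = 0.2
    K_max: float = 0.8
    beta: float = 0.5
    archive_cap: int | None = None     # default: pop_size
    theta: float = 0.6
    neighborhood_size: int = 10
    velocity_clamp: float = 0.2        # fraction of the per-dimension range
    seed: int = 0
    variant: str = "full"
    gbest_decile: float = 0.1

    def validate(self) -> None:
        if self.pop_size < 5:
            raise ParameterError("swarm.pop_size must be >= 5")
        if self.max_iter < 0:
            raise ParameterError("swarm.max_iter must be >= 0")
        if not (0.0 <= self.beta <= 1.0):
            raise ParameterError("swarm.beta must be in [0, 1]")
        if not (0.0 <= self.CR <= 1.0):
            raise ParameterError("swarm.CR must be in [0, 1]")
        if not (0.0 < self.theta < 1.0):
            raise ParameterError("swarm.theta must be in (0, 1)")
        if self.K_min > self.K_max:
            raise ParameterError("swarm.K_min must be <= swarm.K_max")
        if self.variant not in VARIANTS:
            raise ParameterError(
                f"swarm.variant must be one of {', '.join(VARIANTS)}"
            )

    @property
    def cap(self) -> int:
        return self.archive_cap if self.archive_cap is not None else self.pop_size


def benchmark_config(problem: BenchmarkProblem, seed: int = 0,
                     variant: str = "full", **overrides) -> SwarmConfig:
    """Benchmark protocol: population 100·Nvar, budget 4000·Nvar evaluations
    (initial sweep included)."""
    pop = 100 * problem.n_var
    budget = 4000 * problem.n_var
    iters = budget // pop - 1
    return SwarmConfig(pop_size=pop, max_iter=iters, seed=seed,
                       variant=variant, **overrides)


# ---------------------------------------------------------------------------
# Main loop

@dataclass
class IterationRecord:
    iteration: int
    archive_size: int
    best_error_rate: float | None
    best_objectives: np.ndarray


@dataclass
class RunResult:
    archive: Archive
    history: list[IterationRecord]
    config: SwarmConfig
    evaluations: int


def _sample_triplets(rng: np.random.Generator, neighbors: np.ndarray,
                     n: int) -> np.ndarray:
    """Distinct (r1, r2, r3) per particle, drawn from its neighborhood."""
    out = np.empty((n, 3), dtype=int)
    for i in range(n):
        pool = neighbors[i]
        pool = pool[pool != i]
        if pool.size < 3:  # fall back to the whole swarm
            pool = np.delete(np.arange(n), i)
        out[i] = rng.choice(pool, size=3, replace=False)
    return out


def _select_leaders(arch: Archive, rng: np.random.Generator, n: int,
                    decile: float, score_free: bool) -> np.ndarray:
    if score_free:
        idx = rng.integers(0, len(arch), size=n)
        return arch.positions[idx]
    order = np.argsort(arch.scores, kind="stable")
    n_top = max(1, int(np.ceil(decile * len(arch))))
    top = order[:n_top]
    idx = top[rng.integers(0, n_top, size=n)]
    return arch.positions[idx]


def run_anpmopso(task, config: SwarmConfig) -> RunResult:
    """Run the full optimizer on a gene-selection or benchmark task."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dim = task.dim
    lower, upper = task.lower, task.upper
    span = upper - lower
    vmax = config.velocity_clamp * span
    pop = config.pop_size
    score_free = config.variant == "no_select"

    if config.variant == "no_init":
        unit = rng.random((pop, dim))
    else:
        unit = sobol_points(pop, dim)
    positions = scale_population(unit, lower, upper)
    velocities = np.zeros_like(positions)

    objectives = task.evaluate(positions)
    evaluations = pop
    pbest_pos = positions.copy()
    pbest_obj = objectives.copy()

    archive = update_archive(
        None, positions, objectives, config.cap, config.beta,
        task.np_quality, rng=rng, score_free=score_free,
    )
    history: list[IterationRecord] = []
    _record(history, 0, archive, task)

    for it in range(1, config.max_iter + 1):
        ranks = nondomination_ranks(objectives)
        max_rank = int(ranks.max())
        K = np.array([
            adaptive_K(int(r), max_rank, config.K_min, config.K_max) for r in ranks
        ])

        if config.variant == "no_de":
            de_term = np.zeros_like(positions)
        else:
            D = squareform(pdist(positions))
            np.fill_diagonal(D, np.inf)
            nb_k = min(config.neighborhood_size, pop - 1)
            neighbors = np.argsort(D, axis=1, kind="stable")[:, :nb_k]
            trip = _sample_triplets(rng, neighbors, pop)
            mutants = de_mutant(
                positions[trip[:, 0]], positions[trip[:, 1]],
                positions[trip[:, 2]], config.F,
            )
            cross = rng.random((pop, dim)) < config.CR
            jrand = rng.integers(0, dim, size=pop)
            cross[np.arange(pop), jrand] = True
            trial = np.where(cross, mutants, positions)
            de_term = K[:, None] * (trial - positions)

        leaders = _select_leaders(archive, rng, pop, config.gbest_decile, score_free)
        r1 = rng.random((pop, dim))
        r2 = rng.random((pop, dim))
        velocities = (
            config.w * velocities
            + config.c1 * r1 * (pbest_pos - positions)
            + config.c2 * r2 * (leaders - positions)
            + de_term
        )
        np.clip(velocities, -vmax, vmax, out=velocities)
        positions = np.clip(positions + velocities, lower, upper)

        objectives = task.evaluate(positions)
        evaluations += pop

        # pbest: dominance replace; mutual non-domination -> coin flip
        new_dom = ((objectives <= pbest_obj).all(axis=1)
                   & (objectives < pbest_obj).any(axis=1))
        old_dom = ((pbest_obj <= objectives).all(axis=1)
                   & (pbest_obj < objectives).any(axis=1))
        tie = ~new_dom & ~old_dom
        coin = rng.random(pop) < 0.5
        take = new_dom | (tie & coin)
        pbest_pos[take] = positions[take]
        pbest_obj[take] = objectives[take]

        archive = update_archive(
            archive, positions, objectives, config.cap, config.beta,
            task.np_quality, rng=rng, score_free=score_free,
        )
        _record(history, it, archive, task)
        if it % 10 == 0 or it == config.max_iter:
            logger.info(
                "iter %d: archive=%d best=%s", it, len(archive),
                np.round(archive.objectives.min(axis=0), 4),
            )

    return RunResult(archive=archive, history=history, config=config,
                     evaluations=evaluations)


def _record(history: list[IterationRecord], it: int, archive: Archive, task) -> None:
    best_err = None
    if task.is_gene_mode:
        # first internal objective is 100 - CA
        best_err = float(archive.objectives[:, 0].min()) / 100.0
    history.append(IterationRecord(
        iteration=it,
        archive_size=len(archive),
        best_error_rate=best_err,
        best_objectives=archive.objectives.min(axis=0).copy(),
    ))


# ---------------------------------------------------------------------------
# Gene-selection entry point

def select_genes(
    evaluator: FitnessEvaluator,
    config: SwarmConfig | None = None,
) -> tuple[SelectionResult, RunResult]:
    """Run the optimizer on a dataset and extract the best gene subset.

    The returned subset is the archive entry with the highest classification
    accuracy; ties break toward fewer genes, then better neighborhood
    preservation.
    """
    config = config or SwarmConfig()
    task = GeneSelectionTask(evaluator, theta=config.theta)
    result = run_anpmopso(task, config)
    arch = result.archive
    order = np.lexsort(
        (arch.objectives[:, 2], arch.objectives[:, 1], arch.objectives[:, 0])
    )
    best = arch.positions[order[0]]
    mask = task.decode(best)
    vec = evaluator.evaluate(mask)
    ds = evaluator.dataset
    selection = SelectionResult(
        selected_gene_ids=[ds.gene_ids[i] for i in np.flatnonzero(mask)],
        objective_vector=(vec.CA, vec.NF, vec.NP_dist),
        run_metadata={
            "seed": config.seed,
            "iterations": config.max_iter,
            "variant": config.variant,
            "evaluations": result.evaluations,
        },
    )
    return selection, result


def best_mask(result: RunResult, task: GeneSelectionTask) -> np.ndarray:
    """Decoded mask of the accuracy-best archive entry."""
    arch = result.archive
    order = np.lexsort(
        (arch.objectives[:, 2], arch.objectives[:, 1], arch.objectives[:, 0])
    )
    return task.decode(arch.positions[order[0]])
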
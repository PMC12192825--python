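"""Three-objective fitness of a gene subset.

A candidate subset (binary mask over the L genes) is scored by

* **CA** — validation accuracy (percent) of an extreme learning machine
  trained on the masked training features;
* **NF** — the number of selected genes;
* **NP** — a neighborhood-preservation distance between a fixed reference
  space (by default the WNPEE embedding of the full normalized data) and the
  subspace spanned by the selected genes; lower means the subset retains the
  local sample geometry better.

Internally the optimizer minimizes ``(100 − CA, NF, NP)``; reported CA stays
on the 0–100 scale.  Evaluations are memoized per unique mask and fully
seeded, so the fitness is a pure function of (mask, dataset, seeds).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import ExpressionDataset, minmax_normalize
from .elm import classification_accuracy, train_elm
from .wnpee import default_k_list, fit_wnpee

logger = logging.getLogger(__name__)

#: Sentinel NP distance for invalid (empty) masks.
NP_SENTINEL = np.inf
#: Internal minimization objectives assigned to an empty mask (large finite
#: values keep dominance comparisons and archive normalization well-behaved).
INVALID_OBJECTIVES = (100.0, 1e12, 1e12)


class ParameterError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class ObjectiveVector:
    CA: float       # percent, [0, 100]
    NF: int         # selected gene count
    NP_dist: float  # >= 0, lower = better preservation
    valid: bool = True

    def as_minimization(self) -> tuple[float, float, float]:
        if not self.valid:
            return INVALID_OBJECTIVES
        return (100.0 - self.CA, float(self.NF), self.NP_dist)


def gene_count(mask: np.ndarray) -> int:
    """Popcount of a binary selection vector."""
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ContractError("mask must be binary")
    return int(np.count_nonzero(mask))


def _neighbor_lists(coords: np.ndarray, k: int) -> np.ndarray:
    """(N, k) nearest-neighbor indices, self excluded, ties by smaller index."""
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    return np.argsort(D, axis=1, kind="stable")[:, :k]


def neighborhood_preservation(
    reference_space: np.ndarray, subset_space: np.ndarray, k: int
) -> float:
    """Mean displacement between matched neighbors of the two spaces.

    For each sample i, its j-th nearest neighbor in the reference space is
    matched with its j-th nearest neighbor in the subset space, and the
    Euclidean distance between those two neighbor points is measured in
    subset-space coordinates (both neighbor lists live in the same space, so
    the difference is well defined).  The score is the average over
    j = 1..k and all N samples; it is 0 exactly when the neighbor orderings
    agree.
    """
    ref = np.asarray(reference_space, dtype=float)
    sub = np.asarray(subset_space, dtype=float)
    if ref.shape[0] != sub.shape[0]:
        raise ParameterError("spaces must contain the same samples")
    N = ref.shape[0]
    if not (0 < k < N):
        raise ParameterError(f"k={k} must be in (0, N={N})")
    nb_ref = _neighbor_lists(ref, k)
    nb_sub = _neighbor_lists(sub, k)
    diffs = sub[nb_ref] - sub[nb_sub]  # (N, k, q)
    return float(np.mean(np.linalg.norm(diffs, axis=-1)))


def anova_prefilter(
    dataset: ExpressionDataset, top_m: int
) -> tuple[ExpressionDataset, np.ndarray]:
    """Keep the ``top_m`` genes by one-way ANOVA F-score.

    A univariate relevance filter computed on the training partition only
    (no leakage from held-out samples); the wrapper search then runs in the
    reduced space.  Returns the reduced dataset and the original indices of
    the retained genes, in retained order.
    """
    from sklearn.feature_selection import f_classif

    if top_m < 1:
        raise ParameterError("top_m must be >= 1")
    if dataset.split is None:
        raise ParameterError("dataset must carry a train/test split")
    top_m = min(top_m, dataset.n_genes)
    tr = dataset.split.train
    F, _ = f_classif(dataset.values[:, tr].T, dataset.label_codes[tr])
    F = np.nan_to_num(F, nan=0.0)
    keep = np.sort(np.argsort(-F, kind="stable")[:top_m])
    reduced = ExpressionDataset(
        values=dataset.values[keep],
        gene_ids=[dataset.gene_ids[i] for i in keep],
        sample_ids=dataset.sample_ids,
        labels=dataset.labels,
        split=dataset.split,
    )
    return reduced, keep


@dataclass
class ObjectivesConfig:
    hidden_units: int = 100
    np_k: int = 10
    reference_space: str = "wnpee"  # or "raw": full-gene input space
    # readout ridge: with H comparable to the training-set size an
    # unregularized readout interpolates and collapses under noise features
    elm_ridge: float = 1e-1
    cv_mode: str = "holdout"        # holdout | kfold:5 | loocv
    embed_dim: int | None = None
    base_seed: int = 0


class FitnessEvaluator:
    """Memoized three-objective fitness for one dataset.

    The reference space, the per-gene normalization (computed on the training
    partition only) and the train/validation split are fixed at construction;
    each mask then costs one ELM fit plus one k-NN comparison.  The ELM seed
    is the run-level base seed offset by a CRC of the mask, so repeated
    evaluations of one mask agree bit-for-bit while different masks get
    independent hidden layers.
    """

    def __init__(self, dataset: ExpressionDataset, config: ObjectivesConfig | None = None):
        self.config = config or ObjectivesConfig()
        self.dataset = dataset
        if dataset.split is None:
            raise ParameterError("dataset must carry a train/test split")
        self.train_idx = dataset.split.train
        self.val_idx = dataset.split.test
        self.values = minmax_normalize(dataset.values, self.train_idx)
        self.y = dataset.label_codes
        k = min(self.config.np_k, dataset.n_samples - 1)
        if k != self.config.np_k:
            logger.warning("np_k clipped to %d for N=%d", k, dataset.n_samples)
        self.np_k = k
        self._cache: dict[bytes, ObjectiveVector] = {}
        self.reference_coords = self._reference_coords()

    def _reference_coords(self) -> np.ndarray:
        if self.config.reference_space == "raw":
            return self.values.T.copy()
        if self.config.reference_space != "wnpee":
            raise ParameterError(
                f"unknown reference_space {self.config.reference_space!r}"
            )
        N = self.dataset.n_samples
        d = self.config.embed_dim or max(1, min(20, N - 2, self.dataset.n_genes - 1))
        model = fit_wnpee(self.values, k_list=default_k_list(N), d=d)
        return model.embedded.T.copy()  # (N, d)

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, mask: np.ndarray) -> ObjectiveVector:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.dataset.n_genes,):
            raise ContractError("mask length must equal the gene count")
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        nf = gene_count(mask)
        if nf == 0:
            vec = ObjectiveVector(CA=0.0, NF=0, NP_dist=NP_SENTINEL, valid=False)
        else:
            vec = ObjectiveVector(
                CA=self._accuracy(mask, key), NF=nf, NP_dist=self._np_dist(mask)
            )
        self._cache[key] = vec
        return vec

    def _mask_seed(self, key: bytes) -> int:
        return (self.config.base_seed + zlib.crc32(key)) % (2**31)

    def _accuracy(self, mask: np.ndarray, key: bytes) -> float:
        X = self.values[mask].T  # (N, NF)
        seed = self._mask_seed(key)
        cfg = self.config
        mode = cfg.cv_mode
        if mode == "holdout":
            model = train_elm(
                X[self.train_idx], self.y[self.train_idx],
                n_hidden=cfg.hidden_units, seed=seed, ridge=cfg.elm_ridge,
            )
            return classification_accuracy(model, X[self.val_idx], self.y[self.val_idx])
        if mode.startswith("kfold:"):
            n_folds = int(mode.split(":", 1)[1])
        elif mode == "loocv":
            n_folds = X.shape[0]
        else:
            raise ParameterError(f"unknown cv_mode {mode!r}")
        rng = np.random.default_rng(seed)
        order = rng.permutation(X.shape[0])
        folds = np.array_split(order, n_folds)
        correct = 0
        for f, held in enumerate(folds):
            train = np.concatenate([fo for g, fo in enumerate(folds) if g != f])
            model = train_elm(
                X[train], self.y[train],
                n_hidden=cfg.hidden_units, seed=seed + f, ridge=cfg.elm_ridge,
            )
            correct += int(np.count_nonzero(model.predict(X[held]) == self.y[held]))
        return 100.0 * correct / X.shape[0]

    def _np_dist(self, mask: np.ndarray) -> float:
        # distances grow ~ sqrt(q) with subspace dimension q; normalizing the
        # coordinates keeps NP comparable across subset sizes instead of
        # acting as a second copy of the gene-count objective
        nf = int(np.count_nonzero(mask))
        subset_coords = self.values[mask].T / np.sqrt(nf)  # (N, NF)
        return neighborhood_preservation(
            self.reference_coords, subset_coords, self.np_k
        )
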
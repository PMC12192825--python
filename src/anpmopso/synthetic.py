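"""Synthetic microarray generator with known informative genes.

Emulates the structure of classic benchmark microarray panels (thousands of
genes, tens to a couple of hundred samples, 2–5 classes): a small set of
class-informative genes whose class-conditional means are separated by a
controlled effect size, a correlated redundant block tied to the informative
genes, and pure Gaussian noise genes.  Because the informative set is known,
every downstream stage (embedding, fitness, the full optimizer) is testable
without downloading any accession.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset, TrainTestSplit


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Defaults mirror a small two-class microarray study (Colon-like scale):
    2,000 genes, 62 samples, 20 informative genes shifted by 2 noise-SD
    between classes, a 40-gene redundant block correlated at 0.8.
    """

    n_genes: int = 2000
    n_samples: int = 62
    n_classes: int = 2
    n_informative: int = 20
    n_redundant: int = 40
    effect_size: float = 2.0
    within_block_correlation: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0
    train_fraction: float = 2 / 3

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if self.n_informative + self.n_redundant > self.n_genes:
            raise ParameterError("n_informative + n_redundant exceeds n_genes")
        if self.n_informative < 0 or self.n_redundant < 0:
            raise ParameterError("gene-block sizes must be non-negative")
        if not (0 <= self.within_block_correlation < 1):
            raise ParameterError("within_block_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.n_samples < 2 * self.n_classes:
            raise ParameterError("need >= 2 samples per class")
        if not (0 < self.train_fraction < 1):
            raise ParameterError("train_fraction must be in (0, 1)")


def generate_synthetic(spec: SyntheticSpec) -> tuple[ExpressionDataset, np.ndarray]:
    """Generate a dataset and the index set of its informative genes.

    Layout: genes ``[0, n_informative)`` are informative, the next
    ``n_redundant`` are redundant copies (informative parent plus calibrated
    Gaussian noise reaching the requested Pearson correlation), the rest are
    pure noise.  Informative genes act as subtype markers: gene ``j`` is
    shifted by ``effect_size * noise_sd`` in class ``j mod n_classes`` and
    centered at zero elsewhere, so the marked class is separated from the
    rest by ``effect_size`` noise-standard-deviations and no single gene
    carries the information of the others.  Deterministic for fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L, N = spec.n_genes, spec.n_samples

    labels = np.arange(N) % spec.n_classes
    rng.shuffle(labels)

    values = rng.normal(0.0, spec.noise_sd, size=(L, N))

    shift = spec.effect_size * spec.noise_sd
    for j in range(spec.n_informative):
        marked = labels == (j % spec.n_classes)
        values[j, marked] += shift

    informative = np.arange(spec.n_informative)
    if spec.n_redundant and spec.n_informative:
        rho = spec.within_block_correlation
        for j in range(spec.n_redundant):
            parent = informative[j % spec.n_informative]
            row = spec.n_informative + j
            if rho == 0.0:
                values[row] = rng.normal(0.0, spec.noise_sd, size=N)
                continue
            parent_sd = float(np.std(values[parent]))
            extra_sd = parent_sd * np.sqrt(1.0 / rho**2 - 1.0)
            values[row] = values[parent] + rng.normal(0.0, extra_sd, size=N)

    split = _stratified_split(labels, spec.train_fraction, rng)
    ds = ExpressionDataset(
        values=values,
        gene_ids=[f"g{i:05d}" for i in range(L)],
        sample_ids=[f"s{i:04d}" for i in range(N)],
        labels=labels,
        split=split,
    )
    return ds, informative


def _stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> TrainTestSplit:
    train: list[int] = []
    test: list[int] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = max(2, int(round(train_fraction * idx.size)))
        n_train = min(n_train, idx.size - 1)  # keep >=1 test sample per class
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return TrainTestSplit(train=np.sort(train), test=np.sort(test))
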
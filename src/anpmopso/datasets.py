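"""Expression-matrix containers and delimited-text I/O.

The unit of work is an :class:`ExpressionDataset`: a genes × samples matrix of
real-valued expression levels plus per-sample class labels.  Matrices are read
from CSV/TSV with genes in rows (header row = sample identifiers); labels come
from a single-column text file or a named column of a delimited file.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DataFormatError(ValueError):
    """Malformed input: dimension mismatch, duplicate IDs, bad delimiter."""


class DataValueError(ValueError):
    """Well-formed input with unusable values (e.g. NaN with imputation off)."""


@dataclass
class TrainTestSplit:
    train: np.ndarray  # sample indices
    test: np.ndarray

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        if np.intersect1d(self.train, self.test).size:
            raise DataFormatError("train and test partitions overlap")


@dataclass
class ExpressionDataset:
    """Gene × sample expression matrix with labels.

    ``values`` has shape (L, N) for L genes and N samples.  Labels keep their
    original values; ``label_codes`` encodes them 0..C−1 in sorted label order.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    split: TrainTestSplit | None = None

    classes_: np.ndarray = field(init=False, repr=False)
    label_codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise DataFormatError("expression values must be a 2-D matrix")
        L, N = self.values.shape
        if len(self.gene_ids) != L:
            raise DataFormatError(
                f"{len(self.gene_ids)} gene IDs for {L} matrix rows"
            )
        if len(self.sample_ids) != N:
            raise DataFormatError(
                f"{len(self.sample_ids)} sample IDs for {N} matrix columns"
            )
        if len(self.labels) != N:
            raise DataFormatError(f"{len(self.labels)} labels for {N} samples")
        if len(set(self.gene_ids)) != L:
            raise DataFormatError("duplicate gene IDs")
        if np.isnan(self.values).any():
            raise DataValueError("matrix contains NaN after loading")
        self.classes_, self.label_codes = np.unique(self.labels, return_inverse=True)
        if self.classes_.size < 2:
            raise DataFormatError("need at least 2 distinct classes")
        if self.split is not None:
            train_labels = self.label_codes[self.split.train]
            counts = np.bincount(train_labels, minlength=self.classes_.size)
            if (counts < 2).any():
                raise DataFormatError(
                    "every class needs >= 2 samples in the training partition"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.classes_.size)


def minmax_normalize(
    values: np.ndarray, train_idx: np.ndarray | None = None
) -> np.ndarray:
    """Per-gene min–max scaling to [0, 1].

    When ``train_idx`` is given, the minimum and maximum are computed on the
    training samples only and applied to all samples (no information from the
    held-out samples leaks into the scaling).  Constant genes map to 0.
    """
    values = np.asarray(values, dtype=float)
    ref = values if train_idx is None else values[:, np.asarray(train_idx, int)]
    lo = ref.min(axis=1, keepdims=True)
    hi = ref.max(axis=1, keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0
    return (values - lo) / span


def _read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_expression(
    path_matrix: str | Path,
    path_labels: str | Path | None = None,
    *,
    label_column: str | None = None,
    sep: str | None = None,
    genes_in_rows: bool = True,
    normalize: bool = False,
    impute: bool = False,
) -> ExpressionDataset:
    """Load a delimited expression matrix and its labels.

    Parameters
    ----------
    path_matrix:
        CSV/TSV with gene IDs in the first column and sample IDs in the header
        (set ``genes_in_rows=False`` for the transposed layout).
    path_labels:
        Single-column text file (one label per sample, optionally with a
        header) or a delimited file; required unless ``label_column`` names a
        row of the matrix file.
    normalize:
        Apply per-gene min–max scaling after loading.
    impute:
        Replace NaN entries by the gene mean instead of raising.
    """
    df = _read_table(path_matrix, sep)
    if not genes_in_rows:
        df = df.T

    if label_column is not None:
        if label_column not in df.index:
            raise DataFormatError(f"label row {label_column!r} not in matrix")
        labels = df.loc[label_column].to_numpy()
        df = df.drop(index=label_column)
    elif path_labels is not None:
        raw = pd.read_csv(path_labels, header=None).iloc[:, -1]
        # tolerate a header line in single-column label files
        if len(raw) == df.shape[1] + 1:
            raw = raw.iloc[1:]
        labels = raw.to_numpy()
    else:
        raise DataFormatError("labels required: pass path_labels or label_column")

    if len(labels) != df.shape[1]:
        raise DataFormatError(
            f"{len(labels)} labels for {df.shape[1]} samples"
        )

    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataFormatError(f"non-numeric expression values: {exc}") from exc

    if np.isnan(values).any():
        if not impute:
            raise DataValueError("matrix contains NaN (pass impute=True to mean-impute)")
        row_mean = np.nanmean(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), row_mean, values)

    if normalize:
        values = minmax_normalize(values)

    return ExpressionDataset(
        values=values,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        labels=np.asarray(labels),
    )


@dataclass
class SelectionResult:
    """A selected gene subset with its objective vector and provenance."""

    selected_gene_ids: list[str]
    objective_vector: tuple[float, int, float]  # (CA %, NF, NP quality)
    run_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ca, nf, np_dist = self.objective_vector
        if nf != len(self.selected_gene_ids):
            raise DataFormatError(
                "NF must equal the number of selected gene IDs"
            )
        self.objective_vector = (float(ca), int(nf), float(np_dist))


def save_selection(result: SelectionResult, path: str | Path) -> Path:
    """Write the selection as TSV (gene_id, rank) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not result.selected_gene_ids:
        warnings.warn("saving an empty gene selection", stacklevel=2)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\trank\n")
        for rank, gid in enumerate(result.selected_gene_ids, start=1):
            fh.write(f"{gid}\t{rank}\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    ca, nf, np_dist = result.objective_vector
    with open(sidecar, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(
            {
                "objective_vector": {"CA": ca, "NF": nf, "NP_dist": np_dist},
                "run_metadata": result.run_metadata,
            },
            fh,
            indent=2,
            allow_nan=False,
            default=str,
        )
        fh.write("\n")
    return path


def load_selection(path: str | Path) -> SelectionResult:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise DataFormatError("not a selection TSV (missing header)")
        gene_ids = [line.split("\t")[0] for line in fh if line.strip()]
    with open(path.with_suffix(path.suffix + ".json"), encoding="utf-8") as fh:
        meta = json.load(fh)
    obj = meta["objective_vector"]
    return SelectionResult(
        selected_gene_ids=gene_ids,
        objective_vector=(obj["CA"], obj["NF"], obj["NP_dist"]),
        run_metadata=meta.get("run_metadata", {}),
    )


def save_expression(ds: ExpressionDataset, path_matrix: str | Path,
                    path_labels: str | Path, sep: str = ",") -> None:
    """Round-trippable writer used by tests and the CLI."""
    df = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids)
    df.to_csv(path_matrix, sep=sep, lineterminator="\n")
    pd.Series(ds.labels).to_csv(path_labels, index=False, header=False)
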
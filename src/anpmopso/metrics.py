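"""Evaluation metrics: hypervolume, error rate, PSP family, ANO, SRC.

All fronts are minimization-oriented.  Hypervolume uses the exact 2-D
sweep-line algorithm (every benchmark here is bi-objective); 1/HV is the
smaller-is-better form reported alongside.  The decision-space proximity
family reports three numbers to avoid the orientation ambiguity around
"PSP": ``igdx`` (mean over the obtained set of squared distance to the
nearest true Pareto-set point), the suite-convention ``psp`` (cover rate
divided by the reference-averaged IGDX, larger = better) and its inverse
``inv_psp`` (smaller = better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata


class ContractError(ValueError):
    pass


class ParameterError(ValueError):
    pass


#: Reported for 1/HV when the usable front is empty (HV = 0).
INV_HV_SENTINEL = np.inf


def nondominated_mask(points: np.ndarray) -> np.ndarray:
    """Boolean mask of points not dominated by any other (minimization)."""
    P = np.asarray(points, dtype=float)
    n = P.shape[0]
    le = (P[:, None, :] <= P[None, :, :]).all(axis=2)
    lt = (P[:, None, :] < P[None, :, :]).any(axis=2)
    dominates = le & lt  # dominates[i, j]: i dominates j
    return ~dominates.any(axis=0)


def hypervolume(front: np.ndarray, ref_point: np.ndarray) -> tuple[float, float]:
    """Exact 2-D hypervolume and its inverse.

    Points that do not strictly dominate the reference point are dropped with
    a warning; an empty usable front yields ``(0, inf)``.
    """
    F = np.atleast_2d(np.asarray(front, dtype=float))
    r = np.asarray(ref_point, dtype=float)
    if F.shape[1] != 2 or r.shape != (2,):
        raise ParameterError("exact hypervolume implemented for 2 objectives only")
    usable = (F < r).all(axis=1)
    if not usable.all():
        warnings.warn(
            f"dropping {int((~usable).sum())} front points outside the "
            "reference box",
            stacklevel=2,
        )
    F = F[usable]
    if F.size == 0:
        return 0.0, INV_HV_SENTINEL
    F = F[nondominated_mask(F)]
    order = np.lexsort((F[:, 1], F[:, 0]))  # f1 ascending (f2 then descending)
    F = F[order]
    hv = 0.0
    prev_f2 = r[1]
    for f1, f2 in F:
        if f2 < prev_f2:
            hv += (r[0] - f1) * (prev_f2 - f2)
            prev_f2 = f2
    return float(hv), (1.0 / hv if hv > 0 else INV_HV_SENTINEL)


def error_rate(accuracy: float) -> float:
    """Complement of a fractional accuracy."""
    if not (0.0 <= accuracy <= 1.0):
        raise ContractError("accuracy must be a fraction in [0, 1]")
    return 1.0 - accuracy


def igdx(obtained_ps: np.ndarray, reference_ps: np.ndarray) -> float:
    """Mean over the obtained set of the squared decision-space distance to
    its nearest true Pareto-set point (0 iff obtained ⊆ reference)."""
    P = np.atleast_2d(np.asarray(obtained_ps, dtype=float))
    R = np.atleast_2d(np.asarray(reference_ps, dtype=float))
    if P.size == 0:
        raise ParameterError("empty obtained set")
    d = cdist(P, R)
    return float(np.mean(d.min(axis=1) ** 2))


def _cover_rate(obtained: np.ndarray, reference: np.ndarray) -> float:
    """Per-dimension overlap of the obtained and true Pareto-set boxes."""
    lo_o, hi_o = obtained.min(axis=0), obtained.max(axis=0)
    lo_r, hi_r = reference.min(axis=0), reference.max(axis=0)
    span = hi_r - lo_r
    ratios = np.ones_like(span)
    ok = span > 0
    overlap = np.minimum(hi_o, hi_r) - np.maximum(lo_o, lo_r)
    ratios[ok] = np.clip(overlap[ok] / span[ok], 0.0, 1.0) ** 2
    v = reference.shape[1]
    return float(np.prod(ratios) ** (1.0 / (2.0 * v)))


@dataclass
class PSPReport:
    igdx: float      # obtained-averaged squared-distance form
    igdx_ref: float  # reference-averaged distance (suite convention)
    cover_rate: float
    psp: float       # cover_rate / igdx_ref, larger = better
    inv_psp: float   # smaller = better


def psp_family(obtained_ps: np.ndarray, reference_ps: np.ndarray) -> PSPReport:
    """Decision-space proximity between an obtained set and the true PS."""
    P = np.atleast_2d(np.asarray(obtained_ps, dtype=float))
    R = np.atleast_2d(np.asarray(reference_ps, dtype=float))
    if P.size == 0:
        raise ParameterError("empty obtained set")
    d = cdist(R, P)
    igdx_ref = float(np.mean(d.min(axis=1)))
    cr = _cover_rate(P, R)
    psp = cr / igdx_ref if igdx_ref > 0 else np.inf
    return PSPReport(
        igdx=igdx(P, R),
        igdx_ref=igdx_ref,
        cover_rate=cr,
        psp=psp,
        inv_psp=(1.0 / psp if psp > 0 and np.isfinite(psp) else 0.0),
    )


def _knn_sets(coords: np.ndarray, k: int) -> np.ndarray:
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    return np.argsort(D, axis=1, kind="stable")[:, :k]


def average_neighborhood_overlap(
    high_space: np.ndarray, low_space: np.ndarray, k: int
) -> float:
    """Mean fraction of shared k-nearest neighbors between two spaces."""
    H = np.atleast_2d(np.asarray(high_space, dtype=float))
    L = np.atleast_2d(np.asarray(low_space, dtype=float))
    if H.shape[0] != L.shape[0]:
        raise ParameterError("spaces must contain the same samples")
    N = H.shape[0]
    if not (0 < k < N):
        raise ParameterError(f"k={k} must be in (0, N={N})")
    nb_h = _knn_sets(H, k)
    nb_l = _knn_sets(L, k)
    overlaps = [
        np.intersect1d(nb_h[i], nb_l[i], assume_unique=True).size for i in range(N)
    ]
    return float(np.mean(overlaps)) / k


def spearman_rank_correlation(
    dist_high: np.ndarray, dist_low: np.ndarray
) -> float:
    """Spearman rank correlation of two paired distance lists.

    Average ranks break ties; a constant list leaves the correlation
    undefined and returns NaN with a warning.
    """
    a = np.asarray(dist_high, dtype=float).ravel()
    b = np.asarray(dist_low, dtype=float).ravel()
    if a.shape != b.shape:
        raise ParameterError("paired distance lists must have equal length")
    n = a.size
    if n < 2:
        raise ParameterError("need at least two pairs")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant distance list: rank correlation undefined", stacklevel=2)
        return float("nan")
    d = rankdata(a, method="average") - rankdata(b, method="average")
    return float(1.0 - 6.0 * np.sum(d**2) / (n * (n**2 - 1.0)))


def np_score(np_dist: float) -> float:
    """Bounded larger-is-better transform of the NP distance, 1/(1+NP)."""
    return 1.0 / (1.0 + np_dist)
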
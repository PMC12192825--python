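"""Sobol quasi-random initialization.

Low-discrepancy points in the unit hypercube, affinely scaled to the decision
bounds of the swarm.  The generator is the standard Gray-code Sobol
construction with Joe–Kuo direction numbers (via ``scipy.stats.qmc``); the
first, all-zeros point is included by default so the unscrambled 1-D prefix is
the base-2 van der Corput sequence (0, 1/2, 3/4, 1/4, ...).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import qmc


class ParameterError(ValueError):
    pass


#: Largest dimension supported by the direction-number table we rely on.
MAX_DIMS = 21201


def sobol_points(
    n: int,
    dims: int,
    scramble: bool = False,
    seed: int | None = None,
    skip_zero: bool = False,
) -> np.ndarray:
    """First ``n`` Sobol points in [0, 1)^dims.

    ``scramble`` applies Owen scrambling (seeded) for run-to-run diversity in
    repeated experiments; the default is the deterministic unscrambled
    sequence.  ``skip_zero`` drops the leading all-zeros point.
    """
    if n < 1:
        raise ParameterError("n_points must be >= 1")
    if dims < 1:
        raise ParameterError("dims must be >= 1")
    if dims > MAX_DIMS:
        raise ParameterError(f"dims={dims} beyond direction-number table ({MAX_DIMS})")
    sampler = qmc.Sobol(d=dims, scramble=scramble, seed=seed)
    total = n + 1 if skip_zero else n
    with warnings.catch_warnings():
        # balance warnings for non-power-of-two sample counts are expected here
        warnings.simplefilter("ignore", UserWarning)
        pts = sampler.random(total)
    if skip_zero:
        pts = pts[1:]
    return pts


def scale_population(
    points: np.ndarray, x_min: np.ndarray | float, x_max: np.ndarray | float
) -> np.ndarray:
    """Affine map of unit-cube points onto [x_min, x_max] per dimension."""
    points = np.asarray(points, dtype=float)
    x_min = np.broadcast_to(np.asarray(x_min, dtype=float), points.shape[-1:])
    x_max = np.broadcast_to(np.asarray(x_max, dtype=float), points.shape[-1:])
    if np.any(x_min >= x_max):
        raise ParameterError("x_min must be elementwise < x_max")
    if points.min(initial=0.0) < 0.0 or points.max(initial=0.0) > 1.0:
        raise ParameterError("points must lie in [0, 1]")
    return x_min + points * (x_max - x_min)


def unscale_population(
    positions: np.ndarray, x_min: np.ndarray | float, x_max: np.ndarray | float
) -> np.ndarray:
    """Inverse of :func:`scale_population`."""
    positions = np.asarray(positions, dtype=float)
    x_min = np.asarray(x_min, dtype=float)
    x_max = np.asarray(x_max, dtype=float)
    return (positions - x_min) / (x_max - x_min)
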
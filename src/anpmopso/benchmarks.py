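"""Multimodal multi-objective benchmark problems.

Bi-objective test functions whose defining property is *decision-space
multimodality*: several disjoint Pareto-optimal sets map onto the same Pareto
front, so an optimizer must preserve decision-space diversity to cover them
all.  The suite comprises MMF1–MMF8, the SYM-PART problems (simple and
rotated) and the Omni-test with three variables; definitions follow the
standard multimodal multi-objective benchmark suite used with ring-topology
MOPSO (MMFs, SYM-PART) and the Omni-test of Deb & Tiwari.

Each problem carries dense analytic samples of its true Pareto set (decision
space) and Pareto front (objective space), generated at construction, plus a
hypervolume reference point ``ideal + 1.1 · (nadir − ideal)`` per objective
computed from the true front — which is exactly (1.1, 1.1) for the MMFs,
whose fronts are normalized to [0, 1]².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


class ParameterError(ValueError):
    pass


@dataclass
class BenchmarkProblem:
    name: str
    n_var: int
    lower: np.ndarray
    upper: np.ndarray
    _evaluate: Callable[[np.ndarray], np.ndarray]
    reference_ps: np.ndarray       # (n, n_var) true Pareto-set sample
    reference_pf: np.ndarray       # (n, 2) true Pareto-front sample
    hv_reference_point: np.ndarray  # (2,)

    @property
    def n_obj(self) -> int:
        return 2

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Objective values (minimization) for decision rows of ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_var:
            raise ParameterError(
                f"{self.name} expects {self.n_var} variables, got {X.shape[1]}"
            )
        return self._evaluate(X)


def _hv_reference(pf: np.ndarray) -> np.ndarray:
    ideal = pf.min(axis=0)
    nadir = pf.max(axis=0)
    return ideal + 1.1 * (nadir - ideal)


# ---------------------------------------------------------------------------
# MMF family (all 2 variables)

def _mmf1(X: np.ndarray) -> np.ndarray:
    t = np.abs(X[:, 0] - 2.0)
    f1 = t
    f2 = 1.0 - np.sqrt(t) + 2.0 * (X[:, 1] - np.sin(6 * np.pi * t + np.pi)) ** 2
    return np.column_stack([f1, f2])


def _mmf2(X: np.ndarray) -> np.ndarray:
    x1, x2 = X[:, 0], X[:, 1]
    y = np.where(x2 <= 1.0, x2 - np.sqrt(x1), x2 - 1.0 - np.sqrt(x1))
    f1 = x1
    f2 = 1.0 - np.sqrt(x1) + 2.0 * (
        4.0 * y**2 - 2.0 * np.cos(20.0 * y * np.pi / np.sqrt(2.0)) + 2.0
    )
    return np.column_stack([f1, f2])


def _mmf3(X: np.ndarray) -> np.ndarray:
    x1, x2 = X[:, 0], X[:, 1]
    y = np.where(x2 <= 0.5, x2 - np.sqrt(x1), x2 - 0.5 - np.sqrt(x1))
    f1 = x1
    f2 = 1.0 - np.sqrt(x1) + 2.0 * (
        4.0 * y**2 - 2.0 * np.cos(20.0 * y * np.pi / np.sqrt(2.0)) + 2.0
    )
    return np.column_stack([f1, f2])


def _mmf4(X: np.ndarray) -> np.ndarray:
    x1, x2 = X[:, 0], X[:, 1]
    t = np.abs(x1)
    y = np.where(x2 <= 1.0, x2 - np.sin(np.pi * t), x2 - 1.0 - np.sin(np.pi * t))
    return np.column_stack([t, 1.0 - t**2 + 2.0 * y**2])


def _mmf5(X: np.ndarray) -> np.ndarray:
    x1, x2 = X[:, 0], X[:, 1]
    t = np.abs(x1 - 2.0)
    s = np.sin(6 * np.pi * t + np.pi)
    y = np.where(x2 <= 1.0, x2 - s, x2 - 2.0 - s)
    return np.column_stack([t, 1.0 - np.sqrt(t) + 2.0 * y**2])


def _mmf6(X: np.ndarray) -> np.ndarray:
    x1, x2 = X[:, 0], X[:, 1]
    t = np.abs(x1 - 2.0)
    s = np.sin(6 * np.pi * t + np.pi)
    y = np.where(x2 <= 1.0, x2 - s, x2 - 1.0 - s)
    return np.column_stack([t, 1.0 - np.sqrt(t) + 2.0 * y**2])


def _mmf7_center(t: np.ndarray) -> np.ndarray:
    return (0.3 * t**2 * np.cos(24 * np.pi * t + 4 * np.pi) + 0.6 * t) * np.sin(
        6 * np.pi * t + np.pi
    )


def _mmf7(X: np.ndarray) -> np.ndarray:
    t = np.abs(X[:, 0] - 2.0)
    y = X[:, 1] - _mmf7_center(t)
    return np.column_stack([t, 1.0 - np.sqrt(t) + y**2])


def _mmf8(X: np.ndarray) -> np.ndarray:
    x1, x2 = X[:, 0], X[:, 1]
    t = np.abs(x1)
    s = np.sin(t)
    y = np.where(x2 <= 4.0, x2 - s - t, x2 - 4.0 - s - t)
    f1 = s
    f2 = np.sqrt(np.clip(1.0 - f1**2, 0.0, None)) + 2.0 * y**2
    return np.column_stack([f1, f2])


def _mmf_ps_pf(name: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Pareto set/front samples for the MMF family."""
    n |= 1  # odd grids hit both front extremes exactly
    if name == "MMF1":
        x1 = np.linspace(1.0, 3.0, n)
        t = np.abs(x1 - 2.0)
        ps = np.column_stack([x1, np.sin(6 * np.pi * t + np.pi)])
        tt = np.linspace(0.0, 1.0, n)
        pf = np.column_stack([tt, 1.0 - np.sqrt(tt)])
    elif name in {"MMF2", "MMF3"}:
        half = (n // 2) | 1
        x1 = np.linspace(0.0, 1.0, half)
        off = 1.0 if name == "MMF2" else 0.5
        b1 = np.column_stack([x1, np.sqrt(x1)])
        b2 = np.column_stack([x1, off + np.sqrt(x1)])
        if name == "MMF3":  # lower branch only valid while x2 <= 0.5
            b1 = b1[b1[:, 1] <= 0.5]
        ps = np.vstack([b1, b2])
        tt = np.linspace(0.0, 1.0, n)
        pf = np.column_stack([tt, 1.0 - np.sqrt(tt)])
    elif name == "MMF4":
        half = (n // 2) | 1
        x1 = np.linspace(-1.0, 1.0, half)
        s = np.sin(np.pi * np.abs(x1))
        ps = np.vstack(
            [np.column_stack([x1, s]), np.column_stack([x1, 1.0 + s])]
        )
        tt = np.linspace(0.0, 1.0, n)
        pf = np.column_stack([tt, 1.0 - tt**2])
    elif name in {"MMF5", "MMF6"}:
        half = (n // 2) | 1
        x1 = np.linspace(1.0, 3.0, half)
        s = np.sin(6 * np.pi * np.abs(x1 - 2.0) + np.pi)
        off = 2.0 if name == "MMF5" else 1.0
        ps = np.vstack(
            [np.column_stack([x1, s]), np.column_stack([x1, off + s])]
        )
        tt = np.linspace(0.0, 1.0, n)
        pf = np.column_stack([tt, 1.0 - np.sqrt(tt)])
    elif name == "MMF7":
        x1 = np.linspace(1.0, 3.0, n)
        t = np.abs(x1 - 2.0)
        ps = np.column_stack([x1, _mmf7_center(t)])
        tt = np.linspace(0.0, 1.0, n)
        pf = np.column_stack([tt, 1.0 - np.sqrt(tt)])
    elif name == "MMF8":
        half = 4 * ((n // 2) // 4) + 1  # grid contains 0 and ±π/2
        x1 = np.linspace(-np.pi, np.pi, half)
        t = np.abs(x1)
        s = np.sin(t)
        ps = np.vstack(
            [np.column_stack([x1, s + t]), np.column_stack([x1, 4.0 + s + t])]
        )
        tt = np.linspace(0.0, 1.0, n)
        pf = np.column_stack([tt, np.sqrt(1.0 - tt**2)])
    else:  # pragma: no cover
        raise ParameterError(name)
    return ps, pf


_MMF_BOUNDS = {
    "MMF1": ([1.0, -1.0], [3.0, 1.0]),
    "MMF2": ([0.0, 0.0], [1.0, 2.0]),
    "MMF3": ([0.0, 0.0], [1.0, 1.5]),
    "MMF4": ([-1.0, 0.0], [1.0, 2.0]),
    "MMF5": ([1.0, -1.0], [3.0, 3.0]),
    "MMF6": ([1.0, -1.0], [3.0, 2.0]),
    "MMF7": ([1.0, -1.0], [3.0, 1.0]),
    "MMF8": ([-np.pi, 0.0], [np.pi, 9.0]),
}

_MMF_FUNCS = {
    "MMF1": _mmf1, "MMF2": _mmf2, "MMF3": _mmf3, "MMF4": _mmf4,
    "MMF5": _mmf5, "MMF6": _mmf6, "MMF7": _mmf7, "MMF8": _mmf8,
}


# ---------------------------------------------------------------------------
# SYM-PART (a = 1, b = 10, c = 8; 9 equivalent Pareto subsets on a 3×3 grid)

_SYM_A, _SYM_B, _SYM_C = 1.0, 10.0, 8.0
_ROT = np.pi / 4.0


def _sympart_tiles(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b, c = _SYM_A, _SYM_B, _SYM_C
    t1 = np.clip(
        np.sign(x1) * np.ceil((np.abs(x1) - (a + c / 2.0)) / (2.0 * a + c)), -1, 1
    )
    t2 = np.clip(np.sign(x2) * np.ceil((np.abs(x2) - b / 2.0) / b), -1, 1)
    return t1, t2


def _sympart_simple(X: np.ndarray) -> np.ndarray:
    a, b, c = _SYM_A, _SYM_B, _SYM_C
    x1, x2 = X[:, 0], X[:, 1]
    t1, t2 = _sympart_tiles(x1, x2)
    u = x1 - t1 * (c + 2.0 * a)
    v = x2 - t2 * b
    f1 = (u + a) ** 2 + v**2
    f2 = (u - a) ** 2 + v**2
    return np.column_stack([f1, f2])


def _rotate(X: np.ndarray, angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    R = np.array([[ca, -sa], [sa, ca]])
    return X @ R.T


def _sympart_rotated(X: np.ndarray) -> np.ndarray:
    return _sympart_simple(_rotate(X, _ROT))


def _sympart_ps_pf(rotated: bool, n: int) -> tuple[np.ndarray, np.ndarray]:
    a, b, c = _SYM_A, _SYM_B, _SYM_C
    per_tile = max(10, n // 9)
    u = np.linspace(-a, a, per_tile)
    segs = []
    for t1 in (-1, 0, 1):
        for t2 in (-1, 0, 1):
            segs.append(np.column_stack([u + t1 * (c + 2 * a), np.full_like(u, t2 * b)]))
    ps = np.vstack(segs)
    if rotated:
        ps = _rotate(ps, -_ROT)  # evaluation rotates forward
    s = np.linspace(-a, a, n)
    pf = np.column_stack([(s + a) ** 2, (s - a) ** 2])
    return ps, pf


# ---------------------------------------------------------------------------
# Omni-test, n = 3 (Deb & Tiwari): 27 equivalent Pareto subsets

def _omni(X: np.ndarray) -> np.ndarray:
    f1 = np.sin(np.pi * X).sum(axis=1)
    f2 = np.cos(np.pi * X).sum(axis=1)
    return np.column_stack([f1, f2])


def _omni_ps_pf(n_var: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(1.0, 1.5, max(20, n // 27))
    offsets = np.array(
        np.meshgrid(*([np.arange(3) * 2.0] * n_var), indexing="ij")
    ).reshape(n_var, -1).T  # 27 combinations of {0, 2, 4}
    ps = (t[:, None, None] + offsets[None, :, :]).reshape(-1, n_var)
    tt = np.linspace(1.0, 1.5, n)
    pf = np.column_stack(
        [n_var * np.sin(np.pi * tt), n_var * np.cos(np.pi * tt)]
    )
    return ps, pf


# ---------------------------------------------------------------------------

_ALIASES = {
    "SYM-PART SIMPLE": "SYMPART_SIMPLE",
    "SYM-PART ROTATED": "SYMPART_ROTATED",
    "SYMPART-SIMPLE": "SYMPART_SIMPLE",
    "SYMPART-ROTATED": "SYMPART_ROTATED",
    "OMNI-TEST": "OMNI3",
    "OMNI_TEST": "OMNI3",
    "OMNI": "OMNI3",
}

PROBLEM_NAMES = (
    "MMF1", "MMF2", "MMF3", "MMF4", "MMF5", "MMF6", "MMF7", "MMF8",
    "SYMPART_SIMPLE", "SYMPART_ROTATED", "OMNI3",
)


#: Analytic front curve f2 = phi(f1) of each problem's true Pareto front.
_FRONT_CURVES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "MMF1": lambda f1: 1.0 - np.sqrt(f1),
    "MMF2": lambda f1: 1.0 - np.sqrt(f1),
    "MMF3": lambda f1: 1.0 - np.sqrt(f1),
    "MMF4": lambda f1: 1.0 - f1**2,
    "MMF5": lambda f1: 1.0 - np.sqrt(f1),
    "MMF6": lambda f1: 1.0 - np.sqrt(f1),
    "MMF7": lambda f1: 1.0 - np.sqrt(f1),
    "MMF8": lambda f1: np.sqrt(np.clip(1.0 - f1**2, 0.0, None)),
    "SYMPART_SIMPLE": lambda f1: (2.0 - np.sqrt(f1)) ** 2,
    "SYMPART_ROTATED": lambda f1: (2.0 - np.sqrt(f1)) ** 2,
    "OMNI3": lambda f1: -3.0 * np.sqrt(np.clip(1.0 - (f1 / 3.0) ** 2, 0.0, None)),
}


def make_problem(name: str, n_reference: int = 1000) -> BenchmarkProblem:
    """Construct a named benchmark with analytic reference PS/PF samples.

    The Pareto-set sample is generated from the closed-form branch
    descriptions; candidates landing off the analytic front curve (branch
    boundaries under the piecewise objective definition) are dropped, and
    the front sample is the evaluated image of the retained set, so every
    reference PS point maps exactly onto a reference PF point.
    """
    key = _ALIASES.get(name.strip().upper(), name.strip().upper())
    if key not in PROBLEM_NAMES:
        raise ParameterError(
            f"unknown problem {name!r}; choose from {', '.join(PROBLEM_NAMES)}"
        )
    n_reference = max(n_reference, 500)
    if key in _MMF_FUNCS:
        lower, upper = _MMF_BOUNDS[key]
        ps, _ = _mmf_ps_pf(key, n_reference)
        func = _MMF_FUNCS[key]
        n_var = 2
    elif key in {"SYMPART_SIMPLE", "SYMPART_ROTATED"}:
        rotated = key == "SYMPART_ROTATED"
        lower, upper = [-20.0, -20.0], [20.0, 20.0]
        ps, _ = _sympart_ps_pf(rotated, n_reference)
        func = _sympart_rotated if rotated else _sympart_simple
        n_var = 2
    else:  # OMNI3
        n_var = 3
        lower, upper = [0.0] * n_var, [6.0] * n_var
        ps, _ = _omni_ps_pf(n_var, n_reference)
        func = _omni
    F = func(ps)
    on_front = np.abs(F[:, 1] - _FRONT_CURVES[key](F[:, 0])) <= 1e-7
    ps, pf = ps[on_front], F[on_front]
    # snap the image onto the analytic curve: equal-f1 branch points become
    # exactly identical, so the sample is mutually non-dominated by
    # monotonicity of the curve
    pf = pf.copy()
    pf[:, 1] = _FRONT_CURVES[key](pf[:, 0])
    # in near-flat curve regions float noise in f1 creates weak dominance
    # between branch images; keep the exactly non-dominated subset
    le = (pf[:, None, :] <= pf[None, :, :]).all(axis=2)
    lt = (pf[:, None, :] < pf[None, :, :]).any(axis=2)
    clean = ~(le & lt).any(axis=0)
    ps, pf = ps[clean], pf[clean]
    order = np.argsort(pf[:, 0], kind="stable")
    return BenchmarkProblem(
        name=key,
        n_var=n_var,
        lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float),
        _evaluate=func,
        reference_ps=ps[order],
        reference_pf=pf[order],
        hv_reference_point=_hv_reference(pf),
    )
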
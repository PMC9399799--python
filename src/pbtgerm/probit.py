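"""Repeated probit regression engine.

The threshold models (thermal, hydro, hydrothermal time) all reduce to the
same estimation scheme: for a candidate value of the *searched* parameters
(base temperature, time constants, …) build a scalar predictor for every
(condition, percentile) point, regress probit(g) on that predictor by
ordinary least squares, and keep the candidate that maximises R² on the
probit scale. The population median and spread of the threshold then fall
out of the regression line: spread = 1/slope, location = −intercept/slope
(in predictor units).

The search is a coarse grid over the declared bounds followed by geometric
refinement around the incumbent (grid shrinks by ``refine_factor`` each
stage) until the grid step is below each parameter's tolerance. It is
derivative-free, deterministic, and reproducible; ties are broken toward the
lexicographically smallest parameter vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, SearchFailure

__all__ = [
    "probit",
    "fit_probit_line",
    "ProbitDataset",
    "SearchParam",
    "SearchSpec",
    "ProbitFitResult",
    "repeated_probit_search",
]


def probit(g):
    """Inverse standard-normal CDF of g ∈ (0, 1) (modern convention, no +5)."""
    arr = np.asarray(g, dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError(f"probit requires 0 < g < 1, got {g}")
    out = stats.norm.ppf(arr)
    return float(out) if np.isscalar(g) or arr.ndim == 0 else out


def fit_probit_line(x, y) -> tuple[float, float, float]:
    """OLS line y ≈ intercept + slope·x with R² on the probit scale.

    Raises :class:`DegenerateFitError` for <3 points or zero predictor
    variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise DegenerateFitError(f"need ≥3 aligned points, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DegenerateFitError("non-finite predictor values")
    if np.ptp(x) == 0 or np.var(x) < 1e-24 * (1.0 + np.mean(x) ** 2):
        raise DegenerateFitError("zero predictor variance")
    res = stats.linregress(x, y)
    return float(res.intercept), float(res.slope), float(res.rvalue**2)


@dataclass(frozen=True)
class ProbitDataset:
    """(condition, percentile) points with their probit-transformed fractions.

    ``inputs`` holds aligned condition arrays (e.g. ``T``, ``psi``, ``t``)
    that predictor builders consume; ``g`` holds the germination fractions,
    all strictly in (0, 1).
    """

    g: np.ndarray
    inputs: Mapping[str, np.ndarray]

    def __post_init__(self):
        g = np.asarray(self.g, float)
        object.__setattr__(self, "g", g)
        if np.any((g <= 0) | (g >= 1)):
            raise ValueError("all g must lie strictly in (0, 1)")
        inputs = {k: np.asarray(v, float) for k, v in self.inputs.items()}
        for k, v in inputs.items():
            if v.shape != g.shape:
                raise ValueError(f"input {k!r} not aligned with g")
        object.__setattr__(self, "inputs", inputs)

    @property
    def n_points(self) -> int:
        return int(self.g.size)

    @property
    def probit_g(self) -> np.ndarray:
        return stats.norm.ppf(self.g)


@dataclass(frozen=True)
class SearchParam:
    """One searched parameter: bounds, coarse resolution, scale, tolerance.

    ``log=True`` searches on the log10 scale; its ``tol`` is then a *relative*
    tolerance (stop when the grid step corresponds to a relative change below
    ``tol``).
    """

    name: str
    lower: float
    upper: float
    n_coarse: int = 21
    log: bool = False
    tol: float = 1e-3

    def __post_init__(self):
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError(f"{self.name}: bounds must be finite")
        if self.lower >= self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.log and self.lower <= 0:
            raise ValueError(f"{self.name}: log scale requires positive bounds")
        if self.tol <= 0 or self.n_coarse < 2:
            raise ValueError(f"{self.name}: tol > 0 and n_coarse ≥ 2 required")

    # search-space (possibly log10) representation
    @property
    def s_lower(self) -> float:
        return math.log10(self.lower) if self.log else self.lower

    @property
    def s_upper(self) -> float:
        return math.log10(self.upper) if self.log else self.upper

    @property
    def s_tol(self) -> float:
        return math.log10(1.0 + self.tol) if self.log else self.tol

    def to_value(self, s: float) -> float:
        return 10.0**s if self.log else s


@dataclass(frozen=True)
class SearchSpec:
    """Full search specification for a repeated-probit fit."""

    params: tuple[SearchParam, ...]
    refine_factor: int = 5
    max_stages: int = 400

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(self.params))
        if not self.params:
            raise ValueError("at least one searched parameter required")
        if self.refine_factor < 2:
            raise ValueError("refine_factor must be ≥ 2")


@dataclass(frozen=True)
class ProbitFitResult:
    """Outcome of a repeated-probit search."""

    params: dict[str, float]
    intercept: float
    slope: float
    r2: float
    n_points: int
    trace: tuple[dict, ...] = field(repr=False)
    at_bounds: dict[str, bool]
    final_steps: dict[str, float]

    @property
    def location(self) -> float:
        """Median threshold in predictor units: −intercept/slope."""
        return -self.intercept / self.slope

    @property
    def scale(self) -> float:
        """Population spread in predictor units: 1/slope."""
        return 1.0 / self.slope


def _batch_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS of y on each row of X: (intercept, slope, R²) per row.

    Rows with non-finite predictors, ~zero variance, or non-positive slope
    get R² = −inf (rejected candidates).
    """
    n = y.size
    ym = y.mean()
    syy = float(np.sum((y - ym) ** 2))
    valid = np.all(np.isfinite(X), axis=1)
    Xs = np.where(valid[:, None], X, 0.0)
    xm = Xs.mean(axis=1)
    dx = Xs - xm[:, None]
    sxx = np.einsum("ij,ij->i", dx, dx)
    sxy = dx @ (y - ym)
    scale = 1.0 + xm**2
    ok = valid & (sxx > 1e-20 * n * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(ok, sxy / sxx, np.nan)
        r2 = np.where(ok, (sxy**2) / (sxx * syy), -np.inf)
    ok &= slope > 0
    r2 = np.where(ok, r2, -np.inf)
    intercept = ym - slope * xm
    return intercept, slope, r2


def _best_candidate(cands: np.ndarray, r2: np.ndarray) -> int | None:
    """Index of max-R² candidate; exact ties go to the lexicographically
    smallest parameter vector."""
    best = np.max(r2)
    if not np.isfinite(best):
        return None
    tied = np.flatnonzero(r2 == best)
    if tied.size == 1:
        return int(tied[0])
    sub = cands[tied]
    order = np.lexsort(tuple(sub[:, k] for k in reversed(range(sub.shape[1]))))
    return int(tied[order[0]])


def repeated_probit_search(
    dataset: ProbitDataset,
    predictor_builder: Callable[..., np.ndarray],
    spec: SearchSpec,
) -> ProbitFitResult:
    """Grid-and-refine search for the parameters maximising probit-scale R².

    ``predictor_builder(inputs, **params)`` must accept each searched
    parameter as a column vector of candidates (shape ``(n_cand, 1)``) and
    return the predictor matrix of shape ``(n_cand, n_points)`` — plain
    broadcasting expressions like ``(inputs["T"] - Tb) * inputs["t"]`` do
    this naturally.

    Raises :class:`SearchFailure` when every candidate is degenerate.
    """
    if dataset.n_points < 3:
        raise DegenerateFitError(
            f"need ≥3 probit points (intercept + slope + 1 df), got {dataset.n_points}"
        )
    y = dataset.probit_g
    names = [p.name for p in spec.params]

    def evaluate(grids: Sequence[np.ndarray]):
        mesh = np.meshgrid(*grids, indexing="ij")
        cands = np.stack([m.ravel() for m in mesh], axis=1)  # search-space
        values = np.column_stack(
            [10.0 ** cands[:, j] if p.log else cands[:, j]
             for j, p in enumerate(spec.params)]
        )
        X = predictor_builder(
            dataset.inputs, **{nm: values[:, j][:, None] for j, nm in enumerate(names)}
        )
        X = np.broadcast_to(np.asarray(X, float), (cands.shape[0], dataset.n_points))
        intercept, slope, r2 = _batch_ols(X, y)
        idx = _best_candidate(cands, r2)
        return cands, r2, intercept, slope, idx

    # --- coarse stage
    grids = [np.linspace(p.s_lower, p.s_upper, p.n_coarse) for p in spec.params]
    steps = np.array([(p.s_upper - p.s_lower) / (p.n_coarse - 1) for p in spec.params])
    cands, r2, intercept, slope, idx = evaluate(grids)
    trace: list[dict] = []
    if idx is None:
        raise SearchFailure(
            "all coarse-grid candidates degenerate (no positive-slope probit fit); "
            f"bounds={[(p.name, p.lower, p.upper) for p in spec.params]}"
        )
    inc = cands[idx].copy()
    inc_stats = (float(intercept[idx]), float(slope[idx]), float(r2[idx]))
    trace.append(
        {
            "stage": 0,
            "steps": steps.copy(),
            "params": {nm: spec.params[j].to_value(inc[j]) for j, nm in enumerate(names)},
            "r2": inc_stats[2],
        }
    )

    # --- refinement stages
    # Window of ±step around the incumbent, 2·factor+1 points, so the grid
    # spacing shrinks by `refine_factor` per stage. When the incumbent lands
    # on a window edge (a ridge in parameter space, common for correlated
    # (Tb, θHT) pairs) the window is re-centred without shrinking, letting
    # the search walk along the ridge instead of collapsing beside it.
    tols = np.array([p.s_tol for p in spec.params])
    stage = 0
    while np.any(steps > tols) and stage < spec.max_stages:
        stage += 1
        new_grids = []
        windows = []
        for j, p in enumerate(spec.params):
            if steps[j] <= tols[j]:
                new_grids.append(np.array([inc[j]]))
                windows.append(None)
                continue
            lo = max(p.s_lower, inc[j] - steps[j])
            hi = min(p.s_upper, inc[j] + steps[j])
            npts = 2 * spec.refine_factor + 1
            new_grids.append(np.linspace(lo, hi, npts))
            windows.append((lo, hi))
        cands, r2, intercept, slope, idx = evaluate(new_grids)
        moved_to_edge = [False] * len(spec.params)
        if idx is not None and r2[idx] >= inc_stats[2]:
            inc = cands[idx].copy()
            inc_stats = (float(intercept[idx]), float(slope[idx]), float(r2[idx]))
            for j, (p, win) in enumerate(zip(spec.params, windows)):
                if win is None:
                    continue
                lo, hi = win
                tiny = 1e-12 * (1.0 + abs(inc[j]))
                on_edge = inc[j] <= lo + tiny or inc[j] >= hi - tiny
                at_global = inc[j] <= p.s_lower + tiny or inc[j] >= p.s_upper - tiny
                moved_to_edge[j] = on_edge and not at_global
        for j, win in enumerate(windows):
            if win is None or moved_to_edge[j]:
                continue  # frozen or re-centred without shrinking
            lo, hi = win
            steps[j] = (hi - lo) / (2 * spec.refine_factor)
        trace.append(
            {
                "stage": stage,
                "steps": steps.copy(),
                "params": {nm: spec.params[j].to_value(inc[j]) for j, nm in enumerate(names)},
                "r2": inc_stats[2],
            }
        )

    values = {nm: spec.params[j].to_value(inc[j]) for j, nm in enumerate(names)}
    at_bounds = {
        p.name: bool(
            inc[j] - p.s_lower <= max(steps[j], p.s_tol)
            or p.s_upper - inc[j] <= max(steps[j], p.s_tol)
        )
        for j, p in enumerate(spec.params)
    }
    final_steps = {
        p.name: (10.0 ** steps[j] - 1.0) * values[p.name] if p.log else float(steps[j])
        for j, p in enumerate(spec.params)
    }
    return ProbitFitResult(
        params=values,
        intercept=inc_stats[0],
        slope=inc_stats[1],
        r2=inc_stats[2],
        n_points=dataset.n_points,
        trace=tuple(trace),
        at_bounds=at_bounds,
        final_steps=final_steps,
    )
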
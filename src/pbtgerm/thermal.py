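"""Thermal-time (TT) germination model: sub- and supra-optimal branches.

Sub-optimal (Tb < T ≤ To): each seed fraction g needs a fixed thermal time
θT(g) = (T − Tb)·t(g) of degree-hours above the base temperature Tb, with θT
normally distributed across the population (median θT(50), SD σθT):

    probit(g) = [(T − Tb)·t(g) − θT(50)] / σθT

Supra-optimal (To ≤ T < Tc): the ceiling temperature Tc(g) = T + θT2/t(g) is
distributed across seeds (median Tc(50), SD σTc) with a common thermal
constant θT2:

    probit(g) = [Tc(50) − T − θT2/t(g)] / σTc

Fits run the repeated-probit engine: Tb is searched in the sub-optimal
branch, θT2 (log-spaced) in the supra-optimal branch; the remaining location
and spread fall out of the regression line. The optimum temperature To is
where the two GR(50)-versus-T lines intersect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import FitError, UndefinedPercentileError
from .probit import ProbitDataset, SearchParam, SearchSpec, repeated_probit_search
from .records import GerminationIndices, PercentileCurve

__all__ = [
    "SubThermalParams",
    "SupraThermalParams",
    "CardinalTemperatures",
    "fit_suboptimal_tt",
    "fit_supraoptimal_tt",
    "cardinal_temperatures",
    "observed_optimum_temperature",
    "predict_tt_time_course",
    "tt_quantile_times",
    "tt_percentile_curve",
]


@dataclass(frozen=True)
class SubThermalParams:
    """Sub-optimal thermal-time parameters (θT in °C·h)."""

    theta_T50: float
    Tb: float
    sigma_thetaT: float
    r2: float | None = None
    temperature_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.theta_T50 <= 0 or self.sigma_thetaT <= 0:
            raise FitError(
                f"invalid sub-optimal TT parameters: theta_T50={self.theta_T50}, "
                f"sigma={self.sigma_thetaT}"
            )
        if self.temperature_range is not None and self.Tb >= self.temperature_range[0]:
            raise FitError(
                f"Tb={self.Tb} must lie below the fitted range {self.temperature_range}"
            )


@dataclass(frozen=True)
class SupraThermalParams:
    """Supra-optimal thermal-time parameters (θT2 in °C·h, Tc spread in °C)."""

    theta_T2: float
    Tc50: float
    sigma_Tc: float
    r2: float | None = None
    temperature_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.theta_T2 <= 0 or self.sigma_Tc <= 0:
            raise FitError(
                f"invalid supra-optimal TT parameters: theta_T2={self.theta_T2}, "
                f"sigma_Tc={self.sigma_Tc}"
            )
        if self.temperature_range is not None and self.Tc50 <= self.temperature_range[1]:
            raise FitError(
                f"Tc50={self.Tc50} must lie above the fitted range {self.temperature_range}"
            )


@dataclass(frozen=True)
class CardinalTemperatures:
    Tb: float
    To: float
    Tc: float

    def __post_init__(self):
        if not (self.Tb < self.To < self.Tc):
            raise FitError(
                f"cardinal temperatures must satisfy Tb < To < Tc, got "
                f"({self.Tb}, {self.To}, {self.Tc})"
            )


def _dataset(curves: Iterable[PercentileCurve]) -> ProbitDataset:
    curves = list(curves)
    if not curves:
        raise FitError("no percentile curves supplied")
    T, t, g = [], [], []
    for c in curves:
        T.extend([c.temperature] * len(c.percentiles))
        t.extend(c.times_g)
        g.extend(c.percentiles)
    return ProbitDataset(g=np.asarray(g), inputs={"T": np.asarray(T), "t": np.asarray(t)})


def fit_suboptimal_tt(
    curves: Sequence[PercentileCurve],
    tb_bounds: tuple[float, float] | None = None,
    tol: float = 1e-3,
) -> SubThermalParams:
    """Fit (θT(50), Tb, σθT) to percentile curves at Ψ=0, T in the sub-optimal
    range, by searching Tb and probit-regressing g on (T − Tb)·t(g)."""
    curves = list(curves)
    temps = sorted({c.temperature for c in curves})
    if len(temps) < 2:
        raise FitError(
            f"Tb is unidentifiable from a single temperature ({temps}); "
            "supply curves at ≥2 temperatures"
        )
    ds = _dataset(curves)
    if tb_bounds is None:
        tb_bounds = (0.0, temps[0] - 0.5)
    if tb_bounds[0] >= tb_bounds[1]:
        raise FitError(f"empty Tb search interval {tb_bounds}")
    spec = SearchSpec(
        params=(SearchParam("Tb", tb_bounds[0], tb_bounds[1], n_coarse=41, tol=tol),)
    )
    res = repeated_probit_search(ds, lambda inp, Tb: (inp["T"] - Tb) * inp["t"], spec)
    sigma = res.scale
    theta50 = res.location
    return SubThermalParams(
        theta_T50=theta50,
        Tb=res.params["Tb"],
        sigma_thetaT=sigma,
        r2=res.r2,
        temperature_range=(temps[0], temps[-1]),
    )


def fit_supraoptimal_tt(
    curves: Sequence[PercentileCurve],
    theta_bounds: tuple[float, float] = (0.1, 1e4),
    tol: float = 1e-5,
) -> SupraThermalParams:
    """Fit (θT2, Tc(50), σTc) at supra-optimal temperatures by searching θT2
    (log-spaced) and probit-regressing g on the ceiling Tc(g) = T + θT2/t(g)."""
    curves = list(curves)
    temps = sorted({c.temperature for c in curves})
    if len(temps) < 2:
        raise FitError(
            f"θT2 is unidentifiable from a single temperature ({temps}); "
            "supply curves at ≥2 temperatures"
        )
    ds = _dataset(curves)
    spec = SearchSpec(
        params=(
            SearchParam(
                "theta_T2", theta_bounds[0], theta_bounds[1], n_coarse=41, log=True, tol=tol
            ),
        )
    )
    # probit(g) = (Tc50 − Tc(g))/σTc: regress on −Tc(g) so the slope is positive
    res = repeated_probit_search(
        ds, lambda inp, theta_T2: -(inp["T"] + theta_T2 / inp["t"]), spec
    )
    sigma = res.scale
    tc50 = res.intercept / res.slope
    return SupraThermalParams(
        theta_T2=res.params["theta_T2"],
        Tc50=tc50,
        sigma_Tc=sigma,
        r2=res.r2,
        temperature_range=(temps[0], temps[-1]),
    )


def cardinal_temperatures(
    sub: SubThermalParams, supra: SupraThermalParams
) -> CardinalTemperatures:
    """Tb from the sub-optimal fit, Tc from the supra-optimal fit, and To at
    the intersection of the two GR(50)-versus-T lines:

        GR50 = (T − Tb)/θT(50)  rising,  GR50 = (Tc50 − T)/θT2  falling,

    hence To = (Tc50·θT(50) + Tb·θT2) / (θT(50) + θT2)."""
    to = (supra.Tc50 * sub.theta_T50 + sub.Tb * supra.theta_T2) / (
        sub.theta_T50 + supra.theta_T2
    )
    if not (sub.Tb < to < supra.Tc50):
        raise FitError(
            f"GR50 lines intersect at {to:.2f} °C, outside (Tb, Tc) = "
            f"({sub.Tb:.2f}, {supra.Tc50:.2f})"
        )
    return CardinalTemperatures(Tb=sub.Tb, To=to, Tc=supra.Tc50)


def observed_optimum_temperature(
    indices_by_temperature: Mapping[float, GerminationIndices],
) -> float:
    """Empirical To: the tested temperature with the highest final
    germination, ties broken by higher GR50 then by lower temperature."""
    if not indices_by_temperature:
        raise FitError("no indices supplied")

    def key(item):
        temp, idx = item
        gr = idx.germination_rate_50 if idx.germination_rate_50 is not None else -np.inf
        return (-idx.final_germination_pct, -gr, temp)

    return min(indices_by_temperature.items(), key=key)[0]


def predict_tt_time_course(
    params: SubThermalParams | SupraThermalParams, T: float, times
) -> np.ndarray:
    """Cumulative germination fraction g(t) at temperature T.

    Sub-optimal: g(t) = Φ([(T − Tb)·t − θT(50)]/σθT); at T ≤ Tb no thermal
    time accumulates and the prediction is identically zero (flagged with a
    warning, not an exception). Supra-optimal:
    g(t) = Φ([Tc(50) − T − θT2/t]/σTc).
    """
    t = np.asarray(times, float)
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    if isinstance(params, SubThermalParams):
        if T <= params.Tb:
            warnings.warn(
                f"T={T} °C at or below Tb={params.Tb} °C: predicting zero germination",
                stacklevel=2,
            )
            return np.zeros_like(t)
        z = ((T - params.Tb) * t - params.theta_T50) / params.sigma_thetaT
    elif isinstance(params, SupraThermalParams):
        z = (params.Tc50 - T - params.theta_T2 / t) / params.sigma_Tc
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    return stats.norm.cdf(z)


def tt_asymptote(params: SubThermalParams | SupraThermalParams, T: float) -> float:
    """Limit of g(t) as t → ∞ at temperature T."""
    if isinstance(params, SubThermalParams):
        return 1.0 if T > params.Tb else 0.0
    return float(stats.norm.cdf((params.Tc50 - T) / params.sigma_Tc))


def tt_quantile_times(
    params: SubThermalParams | SupraThermalParams, T: float, percentiles
) -> np.ndarray:
    """Exact model inverse t(g): the time at which the predicted time course
    reaches each fraction g. Raises if a fraction is never reached at T."""
    g = np.asarray(percentiles, float)
    z = stats.norm.ppf(g)
    if isinstance(params, SubThermalParams):
        if T <= params.Tb:
            raise UndefinedPercentileError(f"no germination at T={T} ≤ Tb={params.Tb}")
        num = params.theta_T50 + params.sigma_thetaT * z
        if np.any(num <= 0):
            raise UndefinedPercentileError(
                "requested percentile implies non-positive thermal time"
            )
        return num / (T - params.Tb)
    denom = params.Tc50 - T - params.sigma_Tc * z
    if np.any(denom <= 0):
        raise UndefinedPercentileError(
            f"percentile(s) unreachable at T={T}: ceiling exceeded"
        )
    return params.theta_T2 / denom


def tt_percentile_curve(
    params: SubThermalParams | SupraThermalParams, T: float, percentiles
) -> PercentileCurve:
    """Noise-free percentile curve implied by the model at temperature T."""
    g = tuple(float(v) for v in np.asarray(percentiles, float))
    t = tt_quantile_times(params, T, g)
    return PercentileCurve(
        condition=(float(T), 0.0),
        percentiles=g,
        times_g=tuple(float(v) for v in t),
        final_fraction=tt_asymptote(params, T),
    )
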
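"""Hydrotime (HT) germination model at a single temperature.

Each seed fraction g has a base water potential Ψb(g), normally distributed
across the population (median Ψb(50), SD σΨb), and germinates once it has
accumulated a fixed hydrotime θH = (Ψ − Ψb(g))·t(g) of MPa-hours above its
base. Repeated probit regression searches θH and regresses

    probit(g) = [Ψ − θH/t(g) − Ψb(50)] / σΨb

so Ψb(50) = −intercept/slope and σΨb = 1/slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, UndefinedPercentileError
from .probit import ProbitDataset, SearchParam, SearchSpec, repeated_probit_search
from .records import PercentileCurve

__all__ = [
    "HydrotimeParams",
    "fit_hydrotime",
    "predict_ht_time_course",
    "ht_quantile_times",
    "ht_percentile_curve",
    "compare_across_temperatures",
]


@dataclass(frozen=True)
class HydrotimeParams:
    """Hydrotime parameters at one temperature (θH in MPa·h, Ψ in MPa)."""

    temperature: float
    theta_H: float
    psi_b50: float
    sigma_psib: float
    r2: float | None = None

    def __post_init__(self):
        if self.theta_H <= 0 or self.sigma_psib <= 0:
            raise FitError(
                f"invalid hydrotime parameters: theta_H={self.theta_H}, "
                f"sigma_psib={self.sigma_psib}"
            )
        if self.psi_b50 >= 0:
            raise FitError(f"psi_b50 must be negative (MPa), got {self.psi_b50}")


def _dataset(curves: Sequence[PercentileCurve]) -> ProbitDataset:
    psi, t, g = [], [], []
    for c in curves:
        psi.extend([c.water_potential] * len(c.percentiles))
        t.extend(c.times_g)
        g.extend(c.percentiles)
    return ProbitDataset(g=np.asarray(g), inputs={"psi": np.asarray(psi), "t": np.asarray(t)})


def fit_hydrotime(
    curves: Sequence[PercentileCurve],
    theta_bounds: tuple[float, float] = (1.0, 1e5),
    tol: float = 1e-5,
) -> HydrotimeParams:
    """Fit (θH, Ψb(50), σΨb) to percentile curves at one temperature across
    water potentials. θH is searched log-spaced over ``theta_bounds``."""
    curves = list(curves)
    if not curves:
        raise FitError("no percentile curves supplied")
    temps = sorted({c.temperature for c in curves})
    if len(temps) != 1:
        raise FitError(
            f"hydrotime is a single-temperature model; got temperatures {temps} "
            "(use the hydrothermal model for multi-temperature data)"
        )
    psis = sorted({c.water_potential for c in curves})
    if len(psis) < 2:
        raise FitError(
            f"θH is unidentifiable from a single water potential ({psis}); "
            "supply curves at ≥2 Ψ levels"
        )
    ds = _dataset(curves)
    spec = SearchSpec(
        params=(
            SearchParam("theta_H", theta_bounds[0], theta_bounds[1], n_coarse=41,
                        log=True, tol=tol),
        )
    )
    res = repeated_probit_search(
        ds, lambda inp, theta_H: inp["psi"] - theta_H / inp["t"], spec
    )
    return HydrotimeParams(
        temperature=temps[0],
        theta_H=res.params["theta_H"],
        psi_b50=res.location,
        sigma_psib=res.scale,
        r2=res.r2,
    )


def predict_ht_time_course(params: HydrotimeParams, psi: float, times) -> np.ndarray:
    """g(t) = Φ([Ψ − θH/t − Ψb(50)]/σΨb); limit t→∞ is Φ([Ψ − Ψb(50)]/σΨb)."""
    if psi > 0:
        raise ValueError(f"water potential must be ≤ 0 MPa, got {psi}")
    t = np.asarray(times, float)
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    z = (psi - params.theta_H / t - params.psi_b50) / params.sigma_psib
    return stats.norm.cdf(z)


def ht_asymptote(params: HydrotimeParams, psi: float) -> float:
    return float(stats.norm.cdf((psi - params.psi_b50) / params.sigma_psib))


def ht_quantile_times(params: HydrotimeParams, psi: float, percentiles) -> np.ndarray:
    """Exact model inverse: t(g) = θH / (Ψ − Ψb(g)) with
    Ψb(g) = Ψb(50) + σΨb·probit(g); undefined when Ψ ≤ Ψb(g)."""
    g = np.asarray(percentiles, float)
    psib_g = params.psi_b50 + params.sigma_psib * stats.norm.ppf(g)
    denom = psi - psib_g
    if np.any(denom <= 0):
        raise UndefinedPercentileError(
            f"percentile(s) unreachable at psi={psi}: base water potential not exceeded"
        )
    return params.theta_H / denom


def ht_percentile_curve(params: HydrotimeParams, psi: float, percentiles) -> PercentileCurve:
    """Noise-free percentile curve implied by the model at water potential Ψ."""
    g = tuple(float(v) for v in np.asarray(percentiles, float))
    t = ht_quantile_times(params, psi, g)
    return PercentileCurve(
        condition=(params.temperature, float(psi)),
        percentiles=g,
        times_g=tuple(float(v) for v in t),
        final_fraction=ht_asymptote(params, psi),
    )


@dataclass(frozen=True)
class TemperatureTrendReport:
    """Hydrotime fits ordered by temperature, with monotonicity flags."""

    table: pd.DataFrame
    theta_H_trend: str  # "decreasing" / "increasing" / "none"
    psi_b50_trend: str


def _trend(values: np.ndarray) -> str:
    d = np.diff(values)
    if len(d) == 0:
        return "none"
    if np.all(d < 0):
        return "decreasing"
    if np.all(d > 0):
        return "increasing"
    return "none"


def compare_across_temperatures(fits: Iterable[HydrotimeParams]) -> TemperatureTrendReport:
    """Tabulate per-temperature hydrotime fits and flag monotone trends in
    θH and Ψb(50) with increasing temperature (descriptive, no test)."""
    fits = sorted(fits, key=lambda f: f.temperature)
    if not fits:
        raise FitError("no hydrotime fits supplied")
    table = pd.DataFrame(
        {
            "temperature_C": [f.temperature for f in fits],
            "theta_H_MPa_h": [f.theta_H for f in fits],
            "psi_b50_MPa": [f.psi_b50 for f in fits],
            "sigma_psib_MPa": [f.sigma_psib for f in fits],
            "r2": [f.r2 for f in fits],
        }
    )
    return TemperatureTrendReport(
        table=table,
        theta_H_trend=_trend(table["theta_H_MPa_h"].to_numpy()),
        psi_b50_trend=_trend(table["psi_b50_MPa"].to_numpy()),
    )
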
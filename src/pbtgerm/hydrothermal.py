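"""Hydrothermal-time (HTT) germination model across T × Ψ conditions.

Sub-optimal temperatures (Tb < T ≤ To): a seed fraction g germinates after
accumulating θHT = (Ψ − Ψb(g))·(T − Tb)·t(g) MPa·°C·h, with Ψb normally
distributed across the population:

    probit(g) = [Ψ − θHT/((T − Tb)·t(g)) − Ψb(50)] / σΨb

Supra-optimal temperatures (T > To): the base-water-potential distribution
shifts toward zero at a rate K_T (MPa/°C) per degree above the optimum,
i.e. Ψb(50) is replaced by Ψb(50) + K_T·(T − To).

The sub-optimal fit is a joint 2-D repeated-probit search over (Tb, θHT);
the supra-optimal fit searches (θHT, K_T) given Tb and To (To defaulting to
the thermal-time estimate). At a single temperature the HTT model nests the
hydrotime model exactly, with θH = θHT/(T − Tb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import FitError, UndefinedPercentileError
from .probit import ProbitDataset, SearchParam, SearchSpec, repeated_probit_search
from .records import PercentileCurve

__all__ = [
    "HTTParams",
    "fit_htt_suboptimal",
    "fit_htt_supraoptimal",
    "predict_htt",
    "htt_quantile_times",
    "htt_percentile_curve",
    "psi_b_frequency_distribution",
]


@dataclass(frozen=True)
class HTTParams:
    """Hydrothermal-time parameters (θHT in MPa·°C·h).

    ``To`` and ``K_T`` are present only for fits that include supra-optimal
    temperatures; sub-optimal-only fits leave them None.
    """

    theta_HT: float
    Tb: float
    psi_b50: float
    sigma_psib: float
    r2: float | None = None
    To: float | None = None
    K_T: float | None = None
    fitted_temperature_set: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.theta_HT <= 0 or self.sigma_psib <= 0:
            raise FitError(
                f"invalid HTT parameters: theta_HT={self.theta_HT}, "
                f"sigma_psib={self.sigma_psib}"
            )
        if (self.K_T is None) != (self.To is None):
            raise FitError("K_T and To must be supplied together")
        if self.fitted_temperature_set is not None:
            tset = tuple(sorted(self.fitted_temperature_set))
            object.__setattr__(self, "fitted_temperature_set", tset)
            if self.Tb >= tset[0]:
                raise FitError(f"Tb={self.Tb} must lie below fitted temperatures {tset}")
            supra = self.To is not None and any(t > self.To for t in tset)
            if supra and self.K_T is None:
                raise FitError("fits spanning T > To require K_T")

    def psi_b50_effective(self, T: float) -> float:
        """Median base water potential at temperature T (shifted above To)."""
        if self.K_T is not None and T > self.To:
            return self.psi_b50 + self.K_T * (T - self.To)
        return self.psi_b50


def _dataset(curves: Sequence[PercentileCurve]) -> ProbitDataset:
    T, psi, t, g = [], [], [], []
    for c in curves:
        T.extend([c.temperature] * len(c.percentiles))
        psi.extend([c.water_potential] * len(c.percentiles))
        t.extend(c.times_g)
        g.extend(c.percentiles)
    return ProbitDataset(
        g=np.asarray(g),
        inputs={"T": np.asarray(T), "psi": np.asarray(psi), "t": np.asarray(t)},
    )


def fit_htt_suboptimal(
    curves: Sequence[PercentileCurve],
    tb_bounds: tuple[float, float] | None = None,
    theta_bounds: tuple[float, float] = (1.0, 1e5),
    tb_tol: float = 1e-3,
    theta_tol: float = 1e-5,
) -> HTTParams:
    """Joint 2-D repeated-probit search over (Tb, θHT) on sub-optimal T × Ψ
    data. Tb is searched on a 0.1 °C coarse grid, θHT log-spaced; both are
    geometrically refined to their tolerances."""
    curves = list(curves)
    temps = sorted({c.temperature for c in curves})
    psis = sorted({c.water_potential for c in curves})
    if len(temps) < 2:
        raise FitError(
            f"(Tb, θHT) are not jointly identifiable from one temperature ({temps}); "
            "fit the hydrotime model instead"
        )
    if len(psis) < 2:
        raise FitError(f"need ≥2 water-potential levels, got {psis}")
    if tb_bounds is None:
        tb_bounds = (0.0, temps[0] - 0.5)
    if tb_bounds[0] >= tb_bounds[1]:
        raise FitError(f"empty Tb search interval {tb_bounds}")
    n_tb = max(2, int(round((tb_bounds[1] - tb_bounds[0]) / 0.1)) + 1)
    ds = _dataset(curves)
    spec = SearchSpec(
        params=(
            SearchParam("Tb", tb_bounds[0], tb_bounds[1], n_coarse=n_tb, tol=tb_tol),
            SearchParam("theta_HT", theta_bounds[0], theta_bounds[1], n_coarse=41,
                        log=True, tol=theta_tol),
        )
    )
    res = repeated_probit_search(
        ds,
        lambda inp, Tb, theta_HT: inp["psi"] - theta_HT / ((inp["T"] - Tb) * inp["t"]),
        spec,
    )
    return HTTParams(
        theta_HT=res.params["theta_HT"],
        Tb=res.params["Tb"],
        psi_b50=res.location,
        sigma_psib=res.scale,
        r2=res.r2,
        fitted_temperature_set=tuple(temps),
    )


def fit_htt_supraoptimal(
    curves: Sequence[PercentileCurve],
    To: float,
    Tb: float,
    kt_bounds: tuple[float, float] = (0.0, 0.5),
    theta_bounds: tuple[float, float] = (1.0, 1e5),
    kt_tol: float = 1e-4,
    theta_tol: float = 1e-5,
) -> HTTParams:
    """Fit (θHT, K_T, Ψb(50), σΨb) on supra-optimal data given Tb and To.

    Experimental: the model is exactly as published but no reference
    parameter set exists for this branch, so treat results as exploratory.
    """
    curves = list(curves)
    temps = sorted({c.temperature for c in curves})
    if not any(t > To for t in temps):
        raise FitError(f"no supra-optimal conditions (T > To={To}) among {temps}")
    psis = sorted({c.water_potential for c in curves})
    if len(psis) < 2:
        raise FitError(f"need ≥2 water-potential levels, got {psis}")
    ds = _dataset(curves)
    spec = SearchSpec(
        params=(
            SearchParam("theta_HT", theta_bounds[0], theta_bounds[1], n_coarse=41,
                        log=True, tol=theta_tol),
            SearchParam("K_T", kt_bounds[0], kt_bounds[1], n_coarse=26, tol=kt_tol),
        )
    )
    res = repeated_probit_search(
        ds,
        lambda inp, theta_HT, K_T: (
            inp["psi"]
            - K_T * np.maximum(inp["T"] - To, 0.0)
            - theta_HT / ((inp["T"] - Tb) * inp["t"])
        ),
        spec,
    )
    return HTTParams(
        theta_HT=res.params["theta_HT"],
        Tb=Tb,
        psi_b50=res.location,
        sigma_psib=res.scale,
        r2=res.r2,
        To=To,
        K_T=res.params["K_T"],
        fitted_temperature_set=tuple(temps),
    )


def predict_htt(params: HTTParams, T: float, psi: float, times) -> np.ndarray:
    """g(t) = Φ([Ψ − θHT/((T − Tb)·t) − Ψb_eff(50)]/σΨb), with the K_T shift
    of Ψb above To when fitted. T ≤ Tb predicts identically zero (flagged)."""
    if psi > 0:
        raise ValueError(f"water potential must be ≤ 0 MPa, got {psi}")
    t = np.asarray(times, float)
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    if T <= params.Tb:
        warnings.warn(
            f"T={T} °C at or below Tb={params.Tb} °C: predicting zero germination",
            stacklevel=2,
        )
        return np.zeros_like(t)
    psib = params.psi_b50_effective(T)
    z = (psi - params.theta_HT / ((T - params.Tb) * t) - psib) / params.sigma_psib
    return stats.norm.cdf(z)


def htt_asymptote(params: HTTParams, T: float, psi: float) -> float:
    """Limit of g(t) as t → ∞: Φ([Ψ − Ψb_eff(50)]/σΨb), 0 below Tb."""
    if T <= params.Tb:
        return 0.0
    return float(
        stats.norm.cdf((psi - params.psi_b50_effective(T)) / params.sigma_psib)
    )


def htt_quantile_times(params: HTTParams, T: float, psi: float, percentiles) -> np.ndarray:
    """Exact model inverse: t(g) = θHT / ((Ψ − Ψb_eff(g))·(T − Tb))."""
    if T <= params.Tb:
        raise UndefinedPercentileError(f"no germination at T={T} ≤ Tb={params.Tb}")
    g = np.asarray(percentiles, float)
    psib_g = params.psi_b50_effective(T) + params.sigma_psib * stats.norm.ppf(g)
    denom = (psi - psib_g) * (T - params.Tb)
    if np.any(denom <= 0):
        raise UndefinedPercentileError(
            f"percentile(s) unreachable at (T={T}, psi={psi})"
        )
    return params.theta_HT / denom


def htt_percentile_curve(
    params: HTTParams, T: float, psi: float, percentiles
) -> PercentileCurve:
    """Noise-free percentile curve implied by the model at (T, Ψ)."""
    g = tuple(float(v) for v in np.asarray(percentiles, float))
    t = htt_quantile_times(params, T, psi, g)
    return PercentileCurve(
        condition=(float(T), float(psi)),
        percentiles=g,
        times_g=tuple(float(v) for v in t),
        final_fraction=htt_asymptote(params, T, psi),
    )


def psi_b_frequency_distribution(params: HTTParams, grid) -> np.ndarray:
    """Normal density of base water potentials Ψb across the seed population,
    mean Ψb(50) and SD σΨb, evaluated on ``grid`` (per MPa)."""
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty water-potential grid")
    return stats.norm.pdf(grid, loc=params.psi_b50, scale=params.sigma_psib)
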
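"""Synthetic germination time courses with exact threshold-model structure.

Each seed draws its own threshold from the population distribution the
probit forms imply — θT ~ N(θT(50), σθT) for sub-optimal thermal time,
Tc ~ N(Tc(50), σTc) for supra-optimal, Ψb ~ N(Ψb(50), σΨb) for hydro- and
hydrothermal time — and germinates at the deterministic time the accumulation
equation assigns, or never when the sign condition fails (Ψ ≤ Ψb, T ≤ Tb,
Tc ≤ T). Counts are recorded at the observation schedule: a seed germinating
between counts appears at the next count, exactly as bench counts are taken.

The default designs mirror the factorial layout of the study this package
reproduces: constant temperatures 5–40 °C in 5 °C steps at 0 MPa for thermal
time; Ψ ∈ {0, −0.25, −0.5, −0.75, −1.0} MPa at 10/20/30 °C for hydro- and
hydrothermal time; 10 replicates × 25 seeds per treatment; counts every 12 h
for 10 days (censoring at 240 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .hydro import HydrotimeParams
from .hydrothermal import HTTParams
from .records import GerminationAssay
from .thermal import SubThermalParams, SupraThermalParams

__all__ = [
    "SimulationDesign",
    "simulate_seed_thresholds",
    "germination_time",
    "simulate_dataset",
    "paper_design",
    "DEFAULT_OBSERVATION_TIMES",
]

#: twice-daily counts for 10 days
DEFAULT_OBSERVATION_TIMES: tuple[float, ...] = tuple(float(t) for t in range(12, 241, 12))

MODELS = ("tt-sub", "tt-supra", "ht", "htt")

_PARAM_TYPES = {
    "tt-sub": SubThermalParams,
    "tt-supra": SupraThermalParams,
    "ht": HydrotimeParams,
    "htt": HTTParams,
}


@dataclass(frozen=True)
class SimulationDesign:
    """A factorial germination experiment driven by one generating model."""

    model: str
    params: object
    temperatures: tuple[float, ...]
    water_potentials: tuple[float, ...] = (0.0,)
    n_replicates: int = 10
    seeds_per_replicate: int = 25
    observation_times: tuple[float, ...] = DEFAULT_OBSERVATION_TIMES
    rng_seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValidationError(f"model must be one of {MODELS}, got {self.model!r}")
        expected = _PARAM_TYPES[self.model]
        if not isinstance(self.params, expected):
            raise ValidationError(
                f"model {self.model!r} requires {expected.__name__} parameters, "
                f"got {type(self.params).__name__}"
            )
        object.__setattr__(self, "temperatures", tuple(float(t) for t in self.temperatures))
        object.__setattr__(
            self, "water_potentials", tuple(float(p) for p in self.water_potentials)
        )
        object.__setattr__(
            self, "observation_times", tuple(float(t) for t in self.observation_times)
        )
        obs = np.asarray(self.observation_times)
        if obs.size == 0 or np.any(obs <= 0) or np.any(np.diff(obs) <= 0):
            raise ValidationError("observation_times must be strictly increasing and > 0")
        if self.seeds_per_replicate <= 0 or self.n_replicates <= 0:
            raise ValidationError("seeds_per_replicate and n_replicates must be > 0")
        if any(p > 0 for p in self.water_potentials):
            raise ValidationError("water potentials must be ≤ 0 MPa")

    @property
    def censor_time(self) -> float:
        return self.observation_times[-1]

    @property
    def conditions(self) -> list[tuple[float, float]]:
        return [(T, p) for T in self.temperatures for p in self.water_potentials]


def _spread(design: SimulationDesign) -> float:
    p = design.params
    if design.model == "tt-sub":
        return p.sigma_thetaT
    if design.model == "tt-supra":
        return p.sigma_Tc
    return p.sigma_psib


def _median(design: SimulationDesign) -> float:
    p = design.params
    if design.model == "tt-sub":
        return p.theta_T50
    if design.model == "tt-supra":
        return p.Tc50
    return p.psi_b50


def simulate_seed_thresholds(
    design: SimulationDesign, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n per-seed thresholds from the design's population distribution.

    Draws are untruncated normals — the sign conditions of
    :func:`germination_time` alone decide which seeds never germinate, which
    keeps the simulated population exactly the one the probit forms describe.
    """
    sigma = _spread(design)
    if sigma < 0:
        raise ValidationError(f"spread must be ≥ 0, got {sigma}")
    return _median(design) + sigma * rng.standard_normal(n)


def germination_time(threshold: float, T: float, psi: float, design: SimulationDesign):
    """Time (hours) for one seed to germinate at (T, Ψ), or ``inf`` ("never").

    tt-sub:   t = θT_i/(T − Tb)              requires T > Tb (θT_i ≤ 0 → t=0)
    tt-supra: t = θT2/(Tc_i − T)             requires Tc_i > T
    ht:       t = θH/(Ψ − Ψb_i)              requires Ψ > Ψb_i
    htt:      t = θHT/((Ψ − Ψb_eff_i)(T − Tb)), Ψb shifted by K_T above To
    """
    p = design.params
    if design.model == "tt-sub":
        if T <= p.Tb:
            return np.inf
        return max(float(threshold), 0.0) / (T - p.Tb)
    if design.model == "tt-supra":
        if threshold <= T:
            return np.inf
        return p.theta_T2 / (float(threshold) - T)
    if design.model == "ht":
        if psi <= threshold:
            return np.inf
        return p.theta_H / (psi - float(threshold))
    # htt
    if T <= p.Tb:
        return np.inf
    psib = float(threshold)
    if p.K_T is not None and T > p.To:
        psib += p.K_T * (T - p.To)
    if psi <= psib:
        return np.inf
    return p.theta_HT / ((psi - psib) * (T - p.Tb))


def _times_vector(thresholds: np.ndarray, T: float, psi: float,
                  design: SimulationDesign) -> np.ndarray:
    return np.array([germination_time(th, T, psi, design) for th in thresholds])


def simulate_dataset(design: SimulationDesign) -> list[GerminationAssay]:
    """Simulate the full factorial design as one assay per (condition, replicate).

    Streams are spawned per condition and per replicate from ``rng_seed``, so
    enlarging ``n_replicates`` leaves the earlier replicates' counts
    untouched, and reruns with the same seed are identical.
    """
    root = np.random.SeedSequence(design.rng_seed)
    cond_seqs = root.spawn(len(design.conditions))
    obs = np.asarray(design.observation_times)
    assays = []
    for (T, psi), cseq in zip(design.conditions, cond_seqs):
        for rep, rseq in enumerate(cseq.spawn(design.n_replicates), start=1):
            rng = np.random.default_rng(rseq)
            thresholds = simulate_seed_thresholds(design, design.seeds_per_replicate, rng)
            t_germ = _times_vector(thresholds, T, psi, design)
            counts = (t_germ[None, :] <= obs[:, None]).sum(axis=1)
            assays.append(
                GerminationAssay(
                    temperature=T,
                    water_potential=psi,
                    replicate_id=f"R{rep}",
                    n_seeds=design.seeds_per_replicate,
                    times=tuple(obs),
                    cumulative_counts=tuple(int(c) for c in counts),
                )
            )
    return assays


# ---------------------------------------------------------------------------
# Default designs emulating the study layout


def default_generating_params(model: str):
    """Generating parameters used by the default designs.

    Hydro- and hydrothermal values are the reference parameter set for this
    species (θH=65 MPa·h, Ψb(50)=−0.70, σΨb=0.35 at 20 °C; θHT=516.6
    MPa·°C·h, Tb=7.2, Ψb(50)=−0.54, σΨb=0.40, with a K_T=0.02 MPa/°C shift
    above To=20 °C for supra-optimal conditions). Thermal-time defaults keep
    the reference cardinal temperatures (Tb=7.2 °C, Tc(50)=42.8 °C) but use
    thermal constants sized so germination spreads over days and resolves on
    a twice-daily schedule (θT(50)=250 °C·h, σθT=75 °C·h; θT2=250 °C·h,
    σTc=3.0 °C) — see the methods note for the unit discussion.
    """
    if model == "tt-sub":
        return SubThermalParams(theta_T50=250.0, Tb=7.2, sigma_thetaT=75.0)
    if model == "tt-supra":
        return SupraThermalParams(theta_T2=250.0, Tc50=42.8, sigma_Tc=3.0)
    if model == "ht":
        return HydrotimeParams(temperature=20.0, theta_H=65.0, psi_b50=-0.70,
                               sigma_psib=0.35)
    if model == "htt":
        return HTTParams(theta_HT=516.6, Tb=7.2, psi_b50=-0.54, sigma_psib=0.40,
                         To=20.0, K_T=0.02)
    raise ValidationError(f"unknown model {model!r}")


def paper_design(model: str, params=None, rng_seed: int = 0,
                 observation_times: Sequence[float] | None = None) -> SimulationDesign:
    """The study's factorial layout for one generating model.

    tt-sub: 5–20 °C at 0 MPa; tt-supra: 20–40 °C at 0 MPa; ht: 20 °C across
    the five Ψ levels; htt: 10/20/30 °C × five Ψ levels. Always 10 replicates
    of 25 seeds counted twice daily to 240 h.
    """
    if params is None:
        params = default_generating_params(model)
    obs = tuple(observation_times) if observation_times is not None \
        else DEFAULT_OBSERVATION_TIMES
    psis = (0.0, -0.25, -0.5, -0.75, -1.0)
    if model == "tt-sub":
        return SimulationDesign(model, params, temperatures=(5, 10, 15, 20),
                                water_potentials=(0.0,), rng_seed=rng_seed,
                                observation_times=obs)
    if model == "tt-supra":
        return SimulationDesign(model, params, temperatures=(20, 25, 30, 35, 40),
                                water_potentials=(0.0,), rng_seed=rng_seed,
                                observation_times=obs)
    if model == "ht":
        temp = params.temperature if isinstance(params, HydrotimeParams) else 20.0
        return SimulationDesign(model, params, temperatures=(temp,),
                                water_potentials=psis, rng_seed=rng_seed,
                                observation_times=obs)
    if model == "htt":
        return SimulationDesign(model, params, temperatures=(10, 20, 30),
                                water_potentials=psis, rng_seed=rng_seed,
                                observation_times=obs)
    raise ValidationError(f"unknown model {model!r}")
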
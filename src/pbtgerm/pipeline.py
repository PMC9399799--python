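"""One-command reproduction pipeline: ingest/simulate → indices → percentiles
→ TT/HT/HTT fits → predictions → summary report.

The pipeline is a pure function of (input data, configuration): rerunning
with the same config and seed produces byte-identical outputs. Parameters go
to JSON (machine-readable, shared schema with a ``model`` discriminator),
curves and indices to CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd
import yaml

from . import hydro, hydrothermal, records, simulate, thermal
from .errors import ConfigError, FitError, PbtgermError

log = logging.getLogger("pbtgerm")

VALID_MODELS = ("tt", "ht", "htt")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_csv`` / ``design`` must be set; ``design`` is the
    keyword form of :class:`pbtgerm.simulate.SimulationDesign` (see
    :func:`design_from_dict`).
    """

    out_dir: str
    input_csv: str | None = None
    design: dict | None = None
    time_unit: str = "h"
    percentiles: tuple[float, ...] | None = None
    split_at: float = 20.0
    models: tuple[str, ...] = ("tt", "ht", "htt")
    htt_temperatures: tuple[float, ...] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "models", tuple(self.models))
        if not self.models:
            raise ConfigError("model list must be non-empty")
        bad = [m for m in self.models if m not in VALID_MODELS]
        if bad:
            raise ConfigError(f"unknown model(s) {bad}; valid: {VALID_MODELS}")
        if (self.input_csv is None) == (self.design is None):
            raise ConfigError("exactly one of input_csv / design must be given")


@dataclass
class PipelineReport:
    """Everything one run produced, with paths to the files written."""

    groups: list
    curves: list
    tt_sub: thermal.SubThermalParams | None = None
    tt_supra: thermal.SupraThermalParams | None = None
    cardinal: thermal.CardinalTemperatures | None = None
    observed_To: float | None = None
    ht_fits: list = field(default_factory=list)
    htt: hydrothermal.HTTParams | None = None
    summary: pd.DataFrame | None = None
    outputs: dict = field(default_factory=dict)


def design_from_dict(d: dict) -> simulate.SimulationDesign:
    """Build a SimulationDesign from the YAML/JSON dict schema.

    Keys: ``model``, ``params`` (fields of the matching parameter type),
    ``temperatures``, ``water_potentials``, ``n_replicates``,
    ``seeds_per_replicate``, ``observation_times`` (list, or
    ``{start, stop, step}``), ``rng_seed``.
    """
    d = dict(d)
    model = d.pop("model", None)
    if model not in simulate.MODELS:
        raise ConfigError(f"design.model must be one of {simulate.MODELS}, got {model!r}")
    raw = d.pop("params", None)
    if raw is None:
        params = simulate.default_generating_params(model)
    elif isinstance(raw, dict):
        params = simulate._PARAM_TYPES[model](**raw)
    else:
        params = raw
    obs = d.pop("observation_times", None)
    if isinstance(obs, dict):
        obs = tuple(
            np.arange(obs["start"], obs["stop"] + obs["step"] / 2, obs["step"]).tolist()
        )
    kwargs = {}
    if obs is not None:
        kwargs["observation_times"] = tuple(obs)
    for key in ("temperatures", "water_potentials", "n_replicates",
                "seeds_per_replicate", "rng_seed"):
        if key in d:
            kwargs[key] = tuple(d[key]) if isinstance(d[key], (list, tuple)) else d[key]
    try:
        return simulate.SimulationDesign(model=model, params=params, **kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid design: {exc}") from exc


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    for key in ("models", "percentiles", "htt_temperatures"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def _params_json(obj, model: str) -> dict:
    d = {"model": model}
    d.update(dataclasses.asdict(obj))
    return d


def _dump_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


class _Stage:
    """Context manager attributing failures to a pipeline stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, PbtgermError):
            raise PbtgermError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full analysis chain and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    with _Stage("ingest"):
        if config.design is not None:
            design = design_from_dict({**config.design, "rng_seed":
                                       config.design.get("rng_seed", config.rng_seed)})
            assays = simulate.simulate_dataset(design)
            counts_path = out / "counts.csv"
            records.write_assays(assays, counts_path)
            outputs["counts"] = str(counts_path)
        else:
            assays = records.read_assays(config.input_csv, time_unit=config.time_unit)
        groups = records.pool_replicates(assays)

    with _Stage("indices"):
        idx_df = records.indices_table(groups)
        idx_path = out / "indices.csv"
        idx_df.to_csv(idx_path, index=False)
        outputs["indices"] = str(idx_path)

    with _Stage("percentiles"):
        curves = records.extract_all(groups, config.percentiles)
        if not curves:
            raise FitError("no condition produced an informative percentile curve")
        cur_path = out / "percentiles.csv"
        records.curves_table(curves).to_csv(cur_path, index=False)
        outputs["percentiles"] = str(cur_path)

    report = PipelineReport(groups=groups, curves=curves, outputs=outputs)
    summary_rows = []
    pred_frames = []

    if "tt" in config.models:
        with _Stage("thermal-time"):
            tt_curves = [c for c in curves if c.water_potential == 0.0]
            sub_curves = [c for c in tt_curves if c.temperature <= config.split_at]
            supra_curves = [c for c in tt_curves if c.temperature >= config.split_at]
            payload = {"model": "tt"}
            if len({c.temperature for c in sub_curves}) >= 2:
                report.tt_sub = thermal.fit_suboptimal_tt(sub_curves)
                payload["suboptimal"] = dataclasses.asdict(report.tt_sub)
                summary_rows.append(_summary_row(
                    "TT", f"sub-optimal ({_rng(sub_curves)})",
                    report.tt_sub.theta_T50, report.tt_sub.Tb,
                    report.tt_sub.sigma_thetaT, report.tt_sub.r2))
            if len({c.temperature for c in supra_curves}) >= 2:
                report.tt_supra = thermal.fit_supraoptimal_tt(supra_curves)
                payload["supraoptimal"] = dataclasses.asdict(report.tt_supra)
                summary_rows.append(_summary_row(
                    "TT", f"supra-optimal ({_rng(supra_curves)})",
                    report.tt_supra.theta_T2, report.tt_supra.Tc50,
                    report.tt_supra.sigma_Tc, report.tt_supra.r2))
            if report.tt_sub and report.tt_supra:
                report.cardinal = thermal.cardinal_temperatures(
                    report.tt_sub, report.tt_supra)
                payload["cardinal"] = dataclasses.asdict(report.cardinal)
            by_T = {g.temperature: records.germination_indices(g)
                    for g in groups if g.water_potential == 0.0}
            if by_T:
                report.observed_To = thermal.observed_optimum_temperature(by_T)
                payload["observed_To"] = report.observed_To
            _dump_json(payload, out / "tt_params.json")
            outputs["tt_params"] = str(out / "tt_params.json")
            for p, label in ((report.tt_sub, "tt-sub"), (report.tt_supra, "tt-supra")):
                if p is None:
                    continue
                for c in (sub_curves if label == "tt-sub" else supra_curves):
                    times = _pred_times(groups)
                    pred_frames.append(_prediction_frame(
                        label, c.temperature, 0.0, times,
                        thermal.predict_tt_time_course(p, c.temperature, times)))

    if "ht" in config.models:
        with _Stage("hydrotime"):
            fits = []
            for T in sorted({c.temperature for c in curves}):
                at_T = [c for c in curves if c.temperature == T]
                if len({c.water_potential for c in at_T}) < 2:
                    continue
                fits.append(hydro.fit_hydrotime(at_T))
            if fits:
                report.ht_fits = fits
                payload = [_params_json(f, "ht") for f in fits]
                _dump_json(payload, out / "ht_params.json")
                outputs["ht_params"] = str(out / "ht_params.json")
                for f in fits:
                    summary_rows.append(_summary_row(
                        "HT", f"{f.temperature:g} °C", f.theta_H, f.psi_b50,
                        f.sigma_psib, f.r2))
                    for c in [c for c in curves if c.temperature == f.temperature]:
                        times = _pred_times(groups)
                        pred_frames.append(_prediction_frame(
                            "ht", f.temperature, c.water_potential, times,
                            hydro.predict_ht_time_course(f, c.water_potential, times)))

    if "htt" in config.models:
        with _Stage("hydrothermal-time"):
            temps = config.htt_temperatures
            if temps is None:
                temps = tuple(
                    T for T in sorted({c.temperature for c in curves})
                    if T <= config.split_at
                    and len({c.water_potential for c in curves
                             if c.temperature == T}) >= 2
                )
            htt_curves = [c for c in curves if c.temperature in temps]
            if len({c.temperature for c in htt_curves}) >= 2:
                report.htt = hydrothermal.fit_htt_suboptimal(htt_curves)
                _dump_json(_params_json(report.htt, "htt"), out / "htt_params.json")
                outputs["htt_params"] = str(out / "htt_params.json")
                f = report.htt
                summary_rows.append(_summary_row(
                    "HTT", " and ".join(f"{t:g}" for t in f.fitted_temperature_set),
                    f.theta_HT, f.psi_b50, f.sigma_psib, f.r2, extra={"Tb_C": f.Tb}))
                for c in htt_curves:
                    times = _pred_times(groups)
                    pred_frames.append(_prediction_frame(
                        "htt", c.temperature, c.water_potential, times,
                        hydrothermal.predict_htt(f, c.temperature,
                                                 c.water_potential, times)))

    with _Stage("report"):
        report.summary = pd.DataFrame(summary_rows)
        sum_path = out / "summary.csv"
        report.summary.to_csv(sum_path, index=False)
        outputs["summary"] = str(sum_path)
        if pred_frames:
            pred = pd.concat(pred_frames, ignore_index=True)
            pred_path = out / "predictions.csv"
            pred.to_csv(pred_path, index=False)
            outputs["predictions"] = str(pred_path)
    report.outputs = outputs
    return report


def _rng(curves) -> str:
    temps = sorted({c.temperature for c in curves})
    return f"{temps[0]:g}–{temps[-1]:g} °C"


def _summary_row(model, condition, constant, location, spread, r2, extra=None):
    row = {
        "model": model,
        "range": condition,
        "constant": constant,
        "location": location,
        "spread": spread,
        "r2": r2,
    }
    if extra:
        row.update(extra)
    return row


def _pred_times(groups) -> np.ndarray:
    return np.asarray(groups[0].times)


def _prediction_frame(model, T, psi, times, g_pred) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": model,
            "temperature_C": T,
            "water_potential_MPa": psi,
            "t_h": np.asarray(times),
            "g_pred": np.asarray(g_pred),
        }
    )
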
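"""Germination time-course data model, I/O, indices, and percentile extraction.

The objects here are the common currency of the package: replicate-level
cumulative germination counts (:class:`GerminationAssay`), treatment-level
pools (:class:`ConditionGroup`), and the percentile times t(g) extracted by
probit-versus-log-time regression (:class:`PercentileCurve`) that every
threshold-model fit consumes.

Conventions
-----------
* time is in hours since sowing throughout; day-based input is converted on
  read (``time_unit="d"``),
* water potential is stored as printed, i.e. ≤ 0 MPa,
* cumulative fractions are computed against seeds sown (``n_seeds``), not
  against the final germinated count — the threshold models describe the whole
  population including seeds that never germinate,
* observed fractions of exactly 0 or 1 are uninformative on the probit scale
  and are excluded from the probit–log-time regression.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, FormatError, UndefinedPercentileError, ValidationError

#: default percentile grid: 10%–90% in 10% steps (truncated at the final
#: observed fraction when extracting from data).
DEFAULT_PERCENTILES: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))

CSV_COLUMNS = (
    "temperature_C",
    "water_potential_MPa",
    "replicate",
    "n_seeds",
    "time_h",
    "cum_germinated",
)


@dataclass(frozen=True)
class GerminationAssay:
    """One replicate's cumulative germination counts at one (T, Ψ) condition."""

    temperature: float
    water_potential: float
    replicate_id: str
    n_seeds: int
    times: tuple[float, ...]
    cumulative_counts: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(
            self, "cumulative_counts", tuple(int(c) for c in self.cumulative_counts)
        )
        if self.n_seeds <= 0:
            raise ValidationError(f"n_seeds must be > 0, got {self.n_seeds}")
        if self.water_potential > 0:
            raise ValidationError(
                f"water_potential must be ≤ 0 MPa, got {self.water_potential}"
            )
        if len(self.times) != len(self.cumulative_counts) or not self.times:
            raise ValidationError("times and cumulative_counts must align and be non-empty")
        t = np.asarray(self.times)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing and > 0")
        c = np.asarray(self.cumulative_counts)
        if np.any(np.diff(c) < 0):
            bad = int(np.flatnonzero(np.diff(c) < 0)[0]) + 1
            raise ValidationError(
                f"cumulative_counts decrease at index {bad} "
                f"({c[bad - 1]} -> {c[bad]}) for replicate {self.replicate_id!r}"
            )
        if np.any(c < 0) or np.any(c > self.n_seeds):
            raise ValidationError(
                f"counts must lie in [0, n_seeds={self.n_seeds}] "
                f"for replicate {self.replicate_id!r}"
            )

    @property
    def condition(self) -> tuple[float, float]:
        return (self.temperature, self.water_potential)

    @property
    def censor_time(self) -> float:
        """Last observation time; seeds not germinated by then are censored."""
        return self.times[-1]


@dataclass(frozen=True)
class ConditionGroup:
    """All replicates of one (T, Ψ) treatment, with pooled totals."""

    temperature: float
    water_potential: float
    assays: tuple[GerminationAssay, ...]
    times: tuple[float, ...]
    pooled_counts: tuple[int, ...]
    n_total: int

    @property
    def condition(self) -> tuple[float, float]:
        return (self.temperature, self.water_potential)

    @property
    def fractions(self) -> np.ndarray:
        return np.asarray(self.pooled_counts, float) / self.n_total

    @property
    def final_fraction(self) -> float:
        return self.pooled_counts[-1] / self.n_total


@dataclass(frozen=True)
class PercentileCurve:
    """Times t(g) to reach germination fractions g at one (T, Ψ) condition."""

    condition: tuple[float, float]
    percentiles: tuple[float, ...]
    times_g: tuple[float, ...]
    final_fraction: float

    def __post_init__(self):
        g = np.asarray(self.percentiles, float)
        t = np.asarray(self.times_g, float)
        if g.size != t.size or g.size == 0:
            raise ValidationError("percentiles and times_g must align and be non-empty")
        if np.any((g <= 0) | (g >= 1)):
            raise ValidationError("percentiles must lie strictly in (0, 1)")
        if np.any(np.diff(g) <= 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("percentiles and times_g must be strictly increasing")
        if np.any(g > self.final_fraction + 1e-12):
            raise ValidationError("every percentile must be ≤ final_fraction")

    @property
    def temperature(self) -> float:
        return self.condition[0]

    @property
    def water_potential(self) -> float:
        return self.condition[1]

    def time_for(self, g: float) -> float:
        g_arr = np.asarray(self.percentiles)
        idx = np.flatnonzero(np.isclose(g_arr, g, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise UndefinedPercentileError(f"g={g} not among curve percentiles")
        return self.times_g[int(idx[0])]


@dataclass(frozen=True)
class GerminationIndices:
    """Classical germination indices for one treatment.

    ``t50`` / ``germination_rate_50`` are None when fewer than half the seeds
    germinated by the censoring horizon; ``mean_germination_time`` is None
    when nothing germinated.
    """

    final_germination_pct: float
    mean_germination_time: float | None
    t50: float | None
    germination_rate_50: float | None


# ---------------------------------------------------------------------------
# I/O


def read_assays(path, time_unit: str = "h") -> list[GerminationAssay]:
    """Read a long-format counts CSV into one assay per (condition, replicate).

    Expected header: ``temperature_C, water_potential_MPa, replicate, n_seeds,
    time_h, cum_germinated``. ``time_unit="d"`` converts observation times from
    days to hours on read.
    """
    if time_unit not in ("h", "d"):
        raise ValueError("time_unit must be 'h' or 'd'")
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    factor = 24.0 if time_unit == "d" else 1.0
    assays = []
    for (temp, psi, rep), sub in df.groupby(
        ["temperature_C", "water_potential_MPa", "replicate"], sort=True
    ):
        sub = sub.sort_values("time_h")
        n_seeds = sub["n_seeds"].unique()
        if n_seeds.size != 1:
            raise ValidationError(
                f"n_seeds not constant within replicate {rep!r} at ({temp}, {psi})"
            )
        assays.append(
            GerminationAssay(
                temperature=float(temp),
                water_potential=float(psi),
                replicate_id=str(rep),
                n_seeds=int(n_seeds[0]),
                times=tuple(sub["time_h"].astype(float) * factor),
                cumulative_counts=tuple(sub["cum_germinated"].astype(int)),
            )
        )
    return assays


def write_assays(assays: Iterable[GerminationAssay], path) -> None:
    """Write assays to the long-format counts CSV (hours)."""
    rows = []
    for a in assays:
        for t, c in zip(a.times, a.cumulative_counts):
            rows.append((a.temperature, a.water_potential, a.replicate_id, a.n_seeds, t, c))
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pooling and indices


def pool_replicates(assays: Iterable[GerminationAssay]) -> list[ConditionGroup]:
    """Pool replicate counts within each (T, Ψ) condition.

    Replicates of one condition must share the observation-time grid exactly;
    no interpolation happens at this stage.
    """
    by_cond: dict[tuple[float, float], list[GerminationAssay]] = {}
    for a in assays:
        by_cond.setdefault(a.condition, []).append(a)
    groups = []
    for cond in sorted(by_cond):
        members = by_cond[cond]
        times0 = members[0].times
        for m in members[1:]:
            if m.times != times0:
                raise ValidationError(
                    f"mismatched time grids within condition {cond}: "
                    f"{m.replicate_id!r} differs from {members[0].replicate_id!r}"
                )
        pooled = np.sum([m.cumulative_counts for m in members], axis=0)
        groups.append(
            ConditionGroup(
                temperature=cond[0],
                water_potential=cond[1],
                assays=tuple(members),
                times=times0,
                pooled_counts=tuple(int(c) for c in pooled),
                n_total=sum(m.n_seeds for m in members),
            )
        )
    return groups


def germination_indices(group: ConditionGroup) -> GerminationIndices:
    """Final germination %, mean germination time, t50, and GR50.

    MGT is the germination-weighted mean of recorded counting times,
    Σ nᵢ·tᵢ / Σ nᵢ, over interval-new germinations nᵢ counted at time tᵢ.
    t50 comes from the probit-vs-log-time regression (see
    :func:`extract_percentiles`), not from linear interpolation of the raw
    curve, and is undefined when the final fraction is below 50%.
    """
    counts = np.asarray(group.pooled_counts, float)
    times = np.asarray(group.times, float)
    new = np.diff(counts, prepend=0.0)
    total = counts[-1]
    final_pct = 100.0 * total / group.n_total
    if total == 0:
        return GerminationIndices(0.0, None, None, None)
    mgt = float(np.sum(new * times) / total)
    t50 = None
    gr50 = None
    if group.final_fraction >= 0.5:
        try:
            curve = extract_percentiles(group, [0.5], method="regress")
            t50 = curve.times_g[0]
            gr50 = 1.0 / t50
        except FitError:
            pass  # fewer than 2 informative points: t50 stays undefined
    return GerminationIndices(final_pct, mgt, t50, gr50)


# ---------------------------------------------------------------------------
# Percentile extraction (probit vs log10 time)


def probit_log_time_fit(group: ConditionGroup) -> tuple[float, float]:
    """Least-squares line probit(fraction) = a + b·log10(t) over informative points.

    Informative points have cumulative fraction strictly in (0, 1). Returns
    (a, b); b must be positive for a usable fit.
    """
    frac = group.fractions
    t = np.asarray(group.times, float)
    mask = (frac > 0) & (frac < 1)
    if mask.sum() < 2:
        raise FitError(
            f"condition {group.condition}: need ≥2 informative points "
            f"(0 < fraction < 1), found {int(mask.sum())}"
        )
    x = np.log10(t[mask])
    y = stats.norm.ppf(frac[mask])
    if np.ptp(x) == 0:
        raise FitError(f"condition {group.condition}: no time variation among informative points")
    res = stats.linregress(x, y)
    if not np.isfinite(res.slope) or res.slope <= 0:
        raise FitError(
            f"condition {group.condition}: non-positive probit–log-time slope "
            f"({res.slope:.4g}); time course not usable"
        )
    return float(res.intercept), float(res.slope)


def _informative_probit_points(group: ConditionGroup) -> tuple[np.ndarray, np.ndarray]:
    """(log10 t, probit fraction) at informative observations, strictly
    increasing in both coordinates.

    A plateau (no new germination between counts) keeps only its first
    observation: with counts attributed to the observation following the
    event, the earliest time a fraction is recorded is when it was reached.
    """
    frac = group.fractions
    t = np.asarray(group.times, float)
    mask = (frac > 0) & (frac < 1)
    x = np.log10(t[mask])
    y = stats.norm.ppf(frac[mask])
    keep = np.concatenate([[True], np.diff(y) > 0]) if y.size else np.array([], bool)
    return x[keep], y[keep]


def extract_percentiles(
    group: ConditionGroup,
    percentiles: Sequence[float] | None = None,
    method: str = "interpolate",
) -> PercentileCurve:
    """Extract t(g) for germination percentiles on the probit–log-time scale.

    ``method="interpolate"`` (default) places each t(g) by piecewise-linear
    interpolation of probit(fraction) against log10(t) between the bracketing
    observed counts — local, and unbiased when counts follow a threshold
    model whose probit trend is not globally log-linear. Percentiles outside
    the observed probit range are dropped (default grid) since no bracket
    exists. ``method="regress"`` uses the single least-squares line
    probit(g) = a + b·log10(t) over all informative points and inverts it,
    t(g) = 10^((probit(g) − a)/b); both methods coincide when the observed
    points are collinear on that scale.

    The default grid is 10–90% in 10% steps, truncated at the final observed
    fraction; an explicitly requested g above the final fraction raises
    :class:`UndefinedPercentileError`.
    """
    if method not in ("interpolate", "regress"):
        raise ValueError(f"unknown extraction method {method!r}")
    final = group.final_fraction
    if percentiles is None:
        g = np.asarray([p for p in DEFAULT_PERCENTILES if p <= final + 1e-12])
        explicit = False
    else:
        g = np.asarray(list(percentiles), float)
        explicit = True
        bad = g[g > final + 1e-12]
        if bad.size:
            raise UndefinedPercentileError(
                f"condition {group.condition}: requested percentile(s) {bad.tolist()} "
                f"exceed final observed fraction {final:.3f}"
            )
    if np.any((g <= 0) | (g >= 1)):
        raise ValidationError("percentiles must lie strictly in (0, 1)")
    if method == "regress":
        a, b = probit_log_time_fit(group)
        t_g = 10.0 ** ((stats.norm.ppf(g) - a) / b)
    else:
        x, y = _informative_probit_points(group)
        if y.size < 2:
            raise FitError(
                f"condition {group.condition}: need ≥2 informative points "
                f"(0 < fraction < 1), found {y.size}"
            )
        z = stats.norm.ppf(g)
        inside = (z >= y[0] - 1e-12) & (z <= y[-1] + 1e-12)
        if explicit and not np.all(inside):
            raise UndefinedPercentileError(
                f"condition {group.condition}: percentile(s) "
                f"{g[~inside].tolist()} outside the observed probit range; "
                "use method='regress' to extrapolate"
            )
        g = g[inside]
        t_g = 10.0 ** np.interp(z[inside], y, x)
    if g.size == 0:
        raise FitError(
            f"condition {group.condition}: no requested percentile lies within "
            f"the observed range (final fraction {final:.3f})"
        )
    return PercentileCurve(
        condition=group.condition,
        percentiles=tuple(float(v) for v in g),
        times_g=tuple(float(v) for v in t_g),
        final_fraction=final,
    )


def extract_all(
    groups: Iterable[ConditionGroup],
    percentiles: Sequence[float] | None = None,
    skip_failures: bool = True,
    method: str = "interpolate",
) -> list[PercentileCurve]:
    """Extract percentile curves for many conditions.

    Conditions whose time course is uninformative (all-zero, complete before
    the first count, or non-monotone probit trend) are skipped when
    ``skip_failures`` is true — they simply contribute no points to the fits.
    """
    curves = []
    for grp in groups:
        try:
            curves.append(extract_percentiles(grp, percentiles, method=method))
        except (FitError, UndefinedPercentileError):
            if not skip_failures:
                raise
    return curves


def germination_rate(curve: PercentileCurve, g: float) -> float:
    """GR(g) = 1 / t(g), in h⁻¹."""
    return 1.0 / curve.time_for(g)


def indices_table(groups: Iterable[ConditionGroup]) -> pd.DataFrame:
    """One row of germination indices per condition."""
    rows = []
    for grp in groups:
        idx = germination_indices(grp)
        rows.append(
            {
                "temperature_C": grp.temperature,
                "water_potential_MPa": grp.water_potential,
                "n_seeds": grp.n_total,
                "final_germination_pct": idx.final_germination_pct,
                "mean_germination_time_h": idx.mean_germination_time,
                "t50_h": idx.t50,
                "germination_rate_50_per_h": idx.germination_rate_50,
            }
        )
    return pd.DataFrame(rows)


def curves_table(curves: Iterable[PercentileCurve]) -> pd.DataFrame:
    """Long-format table (condition, g, t_g_h) of percentile curves."""
    rows = []
    for c in curves:
        for g, t in zip(c.percentiles, c.times_g):
            rows.append(
                {
                    "temperature_C": c.temperature,
                    "water_potential_MPa": c.water_potential,
                    "g": g,
                    "t_g_h": t,
                }
            )
    return pd.DataFrame(rows)


def replace(obj, **changes):
    """dataclasses.replace passthrough (convenience for frozen records)."""
    return dataclasses.replace(obj, **changes)
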
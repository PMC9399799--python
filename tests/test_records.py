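"""Data model, I/O, indices, and percentile extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from pbtgerm.errors import (
    FitError,
    FormatError,
    UndefinedPercentileError,
    ValidationError,
)
from pbtgerm.records import (
    GerminationAssay,
    extract_percentiles,
    germination_indices,
    germination_rate,
    pool_replicates,
    probit_log_time_fit,
    read_assays,
    write_assays,
)
from pbtgerm.thermal import tt_quantile_times

from .conftest import SUB_TT, make_group


def _assay(times, counts, n_seeds=25, T=20.0, psi=0.0, rep="R1"):
    return GerminationAssay(T, psi, rep, n_seeds, tuple(times), tuple(counts))


class TestAssayValidation:
    @pytest.mark.parametrize(
        "times, counts, n_seeds",
        [
            ([24, 48], [5, 3], 25),       # decreasing cumulative count
            ([24, 48], [5, 30], 25),      # count exceeds seeds sown
            ([48, 24], [3, 5], 25),       # times not increasing
            ([0, 24], [0, 5], 25),        # non-positive time
            ([24, 48], [3, 5], 0),        # no seeds
        ],
    )
    def test_invalid_assays_rejected(self, times, counts, n_seeds):
        with pytest.raises(ValidationError):
            _assay(times, counts, n_seeds=n_seeds)

    def test_positive_water_potential_rejected(self):
        with pytest.raises(ValidationError):
            _assay([24, 48], [3, 5], psi=0.5)


class TestIO:
    def test_read_assays_parses_counts(self, tmp_path):
        path = tmp_path / "counts.csv"
        pd.DataFrame(
            {
                "temperature_C": [20.0, 20.0],
                "water_potential_MPa": [0.0, 0.0],
                "replicate": ["R1", "R1"],
                "n_seeds": [25, 25],
                "time_h": [24.0, 48.0],
                "cum_germinated": [3, 5],
            }
        ).to_csv(path, index=False)
        (assay,) = read_assays(path)
        assert assay.cumulative_counts == (3, 5)
        assert assay.times == (24.0, 48.0)
        assert assay.censor_time == 48.0

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"temperature_C": [20], "time_h": [24]}).to_csv(path, index=False)
        with pytest.raises(FormatError, match="missing column"):
            read_assays(path)

    def test_decreasing_counts_is_validation_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "temperature_C": [20.0, 20.0],
                "water_potential_MPa": [0.0, 0.0],
                "replicate": ["R1", "R1"],
                "n_seeds": [25, 25],
                "time_h": [24.0, 48.0],
                "cum_germinated": [5, 3],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="decrease"):
            read_assays(path)

    def test_day_unit_converts_on_read(self, tmp_path):
        path = tmp_path / "days.csv"
        pd.DataFrame(
            {
                "temperature_C": [20.0],
                "water_potential_MPa": [0.0],
                "replicate": ["R1"],
                "n_seeds": [25],
                "time_h": [2.0],  # days when time_unit="d"
                "cum_germinated": [5],
            }
        ).to_csv(path, index=False)
        (assay,) = read_assays(path, time_unit="d")
        assert assay.times == (48.0,)

    @given(
        increments=st.lists(
            st.tuples(
                st.integers(1, 4),             # count increments
                st.floats(1.0, 48.0),          # time increments
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_write_read_round_trip_is_identity(self, tmp_path_factory, increments):
        times, counts, t, c = [], [], 0.0, 0
        for dc, dt in increments:
            t += dt
            c = min(c + dc, 25)
            times.append(round(t, 6))
            counts.append(c)
        original = [
            _assay(times, counts, rep="R1"),
            _assay(times, counts, rep="R2", T=10.0, psi=-0.5),
        ]
        path = tmp_path_factory.mktemp("rt") / "counts.csv"
        write_assays(original, path)
        assert read_assays(path) == sorted(original, key=lambda a: a.condition)


class TestPooling:
    def test_pooled_counts_are_replicate_sums(self):
        a = _assay([24, 48], [10, 20], rep="R1")
        b = _assay([24, 48], [12, 22], rep="R2")
        (group,) = pool_replicates([a, b])
        assert group.n_total == 50
        assert group.pooled_counts == (22, 42)

    def test_single_replicate_pools_to_itself(self):
        a = _assay([24, 48], [10, 20])
        (group,) = pool_replicates([a])
        assert group.pooled_counts == a.cumulative_counts
        assert group.n_total == a.n_seeds

    def test_mismatched_time_grids_rejected(self):
        a = _assay([24, 48], [10, 20], rep="R1")
        b = _assay([24, 50], [12, 22], rep="R2")
        with pytest.raises(ValidationError, match="time grids"):
            pool_replicates([a, b])

    def test_pooled_indices_match_summed_assay(self):
        reps = [
            _assay([24, 48, 72], [2, 8, 12], rep="R1"),
            _assay([24, 48, 72], [5, 9, 15], rep="R2"),
        ]
        (pooled,) = pool_replicates(reps)
        summed = make_group([24, 48, 72], [7, 17, 27], n_seeds=50)
        assert germination_indices(pooled) == germination_indices(summed)


class TestIndices:
    def test_mean_germination_time_is_weighted_mean(self):
        group = make_group([48, 96], [5, 10], n_seeds=10)
        idx = germination_indices(group)
        assert idx.mean_germination_time == pytest.approx(72.0)
        assert idx.final_germination_pct == pytest.approx(100.0)

    def test_below_median_final_leaves_t50_undefined(self):
        group = make_group([48, 96], [4, 10], n_seeds=25)
        idx = germination_indices(group)
        assert idx.final_germination_pct == pytest.approx(40.0)
        assert idx.t50 is None and idx.germination_rate_50 is None

    def test_t50_exact_when_half_reached_at_observation(self):
        # 50% attained exactly at 48 h: the probit-log-time line must pass
        # through that observed point.
        group = make_group([24, 48], [5, 10], n_seeds=20)
        idx = germination_indices(group)
        assert idx.t50 == pytest.approx(48.0, rel=1e-9)
        assert idx.germination_rate_50 * idx.t50 == pytest.approx(1.0)

    def test_zero_germination_flags_not_raises(self):
        group = make_group([24, 48], [0, 0], n_seeds=25)
        idx = germination_indices(group)
        assert idx.final_germination_pct == 0.0
        assert idx.mean_germination_time is None

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=10).filter(
            lambda incs: sum(incs) > 0
        )
    )
    def test_mgt_lies_between_first_and_last_germination(self, increments):
        counts = np.cumsum(increments)
        times = 12.0 * np.arange(1, len(counts) + 1)
        group = make_group(times, counts, n_seeds=int(counts[-1]) + 5)
        idx = germination_indices(group)
        germinated = np.flatnonzero(np.diff(counts, prepend=0) > 0)
        assert times[germinated[0]] <= idx.mean_germination_time <= times[germinated[-1]]


class TestPercentileExtraction:
    def test_inverts_exactly_collinear_probit_line(self):
        # fractions placed exactly on probit(f) = -5 + 3*log10(t)
        fracs = np.array([0.2, 0.5, 0.8])
        times = 10.0 ** ((norm.ppf(fracs) + 5.0) / 3.0)
        group = make_group(times, (fracs * 100).astype(int), n_seeds=100)
        for method in ("interpolate", "regress"):
            curve = extract_percentiles(group, [0.5], method=method)
            assert curve.times_g[0] == pytest.approx(10 ** (5 / 3), rel=1e-9)

    def test_regress_line_reproduces_probit_at_extracted_times(self):
        group = make_group([12, 24, 48, 96], [2, 8, 15, 20], n_seeds=25)
        curve = extract_percentiles(group, [0.2, 0.4, 0.6], method="regress")
        a, b = probit_log_time_fit(group)
        for g, t in zip(curve.percentiles, curve.times_g):
            assert a + b * np.log10(t) == pytest.approx(norm.ppf(g), abs=1e-9)

    def test_all_percentiles_bracketed_by_jump_interval(self):
        # germination goes 1 -> 24 of 25 between 48 h and 60 h: every
        # interpolated t(g) in between must lie inside that interval
        group = make_group([24, 48, 60, 72], [0, 1, 24, 24], n_seeds=25)
        curve = extract_percentiles(group, [0.1, 0.5, 0.9])
        assert all(48.0 <= t <= 60.0 for t in curve.times_g)

    def test_percentile_above_final_fraction_rejected(self):
        group = make_group([24, 48], [5, 15], n_seeds=25)  # final 60%
        with pytest.raises(UndefinedPercentileError, match="0.9"):
            extract_percentiles(group, [0.9])

    def test_single_informative_point_is_fit_error(self):
        group = make_group([24, 48], [0, 10], n_seeds=25)
        with pytest.raises(FitError, match="informative"):
            extract_percentiles(group)

    def test_default_grid_truncates_at_final_fraction(self):
        group = make_group([12, 24, 48, 96], [1, 5, 8, 10], n_seeds=25)  # final 40%
        curve = extract_percentiles(group)
        assert max(curve.percentiles) <= 0.4
        assert curve.final_fraction == pytest.approx(0.4)


class TestGerminationRate:
    def test_rate_is_reciprocal_time(self):
        fracs = np.array([0.25, 0.5, 0.75])
        times = 10.0 ** ((norm.ppf(fracs) + 5.0) / 3.0)
        group = make_group(times, (fracs * 100).astype(int), n_seeds=100)
        curve = extract_percentiles(group, [0.5])
        assert germination_rate(curve, 0.5) == pytest.approx(1.0 / curve.times_g[0])

    def test_rate_decreases_with_percentile(self):
        group = make_group([12, 24, 48, 96], [2, 8, 15, 20], n_seeds=25)
        curve = extract_percentiles(group, [0.2, 0.4, 0.6])
        rates = [germination_rate(curve, g) for g in curve.percentiles]
        assert rates == sorted(rates, reverse=True)

    def test_rate_matches_thermal_time_identity(self):
        # t(50) at 20 °C from the sub-optimal thermal-time reference set:
        # GR(50) = (T − Tb)/θT(50) = 12.8/3.01 ≈ 4.2517 h⁻¹ (t50 ≈ 0.2352 h)
        t50 = float(tt_quantile_times(SUB_TT, 20.0, [0.5])[0])
        assert t50 == pytest.approx(0.2352, abs=2e-4)
        assert 1.0 / t50 == pytest.approx(4.2517, rel=1e-3)

    def test_unlisted_percentile_rejected(self):
        group = make_group([12, 24, 48, 96], [2, 8, 15, 20], n_seeds=25)
        curve = extract_percentiles(group, [0.2])
        with pytest.raises(UndefinedPercentileError):
            germination_rate(curve, 0.5)
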
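import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pbtgerm.hydro import HydrotimeParams
from pbtgerm.hydrothermal import HTTParams
from pbtgerm.records import ConditionGroup, GerminationAssay, pool_replicates
from pbtgerm.thermal import SubThermalParams, SupraThermalParams

#: reference parameter sets the worked examples revolve around
SUB_TT = SubThermalParams(theta_T50=3.01, Tb=7.2, sigma_thetaT=0.30)
SUPRA_TT = SupraThermalParams(theta_T2=3.21, Tc50=42.8, sigma_Tc=0.37)
HT_20C = HydrotimeParams(temperature=20.0, theta_H=65.0, psi_b50=-0.70, sigma_psib=0.35)
HTT_REF = HTTParams(theta_HT=516.6, Tb=7.2, psi_b50=-0.54, sigma_psib=0.40)

GRID_9 = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))


@pytest.fixture
def sub_tt():
    return SUB_TT


@pytest.fixture
def supra_tt():
    return SUPRA_TT


@pytest.fixture
def ht_20c():
    return HT_20C


@pytest.fixture
def htt_ref():
    return HTT_REF


def make_group(times, counts, n_seeds, temperature=20.0, psi=0.0) -> ConditionGroup:
    """Single-replicate condition group from raw cumulative counts."""
    assay = GerminationAssay(
        temperature=temperature,
        water_potential=psi,
        replicate_id="R1",
        n_seeds=n_seeds,
        times=tuple(times),
        cumulative_counts=tuple(counts),
    )
    return pool_replicates([assay])[0]
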
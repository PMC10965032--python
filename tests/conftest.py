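import pytest

from entocalib import SizeRange, ThermalSummationParams


@pytest.fixture
def nlit_params() -> ThermalSummationParams:
    """Necrodes littoralis thermal summation constants."""
    return ThermalSummationParams(k=469.89, s_e=24.59, m=8, unit="ADD", d0=8.5)


@pytest.fixture
def nlit_range() -> SizeRange:
    """Literature size range used for N. littoralis."""
    return SizeRange(15.0, 25.0, source="lit")


@pytest.fixture
def cmax_params() -> ThermalSummationParams:
    """Creophilus maxillosus thermal summation constants."""
    return ThermalSummationParams(k=405.156, s_e=14.63, m=8, unit="ADD", d0=11.7)
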
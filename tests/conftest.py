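import numpy as np
import pytest

from cotrans import ColorCountTable

# Published reference class counts (also packaged under cotrans/data/).
VITRO_ROWS = {
    "1e10": (14, 77, 184, 1475),
    "5e10": (5, 9, 52, 1707),
    "5e11": (0, 0, 0, 1791),
}
VIVO_ROWS = {
    "ACC": (0, 0, 20, 3948),
    "MC": (0, 7, 12, 4319),
    "PFC": (0, 3, 13, 4443),
    "SSC": (0, 5, 7, 4712),
    "VI": (0, 4, 15, 4397),  # internally inconsistent printed total; lambda not asserted
}
VITRO_PRINTED = {"1e10": 7.9, "5e10": 12.4}
VIVO_PRINTED = {"ACC": 19.2, "MC": 18.6, "PFC": 19.7, "SSC": 20.2}


@pytest.fixture
def vitro_low() -> ColorCountTable:
    return ColorCountTable(VITRO_ROWS["1e10"], label="1e10", dose=1e10)


@pytest.fixture
def vitro_mid() -> ColorCountTable:
    return ColorCountTable(VITRO_ROWS["5e10"], label="5e10", dose=5e10)


@pytest.fixture
def vitro_saturated() -> ColorCountTable:
    return ColorCountTable(VITRO_ROWS["5e11"], label="5e11", dose=5e11)


def asymptotic_sd(lam: float, n: int, k: int = 3) -> float:
    """Delta-method sd of the point estimator: sqrt(k p / ((1-p) N))."""
    p = -np.expm1(-lam / k)
    return float(np.sqrt(k * p / ((1 - p) * n)))
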
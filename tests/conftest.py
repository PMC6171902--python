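import pytest

from teratopd.datasets import (
    DOSE_SERIES,
    line_incidences,
    line_latencies,
    teratoma_specimens,
)
from teratopd.expression import TumorigenicityVariables


@pytest.fixture(scope="session")
def dose_series_rows():
    """Bundled dose-incidence rows for the three 201B7 transplantation formats."""
    return DOSE_SERIES


@pytest.fixture(scope="session")
def study_variables():
    """Per-line latency/incidence for the ten hiPSC lines."""
    return TumorigenicityVariables(
        latency_weeks=line_latencies(), incidence_pct=line_incidences()
    )


@pytest.fixture(scope="session")
def specimens():
    return teratoma_specimens()
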
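import pandas as pd
import pytest

from mscompare.io import ExpressionMatrix, SampleSheet
from mscompare.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.5, 0.5, 0.5, 0.5], [10.0, 12.0, 9.0, 11.0]],
        index=["f1", "f2", "f3"],
        columns=["iWAT_1", "iWAT_2", "PANC_1", "PANC_2"],
    )
    return ExpressionMatrix(data, "FPKM")


@pytest.fixture
def small_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["iWAT_1", "iWAT_2", "PANC_1", "PANC_2"],
                "group": ["iWAT", "iWAT", "PANC", "PANC"],
                "excluded": [False] * 4,
            }
        )
    )


def make_sheet(n_per_group: int = 8) -> SampleSheet:
    ref = [f"iWAT_{i + 1}" for i in range(n_per_group)]
    tst = [f"PANC_{i + 1}" for i in range(n_per_group)]
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ref + tst,
                "group": ["iWAT"] * n_per_group + ["PANC"] * n_per_group,
                "excluded": [False] * (2 * n_per_group),
            }
        )
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """A moderately sized coupled dataset shared across read-only tests."""
    return simulate_dataset(
        SimulationConfig(seed=7, n_transcripts=1200, n_mirnas=240, n_terms=40)
    )
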
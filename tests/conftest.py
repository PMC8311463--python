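import pytest

from cyclopept.peaks import PeakList
from cyclopept.refdata import (
    ACAULIFLORA_DERIVATIZATION_TABLE,
    alca1,
    alca2,
)
from cyclopept.screen import ScreenParams


@pytest.fixture(scope="session")
def derivatization_lists():
    """The 18-row A. cauliflora quadruple table as four labelled peak lists."""
    labels = ("native", "reduced", "alkylated", "linearized")
    return {
        label: PeakList.from_pairs(
            [row[i] for row in ACAULIFLORA_DERIVATIZATION_TABLE], label
        )
        for i, label in enumerate(labels)
    }


@pytest.fixture(scope="session")
def dalton_params():
    """0.2 Da step tolerance, matching the one-decimal table precision."""
    return ScreenParams(tolerance_mode="dalton", tolerance_value=0.2)


@pytest.fixture(scope="session")
def alca1_oxidized():
    return alca1("oxidized")


@pytest.fixture(scope="session")
def alca1_cam():
    return alca1("carbamidomethylated")


@pytest.fixture(scope="session")
def alca2_cam():
    return alca2("carbamidomethylated")
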
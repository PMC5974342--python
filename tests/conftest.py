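import pandas as pd
import pytest

from pcrstop import PCRStopDesign, PlateData, THEORY_PROFILE, simulate_pcr_stop


@pytest.fixture(scope="session")
def theory_plate() -> PlateData:
    """Noiseless ideal-assay plate: 6 batches x 8 wells, template 10."""
    return simulate_pcr_stop(PCRStopDesign(initial_template=10), THEORY_PROFILE, seed=1)


def make_plate(batches: dict[int, list]) -> PlateData:
    """Build a plate from {prerun: [value or None (negative), ...]}."""
    rows = []
    for prerun, values in batches.items():
        for well, v in enumerate(values):
            if v is None:
                rows.append((prerun, well, float("nan"), True))
            else:
                rows.append((prerun, well, float(v), False))
    return PlateData(pd.DataFrame(rows, columns=["batch_prerun", "well", "observed_copies", "negative"]))


@pytest.fixture(scope="session")
def plate_builder():
    return make_plate


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    from pcrstop.io import make_fixtures

    outdir = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(outdir)
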
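from pathlib import Path

import hypothesis
import numpy as np
import pandas as pd
import pytest

from nirselect import SimConfig, generate_study, analyze_study

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_rows() -> pd.DataFrame:
    """Panel-A rows (order, index, wavelength, weight, coefficient) of the
    seven published oxidation-marker calibrations of the deep-frying study."""
    return pd.read_csv(DATA / "reference_models.tsv", sep="\t")


@pytest.fixture(scope="session")
def reference_stats() -> pd.DataFrame:
    """Panel-B statistics of the seven published calibrations."""
    return pd.read_csv(DATA / "reference_stats.tsv", sep="\t")


@pytest.fixture(scope="session")
def study():
    """One default synthetic deep-frying study (seed 1)."""
    return generate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def study_results(study):
    """Fitted SELECT-OLS calibrations for all seven markers of the study."""
    return analyze_study(study.spectra, study.markers)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
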
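import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lur.features import PredictorMatrix, PredictorSpec
from lur.synthetic import StudyConfig, simulate_study


def make_matrix(values, names, signs, site_ids=None) -> PredictorMatrix:
    """Wrap a plain numpy array as a PredictorMatrix for selection tests."""
    values = np.asarray(values, dtype=float)
    if site_ids is None:
        site_ids = [f"S{i:03d}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, columns=list(names), index=site_ids)
    specs = {
        name: PredictorSpec(name, "synthetic", "distance", None, sign)
        for name, sign in zip(names, signs)
    }
    return PredictorMatrix(frame=frame, specs=specs)


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    return StudyConfig(
        seed=11,
        area_width=1500.0,
        area_height=1200.0,
        n_sites=30,
        noise_sd=0.0,
        ref_gap_fraction=0.0,
        no2_cutover=None,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)
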
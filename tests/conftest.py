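import warnings

import numpy as np
import pytest

from fibertex.synth import CLASS_PRESETS, generate_dataset
from fibertex.features import build_table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def preset_table():
    """Feature table for 30 crops per class at the default presets (seed 7).

    Session-scoped: this is the synthetic analogue of the study's crop set
    and several tests (directional trends, classifier suite) share it.
    """
    crops, truths = generate_dataset(CLASS_PRESETS, n_crops_per_class=30, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = build_table(crops)
    table.attrs["truths"] = truths
    return table
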
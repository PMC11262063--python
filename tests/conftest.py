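import numpy as np
import pandas as pd
import pytest

from sersquant import (
    NoiseModel,
    SpectraSet,
    default_axis,
    default_thiol_library,
)


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def library(axis):
    return default_thiol_library(axis)


@pytest.fixture()
def zero_noise():
    return NoiseModel.zero(seed=0)


def make_set(axis, X, conc=None, analytes=("A",), batch="t"):
    """Assemble a SpectraSet from a raw matrix for unit tests."""
    n = X.shape[0]
    if conc is None:
        conc = pd.DataFrame(np.zeros((n, len(analytes))), columns=list(analytes))
    elif not isinstance(conc, pd.DataFrame):
        conc = pd.DataFrame(np.atleast_2d(conc), columns=list(analytes))
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"u{i:03d}" for i in range(n)],
            "sample_id": [f"u{i:03d}" for i in range(n)],
            "replicate": 1,
            "batch": batch,
        }
    )
    return SpectraSet(axis=axis, intensities=X, concentrations=conc, metadata=meta)
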
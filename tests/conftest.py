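import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from spotscreen import SceneSpec, render_field, train_default_model


@pytest.fixture(scope="session")
def phenotype_model():
    """Default QDA model trained on generator-labelled nuclei (shared)."""
    return train_default_model(seed=0)


@pytest.fixture(scope="session")
def default_field():
    """One default array-spot field with ground truth (shared, read-only)."""
    return render_field(SceneSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
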
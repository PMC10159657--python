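import numpy as np
import pytest
from hypothesis import settings

from tcrforest import synthetic_data as sd
from tcrforest.core_io import PairRecord

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_repertoire():
    """Noise-free planted-rule repertoire at realistic class imbalance."""
    cfg = sd.SyntheticConfig(n_pairs=4000, binding_fraction=0.0327, seed=11)
    records, rule = sd.generate_repertoire(cfg)
    return records, rule


@pytest.fixture(scope="session")
def labeled_records():
    return [
        PairRecord("CASSLGTDTQYF", "GILGFVFTL", label=1, source="a"),
        PairRecord("CASSPGQGDYEQYF", "NLVPMVATV", label=0, source="a"),
        PairRecord("CASRRGSSYEQYF", "GLCTLVAML", label=1, source="b"),
        PairRecord("CASSLAPGATNEKLFF", "ELAGIGILTV", label=0, source="b"),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
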
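import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def table1():
    from xyypairing import datasets

    return datasets.load_table1()


@pytest.fixture
def table2():
    from xyypairing import datasets

    return datasets.load_table2()


@pytest.fixture
def table3_subsets():
    """Replicate-subset statistics without the all-nine-vials row."""
    from xyypairing import datasets

    t3 = datasets.load_table3()
    return t3[t3["subset"] != "123"]


@pytest.fixture
def table4():
    from xyypairing import datasets

    return datasets.load_table4()
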
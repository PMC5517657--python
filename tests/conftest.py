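import numpy as np
import pytest

from xpct import DiseaseModel, MaterialTable, PhantomSpec, generate_phantom
from xpct.phantom import NeuronParams


@pytest.fixture(scope="session")
def small_spec():
    # 64³ keeps unit tests fast; fewer somata so they fit the smaller horns
    return PhantomSpec.micro_default(shape=(64, 64, 64), seed=11,
                                     neurons=NeuronParams(per_horn=3))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec, DiseaseModel())


@pytest.fixture(scope="session")
def table30():
    return MaterialTable.preset(30.0, "micro")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
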
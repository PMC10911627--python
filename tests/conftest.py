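import pytest

from azodesign.model import apply_medium
from azodesign.synthetic import ToySpec, demo_medium, make_demo_model, make_toy_model


@pytest.fixture(scope="session")
def aromatic_toy():
    """Default aromatic-substrate toy (certified at generation time)."""
    return make_toy_model(ToySpec(substrate_mode="aromatic"))


@pytest.fixture(scope="session")
def sugar_toy():
    return make_toy_model(ToySpec(substrate_mode="sugar"))


@pytest.fixture(scope="session")
def both_toy():
    return make_toy_model(ToySpec(substrate_mode="both"))


@pytest.fixture(scope="session")
def demo_model():
    return make_demo_model()


@pytest.fixture(scope="session")
def demo_mr(demo_model):
    return apply_medium(demo_model, demo_medium("mr"))


@pytest.fixture(scope="session")
def demo_glc(demo_model):
    return apply_medium(demo_model, demo_medium("glc"))


@pytest.fixture(scope="session")
def demo_glc_mr(demo_model):
    return apply_medium(demo_model, demo_medium("glc_mr"))
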
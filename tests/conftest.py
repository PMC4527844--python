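import numpy as np
import pytest

from granulinkit.motif import MotifSpec
from granulinkit.synthetic import GeneratorConfig, build_template, evolve_family


@pytest.fixture(scope="session")
def spec():
    return MotifSpec.default()


@pytest.fixture(scope="session")
def mammalian_template():
    """Default mammalian progranulin-like template with ground truth."""
    rng = np.random.default_rng(123)
    cfg = GeneratorConfig()
    gene, truth = build_template(cfg, rng)
    return gene, truth


@pytest.fixture(scope="session")
def small_family(mammalian_template):
    """Six-species family evolved from the mammalian template."""
    gene, truth = mammalian_template
    cfg = GeneratorConfig(n_species=6, height=0.25)
    rng = np.random.default_rng(99)
    return evolve_family(gene, truth, cfg, rng)
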
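import numpy as np
import pytest

from mipclass.synthetic import (
    generate_heterokont_panel,
    make_template,
    packaged_references,
)


@pytest.fixture(scope="session")
def panel():
    return generate_heterokont_panel(seed=1)


@pytest.fixture(scope="session")
def refs():
    return packaged_references()


@pytest.fixture(scope="session")
def template():
    return make_template(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def simulate_jtt_pair(true_d: float, n_sites: int, seed: int):
    """Two residue strings whose second row evolved from the first under the
    JTT model at distance ``true_d`` (stationary start)."""
    from mipclass.phylo import default_model
    from mipclass.records import AMINO_ACIDS

    model = default_model()
    gen = np.random.default_rng(seed)
    p = model.transition_matrix(true_d)
    p = p / p.sum(axis=1, keepdims=True)
    a = gen.choice(20, size=n_sites, p=model.pi / model.pi.sum())
    b = np.array([gen.choice(20, p=p[x]) for x in a])
    row_a = "".join(AMINO_ACIDS[i] for i in a)
    row_b = "".join(AMINO_ACIDS[i] for i in b)
    return row_a, row_b
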
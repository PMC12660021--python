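import numpy as np
import pytest

import corb


@pytest.fixture(scope="session")
def clear33():
    return corb.make_clear_structure(3, 3)


@pytest.fixture(scope="session")
def g331():
    return corb.make_g_structure(3, 3, 1)


@pytest.fixture(scope="session")
def s333():
    return corb.make_s_structure(3, [3, 3, 3], "all")


@pytest.fixture(scope="session")
def small_corb_fixture():
    """Small identified dataset with known truth for estimation tests."""
    structure = corb.make_g_structure(3, 3, 2)
    Sigma = np.array(
        [
            [1.2, 0.4, -0.2, 0.3],
            [0.4, 1.0, 0.25, 0.1],
            [-0.2, 0.25, 0.8, 0.15],
            [0.3, 0.1, 0.15, 1.1],
        ]
    )
    beta = np.linspace(-1.5, 1.5, structure.n_items)
    data, theta = corb.generate_responses(structure, beta, Sigma, 400, seed=42)
    return structure, data, beta, Sigma, theta


@pytest.fixture(scope="session")
def structure_corpus():
    """Small structures (<= 12 items, D <= 5) for oracle comparisons."""
    return [
        corb.make_clear_structure(2, 2),
        corb.make_clear_structure(3, 3),
        corb.make_clear_structure(4, 2),
        corb.make_g_structure(2, 2, 1),
        corb.make_g_structure(3, 3, 1),
        corb.make_g_structure(3, 2, 3),
        corb.make_g_structure(4, 2, 1),
        corb.make_s_structure(2, [2, 2], "all"),
        corb.make_s_structure(3, [3, 3, 3], "all"),
        corb.make_s_structure(3, [2, 2, 2], [(1, 2)]),
        corb.make_s_structure(4, [2, 2, 2, 2], "all"),
    ]
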
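import numpy as np
import pytest

import metabsel as ms


@pytest.fixture(scope="session")
def nold_panel():
    """2,000 independent SNPs (no LD, unit weights)."""
    return ms.simulate_panel(2000, 2000, 0.01, 0.5, 0.0, seed=42)


@pytest.fixture(scope="session")
def ld_panel():
    """600 SNPs in 30 exchangeable-correlation blocks with spread LD scores."""
    return ms.simulate_panel(600, 30, 0.05, 0.5, (0.2, 0.8), seed=7)


@pytest.fixture(scope="session")
def tree26():
    return ms.random_tree(26, seed=5)


@pytest.fixture(scope="session")
def star_tree():
    import dendropy

    tips = ",".join(f"t{i}:1.0" for i in range(1, 31))
    return dendropy.Tree.get(data=f"({tips});", schema="newick")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
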
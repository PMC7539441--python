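import numpy as np
import pytest

from ssgblup import Pedigree, SimConfig


def random_pedigree(rng: np.random.Generator, n_founders: int = 5,
                    n_offspring: int = 10, allow_inbreeding: bool = True):
    """Random valid pedigree; later animals may have earlier animals as parents."""
    recs = [(f"a{i}", None, None) for i in range(n_founders)]
    for j in range(n_offspring):
        k = n_founders + j
        pool = k
        sire = f"a{rng.integers(0, pool)}"
        dam = f"a{rng.integers(0, pool)}"
        while dam == sire:
            dam = f"a{rng.integers(0, pool)}"
        recs.append((f"a{k}", sire, dam))
    return Pedigree.from_records(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20201007)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down two-line study used by several integration tests."""
    return SimConfig(
        n_snps=800, n_qtl=120, n_generations=5,
        n_g0_candidates=32, n_candidates_per_gen=32,
        n_dams_per_line=12, n_f0_sires=12, n_f0_dams=12,
        response_litters_per_gen=1, seed=77,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    from ssgblup import simulate_study

    return simulate_study(small_config)
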
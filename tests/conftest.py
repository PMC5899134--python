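import numpy as np
import pytest

from ribocap import AssayConfig, ConstructSpec, default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def assay():
    return AssayConfig()


def random_instances(seed: int, n: int, max_species: int = 3, max_sites: int = 30):
    """Randomized competitive-translation instances for solver checks."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        k = int(rng.integers(1, max_species + 1))
        species = [
            ConstructSpec(
                name=f"s{i}",
                rbs_strength=float(rng.uniform(0.3, 3.0)),
                mrna_conc=float(rng.uniform(10.0, 900.0)),
                length_bp=int(rng.integers(1, max_sites + 1)) * 30,
                gamma=float(10 ** rng.uniform(np.log10(0.05), np.log10(5.0))),
            )
            for i in range(k)
        ]
        out.append(species)
    return out
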
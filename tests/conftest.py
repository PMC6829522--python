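import numpy as np
import pytest

from colonybin.markers import MarkerCatalog
from colonybin.synthetic import generate_genome


@pytest.fixture(scope="session")
def catalog() -> MarkerCatalog:
    return MarkerCatalog.synthetic(n_markers=50, tag_length=60, seed=99)


@pytest.fixture(scope="session")
def small_genomes(catalog):
    """Three 20-kbp genomes spanning low/mid/high GC with planted markers."""
    specs = [("gA", 0.30), ("gB", 0.50), ("gC", 0.70)]
    return [
        generate_genome(gid, 20_000, gc, 20, catalog, seed=11 + i)
        for i, (gid, gc) in enumerate(specs)
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
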
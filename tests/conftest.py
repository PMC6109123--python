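import numpy as np
import pytest

from landgen.datatypes import GenotypeMatrix
from landgen.synthetic import SyntheticSpec, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic bundle at a reduced locus count."""
    spec = SyntheticSpec(seed=11, L=1200)
    gm, sf, raster, truth = generate_bundle(spec)
    return {"spec": spec, "gm": gm, "sf": sf, "raster": raster, "truth": truth}


@pytest.fixture(scope="session")
def full_bundle():
    """Full study-scale bundle (3,849 loci) for estimator-accuracy checks."""
    spec = SyntheticSpec(seed=21)
    gm, sf, raster, truth = generate_bundle(spec)
    return {"spec": spec, "gm": gm, "sf": sf, "raster": raster, "truth": truth}


def panmictic_matrix(rng: np.random.Generator, n: int = 30, L: int = 120) -> GenotypeMatrix:
    """HWE genotypes with no spatial or population structure."""
    p = rng.uniform(0.1, 0.9, L)
    G = rng.binomial(2, p, size=(n, L)).astype(np.int8)
    return GenotypeMatrix([f"i{i:03d}" for i in range(n)],
                          [f"l{j:04d}" for j in range(L)], G)
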
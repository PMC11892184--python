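import numpy as np
import pytest

from invertonkit.core import revcomp
from invertonkit.ir_locate import IRSearchParams
from invertonkit.simulate import PlantSpec, make_genome, plant_inverton

# exact-match scoring: a prohibitive mismatch penalty makes the ungapped
# extension stop at the first mismatch, so reported pairs are exactly the
# maximal exact complementary runs the brute-force oracle enumerates
EXACT = IRSearchParams(mismatch_penalty=-(10**6))


@pytest.fixture
def exact_params():
    return EXACT


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


@pytest.fixture
def planted_genome():
    """A 20 kb genome with one planted inverton (20 nt IR, 300 nt payload)."""
    rng = np.random.default_rng(101)
    g = make_genome(20000, 0.5, rng)
    spec = PlantSpec("S1__0", 10000, random_seq(rng, 20), random_seq(rng, 300))
    g, locus = plant_inverton(g, spec)
    return g, locus
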
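import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from intsite.formats_io import PrimerSpec, ReferenceGenome

TR = "ACCTGCAGGCATGCAAGCTTGGCGT"
DISTAL = "AGATCGGAAGAGCACACGTC"
ADAPTOR2 = "CTGTCTCTTATACACATCTG"


@pytest.fixture
def primers():
    return PrimerSpec(TR, DISTAL, ADAPTOR2)


def random_genome(seed: int, lengths=(4000, 3000)) -> ReferenceGenome:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return ReferenceGenome(
        {
            f"chr{i+1}": bases[rng.integers(0, 4, n)].tobytes().decode()
            for i, n in enumerate(lengths)
        }
    )


@pytest.fixture
def small_genome():
    return random_genome(42)
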
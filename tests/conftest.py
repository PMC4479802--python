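import numpy as np
import pytest

from refcoll.params import CodecParams, TOY_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_params() -> CodecParams:
    """Tiny hand-checkable configuration: short seeds, light match weight."""
    return TOY_PARAMS


def random_dna(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length)) if length else ""


def mutated_copy(rng, ref: str, snp_rate: float = 0.01) -> str:
    out = list(ref)
    for i in range(len(out)):
        if rng.random() < snp_rate:
            out[i] = "ACGT"[(("ACGT".find(out[i]) + 1 + int(rng.integers(3))) % 4)]
    return "".join(out)
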
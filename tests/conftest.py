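import numpy as np
import pytest

from mirmarker import ReadLibrary, Condition


@pytest.fixture
def toy_reference() -> dict[str, str]:
    """Ten 20-22 nt reference sequences with deterministic content."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    ref = {}
    for i in range(10):
        L = 20 + i % 3
        ref[f"mir{i + 1:03d}"] = "".join(rng.choice(bases, L))
    return ref


@pytest.fixture
def random_reads():
    """Factory for deterministic random read lists."""

    def make(n: int, lengths=(16, 25), seed: int = 0) -> list[str]:
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        return [
            "".join(rng.choice(bases, int(rng.integers(lengths[0], lengths[1] + 1))))
            for _ in range(n)
        ]

    return make


@pytest.fixture
def normal_libraries():
    return [
        ReadLibrary("n1", Condition.NORMAL, ["ACGTACGTACGTACGT"] * 5 + ["TTTTACGTACGTACGT"] * 5),
        ReadLibrary("n2", Condition.NORMAL, ["GGGGACGTACGTACGT"] * 10),
    ]
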
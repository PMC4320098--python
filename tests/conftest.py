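import numpy as np
import pytest

from pdekit.simulate import default_benchmark


def make_iiia_sequence(
    spacers=(1, 37, 30, 69, 36, 1), variant="GNHD", nter=40, cter=60, bg="A"
):
    """Deterministic planted-architecture sequence over a quiet background."""
    parts = [bg * nter]
    for text, spacer in zip(("D", "H", "GD", variant, "H", "GH", "H"),
                            list(spacers) + [0]):
        parts.append(text)
        parts.append(bg * spacer)
    parts.append(bg * cter)
    return "".join(parts)


@pytest.fixture(scope="session")
def benchmark60():
    """The default three-subclass fixture: 20 sequences per subclass."""
    records, truth = default_benchmark(n_per_subclass=20, seed=0)
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
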
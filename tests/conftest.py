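import numpy as np
import pytest

from aavgenotyper import Msa, SimConfig, simulate_population


@pytest.fixture
def toy_msa() -> Msa:
    return Msa(
        ["s1", "s2", "s3", "s4"],
        [
            "ACGTACGTACGT",
            "ACGTACGAACGT",
            "ACGAACGTACGA",
            "TCGAACGATCGA",
        ],
    )


@pytest.fixture(scope="session")
def default_population():
    """One default-condition simulated population shared across tests."""
    cfg = SimConfig(seed=11)
    msa, truth = simulate_population(cfg)
    return cfg, msa, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_alignment(rng: np.random.Generator, n: int, length: int,
                     gap_frac: float = 0.0) -> Msa:
    """Uniform random nucleotide alignment, optionally gapped."""
    chars = np.frombuffer(b"ACGT-", dtype=np.uint8)
    probs = [(1 - gap_frac) / 4] * 4 + [gap_frac]
    mat = rng.choice(chars, size=(n, length), p=probs)
    return Msa(
        [f"r{i}" for i in range(n)],
        [row.tobytes().decode() for row in mat],
    )
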
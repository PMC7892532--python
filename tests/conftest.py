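import numpy as np
import pytest

from coibarcode import (
    Alignment,
    SequenceRecord,
    SimulationConfig,
    distance_matrix,
    simulate_dataset,
)


@pytest.fixture
def tiny_alignment() -> Alignment:
    """Two species x two individuals, plus an outgroup; hand-built."""
    return Alignment(
        [
            SequenceRecord(id="a1", seq="ACGTACGTACGT", species="Genus alpha"),
            SequenceRecord(id="a2", seq="ACGTACGTACGA", species="Genus alpha"),
            SequenceRecord(id="b1", seq="ACTTGCGAACGT", species="Genus beta"),
            SequenceRecord(id="b2", seq="ACTTGCGAACTT", species="Genus beta"),
            SequenceRecord(id="og", seq="GTTTGCAAACCT", species="Out group", outgroup=True),
        ]
    )


@pytest.fixture(scope="session")
def separated_dataset():
    """Simulated survey with a wide gap between intra- and interspecific
    divergence; every species should be recoverable."""
    config = SimulationConfig(
        n_species=12,
        seed=11,
        gamma_alpha=None,
        p_inv=0.0,
        interspecific_height=0.25,
        intraspecific_height=0.002,
        preserve_reading_frame=True,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def separated_dm(separated_dataset):
    return distance_matrix(separated_dataset.alignment)


def random_alignment(
    rng: np.random.Generator,
    n: int = 8,
    L: int = 60,
    mutation: float = 0.15,
    missing: float = 0.05,
) -> Alignment:
    """Sequences mutated independently from one random ancestor, with a
    sprinkling of gaps and Ns; divergence stays below K2P saturation."""
    bases = np.array(list("ACGT"))
    ancestor = rng.choice(4, size=L)
    records = []
    for i in range(n):
        row = ancestor.copy()
        flip = rng.random(L) < mutation
        row[flip] = rng.choice(4, size=int(flip.sum()))
        seq = bases[row]
        mask = rng.random(L) < missing
        seq[mask] = rng.choice(np.array(list("-N")), size=int(mask.sum()))
        records.append(
            SequenceRecord(id=f"r{i}", seq="".join(seq), species=f"Sp {i // 2}")
        )
    return Alignment(records)
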
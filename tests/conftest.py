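import numpy as np
import pytest

import cemig


@pytest.fixture(scope="session")
def planted_dataset():
    """500 uniform-background sequences, 30% carrying a mutated TGACTCAT."""
    spec = cemig.PlantSpec(
        motif_consensus="TGACTCAT",
        instance_rate=0.3,
        mutation_rate=0.1,
        n_sequences=500,
        seq_length=100,
        background_order=0,
        rng_seed=7,
    )
    return cemig.generate_planted_dataset(spec)


@pytest.fixture(scope="session")
def discovery_result(planted_dataset):
    seqs, _ = planted_dataset
    return cemig.discover(seqs)


def random_sequence_set(rng: np.random.Generator, n: int, length: int) -> cemig.SequenceSet:
    bases = np.array(list("ACGT"))
    return cemig.SequenceSet(
        [
            (f"r{i}", "".join(bases[rng.integers(4, size=length)]))
            for i in range(n)
        ]
    )


def random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    bases = np.array(list("ACGT"))
    out = {"".join(bases[rng.integers(4, size=k)]) for _ in range(n)}
    return sorted(out)
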
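import numpy as np
import pandas as pd
import pytest

from ssgwas.io_formats import GenotypeMatrix, Pedigree


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree.from_records([("s", "0", "0"), ("d", "0", "0"), ("k", "s", "d")])


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """Three animals, four markers on two chromosomes, no missing calls."""
    markers = pd.DataFrame(
        {
            "snp_id": ["m1", "m2", "m3", "m4"],
            "chrom": ["1", "1", "2", "2"],
            "pos": [100, 200, 100, 200],
        }
    )
    calls = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 1],
            [2, 0, 1, 2],
        ],
        dtype=float,
    )
    return GenotypeMatrix(ids=["s", "d", "k"], markers=markers, calls=calls)


def small_sim_config(seed: int, **overrides):
    """A compact simulation shared by several test modules."""
    from ssgwas.synthetic import SimulationConfig, single_trait_model

    defaults = dict(
        seed=seed,
        n_founders=40,
        n_generations=2,
        offspring_per_mating=2,
        n_chromosomes=2,
        markers_per_chromosome=100,
        genotyped_fraction=0.5,
        missing_rate=0.0,
        traits=single_trait_model(0.3),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
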
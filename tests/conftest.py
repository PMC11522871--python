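import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mnbc
from mnbc import benchmark as bm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_community(tmp_path_factory):
    """A tiny 3-species community on disk: FASTAs, taxonomy, built database."""
    root = tmp_path_factory.mktemp("toy_community")
    rng = np.random.default_rng(99)
    genomes, taxonomy = bm.generate_synthetic_genomes(
        n_species=3,
        strains_per_species=2,
        genome_length=20_000,
        strain_divergence=0.01,
        rng=rng,
        out_dir=root / "community",
    )
    db = mnbc.build_database(
        [root / "community" / f"{g}.fasta" for g in sorted(genomes)],
        root / "community" / "taxonomy.tsv",
        k=15,
        out_dir=root / "db",
    )
    return {"root": root, "genomes": genomes, "taxonomy": taxonomy, "db": db}
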
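import numpy as np
import pytest

from organedit import (
    OrganelleGenome,
    SimulationSpec,
    ToyGenomeConfig,
    build_toy_genome,
    load_fixtures,
    simulate_reads,
)
from organedit.genome import GenomeFeature


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def plus_toy_genome():
    """900 nt plastid-like toy genome with one plus-strand CDS and one site."""
    cfg = ToyGenomeConfig(
        genome_id="cp_toy",
        length=900,
        features=[GenomeFeature("ndhB_like", "CDS", 101, 550, "+")],
        editing_sites=[(391, "+", "site_plus")],
        seed=11,
    )
    return build_toy_genome(cfg)


@pytest.fixture(scope="session")
def minus_toy_genome():
    """700 nt mitochondrion-like toy genome with a minus-strand CDS."""
    cfg = ToyGenomeConfig(
        genome_id="mt_toy",
        length=700,
        features=[GenomeFeature("ccmC_like", "CDS", 151, 550, "-")],
        editing_sites=[(300, "-", "site_minus")],
        seed=3,
    )
    return build_toy_genome(cfg)


def random_genome(length: int, seed: int, features=None) -> OrganelleGenome:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return OrganelleGenome(id=f"rand{seed}", sequence=seq, features=features or [])


def simple_library(genome, n_pairs, editing_fractions=None, seed=0, **kw):
    spec = SimulationSpec(
        genome_id=f"lib{seed}",
        n_pairs=n_pairs,
        editing_fractions=editing_fractions or {},
        seed=seed,
        **kw,
    )
    return list(simulate_reads(genome, spec))
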
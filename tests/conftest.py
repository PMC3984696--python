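import numpy as np
import pytest

from matekin.genotype_io import Individual, MicrosatGenotype, Population
from matekin.synthetic import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_pop():
    """Small random-mating population with ground truth (1 year)."""
    cfg = SimulationConfig(
        years=1, n_males=30, n_females=30, n_pairs=12, epp_rate=0.3, seed=11
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def three_year_pop():
    """Three-year random-mating population at moderate size."""
    cfg = SimulationConfig(
        years=3, n_males=40, n_females=40, n_pairs=15, epp_rate=0.4, seed=17
    )
    return generate(cfg)


def make_population(genotypes: dict[str, dict[str, tuple[int, int]]],
                    loci: list[str],
                    sexes: dict[str, str] | None = None) -> Population:
    """Hand-built adult population from literal genotype dicts."""
    sexes = sexes or {}
    inds = {
        iid: Individual(
            id=iid,
            sex=sexes.get(iid, "male"),
            stage="adult",
            genotype=MicrosatGenotype(calls),
        )
        for iid, calls in genotypes.items()
    }
    return Population(individuals=inds, locus_names=loci)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
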
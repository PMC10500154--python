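"""Shared fixtures: one small synthetic study reused across test modules.

Session-scoped objects are treated as read-only by every test.
"""

import numpy as np
import pytest

from epimem.counts import simulate_methylomes
from epimem.genome import generate_genome
from epimem.scenario import PlantedDMR, ScenarioConfig
from epimem.truth import apply_treatment, simulate_truth

SMALL_PLANTED = [
    PlantedDMR("chr1", 10_000, 10_600, "CHG", 0.4),
    PlantedDMR("chr2", 30_000, 30_600, "CHG", 0.4),
]


def make_small_scenario(**overrides) -> ScenarioConfig:
    defaults = dict(
        chrom_lengths={"chr1": 60_000, "chr2": 60_000, "chrC": 10_000},
        genes_per_chrom=12,
        res_per_chrom=10,
        pseudogenes_per_chrom=3,
        groups=("eco1", "eco2"),
        global_shift={"CGN": 0.0, "CHG": 0.0, "CHH": 0.0},
        planted_dmrs=list(SMALL_PLANTED),
        seed=5,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def make_flat_scenario(**overrides) -> ScenarioConfig:
    """All shape parameters neutral: every site of a context shares one truth."""
    defaults = dict(
        chrom_lengths={"chr1": 50_000, "chrC": 8_000},
        genes_per_chrom=8,
        res_per_chrom=5,
        pseudogenes_per_chrom=2,
        subcontext_multipliers={},
        gene_body_mult=1.0,
        gene_dip_mult=1.0,
        re_plateau_mult=1.0,
        pseudogene_edge_mult=1.0,
        pseudogene_body_mult=1.0,
        groups=("eco1",),
        global_shift={"CGN": 0.0, "CHG": 0.0, "CHH": 0.0},
        seed=11,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def small_scenario():
    return make_small_scenario()


@pytest.fixture(scope="session")
def small_genome(small_scenario):
    return generate_genome(small_scenario)


@pytest.fixture(scope="session")
def small_truth(small_scenario, small_genome):
    return apply_treatment(simulate_truth(small_genome, small_scenario),
                           small_scenario)


@pytest.fixture(scope="session")
def small_table(small_scenario, small_truth):
    return simulate_methylomes(small_truth, small_scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
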
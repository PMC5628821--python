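"""Shared fixtures: small synthetic panels and breed models."""

import numpy as np
import pytest

from snpwave import BreedModel, simulate_breed_frequencies, simulate_genome_and_sites, simulate_genotypes


RIVER_BREEDS = [
    BreedModel("Mediterranean", fst=0.05, maf_spectrum_shape=1.0, n_samples=8),
    BreedModel("Murrah", fst=0.08, maf_spectrum_shape=1.0, n_samples=8),
    BreedModel("Jaffarabadi", fst=0.12, maf_spectrum_shape=1.6, n_samples=6),
    BreedModel("Nili-Ravi", fst=0.08, maf_spectrum_shape=1.0, n_samples=6),
]


@pytest.fixture(scope="session")
def river_breeds():
    return RIVER_BREEDS


@pytest.fixture(scope="session")
def small_panel(river_breeds):
    """200 kb x 2 chromosomes with planted clusters, ambiguous SNPs and
    low-quality sites, plus breed frequencies and genotypes."""
    panel = simulate_genome_and_sites(
        n_chrom=2, chrom_length=200_000, site_density=1e-3,
        cluster_fraction=0.06, ambiguous_fraction=0.10,
        low_quality_fraction=0.05, seed=11)
    panel.breed_frequencies = simulate_breed_frequencies(
        len(panel.sites), river_breeds, seed=12)
    panel.breed_names = [b.name for b in river_breeds]
    return panel


@pytest.fixture(scope="session")
def small_genotypes(small_panel, river_breeds):
    return simulate_genotypes(small_panel, river_breeds, seed=13)
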
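"""Shared fixtures: fast synthetic haplotype panels and small founder sets.

Most tests avoid the coalescent backend entirely by plugging a random binary
panel generator into ``simulate_founder_haplotypes`` (the engine hook exists
precisely so a cheap generator can stand in); only the coalescent-specific
tests and the acceptance suite run msprime.
"""

from __future__ import annotations

import numpy as np
import pytest

from heteropool import (
    DominanceConfig,
    GenomeParams,
    calibrate_trait,
    make_inbred_founders,
    sample_effects,
    select_loci,
    simulate_founder_haplotypes,
)

# 2 chromosomes of 1 Morgan each on a tiny physical map
TINY_GENOME = GenomeParams(n_chromosomes=2, genetic_length=1.0,
                           physical_length=1e6, recombination_rate=1e-6)


def random_panel_engine(sites_per_chromosome: int = 60):
    """A drift-free random binary panel generator with the engine signature."""

    def engine(params: GenomeParams, n_haplotypes: int, seed: int):
        rng = np.random.default_rng(seed)
        positions, haplotypes = [], []
        top = int(params.physical_length)
        for _ in range(params.n_chromosomes):
            pos = np.sort(rng.choice(np.arange(1, top), size=sites_per_chromosome,
                                     replace=False)).astype(np.int64)
            h = rng.integers(0, 2, size=(n_haplotypes, sites_per_chromosome)).astype(np.uint8)
            # force every site segregating
            f = h.mean(axis=0)
            h[0, f == 0] = 1
            h[0, f == 1] = 0
            positions.append(pos)
            haplotypes.append(h)
        return positions, haplotypes

    return engine


def make_toy_inputs(n_founders: int = 20, n_snp: int = 40, n_qtn: int = 16,
                    dom_mean: float = 0.4, dom_var: float = 0.2, seed: int = 11,
                    sites_per_chromosome: int = 60, calibrate: bool = True):
    """Founders + loci + (optionally calibrated) trait on a synthetic panel."""
    panel = simulate_founder_haplotypes(
        TINY_GENOME, n_founders, seed,
        min_sites_per_chromosome=(n_snp + n_qtn) // TINY_GENOME.n_chromosomes,
        engine=random_panel_engine(sites_per_chromosome))
    founders = make_inbred_founders(panel, n_founders)
    loci = select_loci(panel, n_snp, n_qtn, seed + 1)
    arch = sample_effects(n_qtn, DominanceConfig(dom_mean, dom_var), seed + 2)
    if calibrate:
        arch = calibrate_trait(arch, founders.dosages_at(loci, "qtn"))
    return founders, loci, arch


@pytest.fixture(scope="session")
def toy_inputs():
    return make_toy_inputs()


@pytest.fixture(scope="session")
def coalescent_panel():
    """One real (msprime) panel at reduced scale, shared across tests."""
    genome = GenomeParams(n_chromosomes=2, genetic_length=1.0,
                          physical_length=2.5e7, recombination_rate=4e-8)
    return simulate_founder_haplotypes(genome, 40, seed=3,
                                       min_sites_per_chromosome=700)
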
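import sys
from pathlib import Path

import pytest

import capmeth as cm

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module


@pytest.fixture(scope="session")
def toy_genome():
    return cm.generate_genome(1, 20000, 0.45,
                              {"n_per_chrom": 4, "length": 800,
                               "cpg_fraction": 0.25}, seed=7)


@pytest.fixture(scope="session")
def toy_methylome(toy_genome):
    return cm.generate_methylome(toy_genome, seed=1)


@pytest.fixture(scope="session")
def toy_targets(toy_genome):
    return cm.define_targets(toy_genome, 20, 100, 300, seed=2)


@pytest.fixture(scope="session")
def toy_hets(toy_genome):
    return cm.plant_het_sites(toy_genome, 0.001, seed=3)


@pytest.fixture(scope="session")
def toy_library(toy_genome, toy_methylome, toy_targets, toy_hets):
    params = cm.SimParams(n_fragments=2000, seed=5)
    return cm.simulate_reads(toy_genome, toy_methylome, toy_targets,
                             toy_hets, params)


@pytest.fixture(scope="session")
def toy_index(toy_genome):
    return cm.ConvertedIndex(toy_genome)


@pytest.fixture(scope="session")
def toy_aligned(toy_library, toy_index):
    return cm.align_library(toy_library.pairs, toy_index)


@pytest.fixture(scope="session")
def toy_dedup(toy_aligned):
    return cm.deduplicate(toy_aligned)


@pytest.fixture(scope="session")
def toy_calls(toy_dedup, toy_genome):
    calls = cm.pileup(toy_dedup.kept, toy_genome)
    est = cm.estimate_nonconversion(calls)
    return cm.correct_levels(calls, est)
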
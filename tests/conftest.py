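"""Shared fixtures: hand-constructable site tables and one small shared
simulation run used by several test modules."""

import numpy as np
import pandas as pd
import pytest

from archstats.genotype_io import AlignedSiteTable, classify_mutation
from archstats.synthetic_data import DemographyConfig, sim_to_site_table, simulate


def make_table(
    nea, den, pop_b_counts, pop_n_called, sample_dosages=None,
    alleles=("A", "G"), chrom="1",
):
    """Build an AlignedSiteTable from parallel per-site arrays.

    ``nea``/``den``: archaic states (0/1/-1); ``pop_b_counts`` /
    ``pop_n_called``: dicts population -> int array; ``sample_dosages``:
    dict sample -> diploid dosage array (0/1/2/-1).  Alleles may be a pair
    (applied to all sites) or a list of pairs.
    """
    n = len(nea)
    if isinstance(alleles[0], str):
        alleles = [alleles] * n
    data = {
        "chrom": [chrom] * n,
        "pos": np.arange(1, n + 1, dtype=np.int64),
        "allele_A": [a for a, _ in alleles],
        "allele_B": [b for _, b in alleles],
        "mutation_class": [classify_mutation(a, b) for a, b in alleles],
        "state_chimpanzee": np.zeros(n, dtype=np.int8),
        "state_neanderthal": np.asarray(nea, dtype=np.int8),
        "state_denisovan": np.asarray(den, dtype=np.int8),
    }
    for pop, bc in pop_b_counts.items():
        data[f"bcount_{pop}"] = np.asarray(bc, dtype=np.int64)
        data[f"ncalled_{pop}"] = np.asarray(pop_n_called[pop], dtype=np.int64)
    for sample, dos in (sample_dosages or {}).items():
        data[f"gt_{sample}"] = np.asarray(dos, dtype=np.int8)
    return AlignedSiteTable(pd.DataFrame(data))


def random_table(rng, n_sites=40, pops=("P1", "P2", "P3"), n_alleles=20,
                 n_samples=2):
    """A random small table for brute-force oracle comparisons."""
    nea = rng.choice([0, 1, -1], size=n_sites, p=[0.45, 0.45, 0.1])
    den = rng.choice([0, 1, -1], size=n_sites, p=[0.45, 0.45, 0.1])
    ncalled = {p: rng.integers(2, n_alleles + 1, size=n_sites) for p in pops}
    bcounts = {p: rng.integers(0, ncalled[p] + 1) for p in pops}
    dosages = {f"s{k}": rng.choice([0, 1, 2, -1], size=n_sites,
                                   p=[0.35, 0.25, 0.3, 0.1])
               for k in range(n_samples)}
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    alleles = [pairs[i] for i in rng.integers(0, len(pairs), size=n_sites)]
    return make_table(nea, den, bcounts, ncalled, dosages, alleles=alleles)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down copy of the default scenario for fast shared runs."""
    return DemographyConfig(num_fragments=10)


@pytest.fixture(scope="session")
def small_sim_table(small_config):
    """Ten simulated fragments under the full default scenario."""
    return sim_to_site_table(simulate(small_config, seed=1234), small_config)
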
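import numpy as np
import pandas as pd
import pytest

import crosscna as c


@pytest.fixture
def small_genome():
    return c.uniform_genome(3, 50_000_000)


@pytest.fixture
def probe_map(small_genome):
    return c.build_probe_map(small_genome, 60, seed=11)


@pytest.fixture
def fast_params():
    """Coarse grid keeps unit tests quick; kernel width stays at 20 Mb."""
    return c.KSEParams(grid_step=1_000_000)


@pytest.fixture
def noisy_cohort(probe_map):
    spec = c.GroupSpec(
        "tumors", 8, 0.2,
        cnas=(c.CNASpec("1", 10_000_000, 35_000_000, "gain", 0.6, 0.8, 0.1),
              c.CNASpec("2", 5_000_000, 25_000_000, "loss", 0.5, -0.7, 0.1)),
    )
    return c.simulate_group(probe_map, spec, seed=7)


def random_cohort(rng, n_probes=15, n_samples=4, n_chroms=2, chrom_len=40_000_000):
    """Small random dataset for oracle-equivalence checks."""
    genome = c.uniform_genome(n_chroms, chrom_len)
    pm = c.build_probe_map(genome, n_probes, seed=int(rng.integers(2**31)))
    values = rng.normal(0, 0.5, size=(n_samples, n_probes))
    ids = pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id")
    samples = pd.DataFrame({"group": "g", "tumor_type": "unknown"}, index=ids)
    frame = pd.DataFrame(values, index=ids, columns=pm.table["probe_id"])
    return c.ACGHGroup(pm, frame, samples)
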
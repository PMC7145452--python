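"""Shared fixtures: one small synthetic bundle reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from amynet.config import SimConfig
from amynet import simulate as sim
from amynet.datatypes import GwasSummary


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced genome for fast unit tests (study design otherwise intact)."""
    return SimConfig(seed=42, n_genes=400, n_module_genes=60,
                     n_direct_responders=6, n_early_transient=6,
                     ld_block_sizes=(1, 2, 4, 6, 8, 10))


@pytest.fixture(scope="session")
def small_expression(small_config):
    return sim.simulate_expression(small_config)


@pytest.fixture(scope="session")
def small_genetics(small_config):
    mapping = sim.generate_orthologue_map(small_config)
    annotation = sim.build_annotation(sorted(set(mapping.values())),
                                      small_config)
    panel, gwas, truth = sim.simulate_panel_and_gwas(small_config, annotation)
    truth.orthologue_map = mapping
    return annotation, panel, gwas, truth


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = sim.write_fixture_bundle(outdir, small_config)
    return paths


def gwas_from_z(z, bp=None, chrom="1", n=50000):
    """Minimal GWAS table from a z-score vector."""
    from scipy import stats

    z = np.asarray(z, dtype=float)
    k = z.size
    freq = np.full(k, 0.3)
    se = 1.0 / np.sqrt(2 * freq * (1 - freq) * n)
    table = pd.DataFrame(
        {"snp": [f"rs{i}" for i in range(k)], "chr": chrom,
         "bp": bp if bp is not None else np.arange(1, k + 1) * 1000,
         "a1": "A", "a2": "G", "beta": z * se, "se": se,
         "p": np.maximum(2 * stats.norm.sf(np.abs(z)), 1e-300), "freq": freq}
    )
    return GwasSummary(table)
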
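"""Shared fixtures: small toy datasets and the standard synthetic panel."""

import numpy as np
import pandas as pd
import pytest

from pvpopgen.config import Config
from pvpopgen.dataset import VariantDataset
from pvpopgen.simulate import SimulationParams, simulate_dataset


def make_dataset(depth, alt_fraction, alt2_fraction=None, samples=None, loci=None):
    """Build a VariantDataset from raw matrices with minimal metadata."""
    depth = np.asarray(depth, dtype=int)
    frac = np.asarray(alt_fraction, dtype=float)
    frac = np.where(depth == 0, np.nan, frac)
    n, m = depth.shape
    if alt2_fraction is None:
        alt2_fraction = np.full((n, m), np.nan)
    if samples is None:
        samples = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "accession_id": [f"ACC{i // 2}" for i in range(n)],
            "ecotype": ["upland" if i % 2 == 0 else "lowland" for i in range(n)],
            "ploidy": ["4x"] * n,
            "latitude": np.linspace(30, 45, n),
            "longitude": np.linspace(-100, -80, n),
        }).set_index("sample_id")
    if loci is None:
        loci = pd.DataFrame({
            "contig": ["c1"] * m,
            "position": (np.arange(m) + 1) * 10,
            "ref": ["A"] * m,
            "alt1": ["G"] * m,
            "alt2": [None] * m,
            "gene": ["g1"] * m,
            "chromosome": ["Chr1K"] * m,
            "subgenome": ["K"] * m,
            "region": ["intergenic"] * m,
            "frame": [None] * m,
            "strand": ["+"] * m,
            "outgroup": [None] * m,
            "is_indel": [False] * m,
        })
    return VariantDataset(samples=samples, loci=loci, depth=depth,
                          alt_fraction=frac,
                          alt2_fraction=np.asarray(alt2_fraction, dtype=float))


@pytest.fixture(scope="session")
def standard_sim():
    """The standard planted fixture: 3 subpopulations, F=0.2, 36 accessions,
    360 samples, ~250 SNPs."""
    return simulate_dataset(SimulationParams(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A small panel for fast structural tests."""
    params = SimulationParams(n_accessions=12, samples_per_accession=5,
                              n_genes=6, homoeolog_pairs=4,
                              snps_per_contig=10, contig_length=1200, seed=5)
    return simulate_dataset(params)


@pytest.fixture
def config():
    return Config()
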
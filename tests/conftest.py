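"""Shared fixtures: toy tRNA sets and session-scoped synthetic bundles."""

import numpy as np
import pytest

from codonsel import synthetic_data as sd
from codonsel import (
    build_isoacceptor_map,
    compute_weights,
    default_trna_set,
)
from codonsel.genome_io import TRNAGeneSet


@pytest.fixture(scope="session")
def toy_trnas() -> TRNAGeneSet:
    """The two-anticodon alanine system: I34 (AGC) and C34 (CGC) decoders."""
    return TRNAGeneSet(copies={"AGC": 10, "CGC": 5})


@pytest.fixture(scope="session")
def default_trnas() -> TRNAGeneSet:
    return default_trna_set()


@pytest.fixture(scope="session")
def weights(default_trnas):
    return compute_weights(default_trnas)


@pytest.fixture(scope="session")
def isomap(default_trnas):
    return build_isoacceptor_map(default_trnas)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> sd.FixtureBundle:
    """Mid-size bundle with outgroup divergence and VCF decoy records."""
    config = sd.SimConfig(
        seed=11,
        n_genes=40,
        codons_per_gene=(80, 160),
        n_lines=80,
        d2=0.05,
        d3=0.12,
        n_indels=3,
        n_multiallelic=2,
    )
    return sd.generate_fixture_bundle(config, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def bundle_zero_divergence(tmp_path_factory) -> sd.FixtureBundle:
    """Bundle whose outgroups are identical to the ancestor (d2 = d3 = 0)."""
    config = sd.SimConfig(
        seed=13, n_genes=30, codons_per_gene=(80, 160), n_lines=60, d2=0.0, d3=0.0
    )
    return sd.generate_fixture_bundle(config, tmp_path_factory.mktemp("bundle0"))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
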
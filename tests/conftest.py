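"""Shared fixtures: synthetic input bundles at two scales.

``small_bundle`` is a fast, reduced-scale simulation for unit and
integration tests; ``default_bundle`` carries the full default study
conditions and backs the end-to-end recovery and calibration checks.
Both are generated once per session into temporary directories.
"""

import pytest

from regsnp_scout.config import SimulationSpec
from regsnp_scout.synthetic_data import simulate


SMALL_SPEC = dict(
    rng_seed=7,
    n_chroms=2,
    chrom_length_bp=400_000,
    n_genes=24,
    n_otfrs=120,
    n_het_sites=400,
    n_samples=24,
    effect_coverage_enrichment=2.0,
    n_chiapet_loops=10,
    chiapet_noise_pairs=120,
    n_gwas_indexes=20,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_bundle")
    manifest = simulate(SimulationSpec(**SMALL_SPEC), out)
    return out, manifest


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("default_bundle")
    manifest = simulate(SimulationSpec(rng_seed=1), out)
    return out, manifest
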
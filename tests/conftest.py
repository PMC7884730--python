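import numpy as np
import pytest

from hervscape.synthetic import (SimConfig, simulate_bundle,
                                 simulate_immune_profiles, write_bundle)


@pytest.fixture(scope="session")
def profiles():
    """Purified-cell + background-tissue profiles with planted markers."""
    rng = np.random.default_rng(5)
    purified, background, markers = simulate_immune_profiles(
        SimConfig(seed=5), rng)
    return purified, background, markers


@pytest.fixture(scope="session")
def signatures(profiles):
    from hervscape import friction

    purified, background, _ = profiles
    gene_sets = friction.select_signature_genes(purified, background)
    return friction.normalize_signatures(purified, gene_sets)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=1, n_samples=24, n_herv=80,
                     n_background_genes=600, n_msi_sites=40,
                     mut_per_mb_msih=8.0)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return simulate_bundle(small_cfg)


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(small_bundle, out)
    return out
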
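import numpy as np
import pytest

from tmtproc import chem, deconv, simgen


@pytest.fixture(scope="session")
def tags():
    return chem.default_tags()


@pytest.fixture(scope="session")
def identity_tags():
    return chem.identity_tags()


@pytest.fixture(scope="session")
def channels(tags):
    return chem.build_channel_model(tags)


@pytest.fixture(scope="session")
def noiseless_sample():
    """Small noiseless, interference-free two-proteome sample."""
    config = simgen.SimConfig(
        n_yeast_peptides=12, n_human_peptides=6, poisson=False,
        coisolation_prob=0.0, seed=11,
    )
    return simgen.simulate_interference_sample(config)


@pytest.fixture(scope="session")
def noiseless_quant(noiseless_sample):
    s = noiseless_sample
    return deconv.quantify_run(
        {sp.scan_id: sp for sp in s.spectra}, s.psms, s.tags, s.channels
    )


def well_conditioned_system(rng, n_rows=12, n_channels=9):
    """Random strictly diagonally-banded design with non-negative entries."""
    a = np.zeros((n_rows, n_channels))
    for c in range(n_channels):
        a[c, c] = rng.uniform(0.7, 0.85)
        a[c + 1, c] = rng.uniform(0.02, 0.1)
        if c + 2 < n_rows:
            a[c + 2, c] = rng.uniform(0.0, 0.04)
    return a
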
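import numpy as np
import pandas as pd
import pytest

from nestkin.genodata import GenotypeMatrix
from nestkin.synthgen import SimConfig, simulate_study


def make_matrix(dosages, sample_ids=None, quals=None) -> GenotypeMatrix:
    """GenotypeMatrix from a (sites x samples) array of dosages/NaN."""
    dosages = np.asarray(dosages, dtype=float)
    n_sites, n_samples = dosages.shape
    if sample_ids is None:
        sample_ids = [f"S{j}" for j in range(n_samples)]
    sites = pd.DataFrame({
        "chrom": "1",
        "pos": (np.arange(n_sites) + 1) * 10,
        "ref": "A", "alt": "G",
        "qual": 60.0 if quals is None else quals,
    })
    return GenotypeMatrix(list(sample_ids), sites, dosages)


def random_matrix(rng, n_sites=50, n_samples=10, missing=0.05):
    p = rng.uniform(0.05, 0.95, size=n_sites)
    X = rng.binomial(2, p[:, None], size=(n_sites, n_samples)).astype(float)
    if missing:
        X[rng.random(X.shape) < missing] = np.nan
    return make_matrix(X)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale synthetic study shared across tests."""
    return simulate_study(SimConfig(seed=101))


@pytest.fixture(scope="session")
def default_freqs():
    from nestkin.synthgen import draw_reference_freqs

    return draw_reference_freqs(SimConfig(seed=101))
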
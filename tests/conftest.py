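import numpy as np
import pytest

from ganwgcna import synth
from ganwgcna.gan import MLP, GeneratorCheckpoint


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study: 300 genes, 5 planted modules, 12+12 samples."""
    return synth.make_synthetic(seed=7)


def make_linear_generator(n_genes=8, latent_dim=2, seed=0, orthonormal=False):
    """A generator that is exactly linear in its latent input."""
    net = MLP([latent_dim, n_genes], activation="identity", rng=seed)
    if orthonormal:
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(n_genes, latent_dim)))
        net.W[0][:] = q
        net.b[0][:] = 0.0
    return GeneratorCheckpoint(
        net=net,
        step=0,
        gene_ids=[f"G{i}" for i in range(n_genes)],
        mu=np.zeros(n_genes),
        sd=np.ones(n_genes),
    )


def make_random_generator(n_genes=12, latent_dim=3, hidden=(16,), seed=0):
    """An untrained nonlinear generator (leaky-ReLU MLP)."""
    net = MLP([latent_dim, *hidden, n_genes], activation="leaky_relu", rng=seed)
    return GeneratorCheckpoint(
        net=net,
        step=0,
        gene_ids=[f"G{i}" for i in range(n_genes)],
        mu=np.zeros(n_genes),
        sd=np.ones(n_genes),
    )
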
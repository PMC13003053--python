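import numpy as np
import pytest

from allodyn import SyntheticSpec, Trajectory
from allodyn.synthetic import build_covariance, build_reference, sample_trajectory


@pytest.fixture(scope="session")
def block_spec():
    """Two coupled domains, three replicas — the standard small ensemble."""
    return SyntheticSpec(
        n_residues=20,
        n_frames=200,
        domain_blocks=(("head", 0, 10), ("leg", 10, 20)),
        intra_block_corr=0.6,
        inter_block_corr=0.1,
        noise_sd=0.1,
        pull_group=(0, 1, 2),
        ref_group=(17, 18, 19),
        seed=42,
    )


@pytest.fixture(scope="session")
def block_ensemble(block_spec):
    reference = build_reference(block_spec)
    corr = build_covariance(block_spec)
    trajs = [
        sample_trajectory(block_spec, reference, corr, r)
        for r in range(block_spec.n_replicas)
    ]
    return reference, corr, trajs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trajectory(coords, dt=0.1, **kwargs):
    """Trajectory from a raw (frames, residues, 3) array with default labels."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return Trajectory(
        coords=coords,
        times=dt * np.arange(coords.shape[0]),
        resids=np.arange(1, n + 1),
        chain_ids=np.full(n, "A"),
        **kwargs,
    )


def random_trajectory(rng, n_frames=30, n_residues=8, scale=0.1):
    """Linear chain plus Gaussian jitter; generic non-degenerate input."""
    base = np.zeros((n_residues, 3))
    base[:, 0] = 0.38 * np.arange(n_residues)
    coords = base[None] + scale * rng.standard_normal((n_frames, n_residues, 3))
    return make_trajectory(coords)
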
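import numpy as np
import pytest

import coatlattice as cl


@pytest.fixture(scope="session")
def noise_free():
    """Noise-free preset tube (10 turns, seed 1) with its ground truth."""
    config = cl.preset(n_turns=10.0, rng_seed=1)
    table, truth = cl.simulate_lattice(config)
    return config, table, truth


@pytest.fixture(scope="session")
def noise_free_report(noise_free):
    _, table, _ = noise_free
    return cl.estimate_helical_params(table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation_matrices(n, seed):
    """Uniform random rotations via normalized quaternions (independent of
    the package's Euler plumbing)."""
    g = np.random.default_rng(seed)
    q = g.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y**2 + z**2)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x**2 + z**2)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x**2 + y**2)
    return R


def axis_angle_matrix(axis, angle_rad):
    """Rodrigues rotation — the independent axis-angle oracle."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def geodesic_angle(R1, R2):
    """Rotation angle between two rotations.

    Uses ||R1 - R2||_F = 2*sqrt(2)*sin(angle/2), which stays accurate for
    tiny angles where the arccos-of-trace form hits its ~1e-8 noise floor.
    """
    frob = np.linalg.norm(R1 - R2)
    return float(2.0 * np.arcsin(min(1.0, frob / (2.0 * np.sqrt(2.0)))))
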
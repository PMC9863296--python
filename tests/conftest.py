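import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_modes():
    """Small orthonormal normal-mode set for Wigner tests."""
    from tirspec.wigner import NormalModeSet

    gen = np.random.default_rng(7)
    raw = gen.standard_normal((12, 4))
    q, _ = np.linalg.qr(raw)
    return NormalModeSet(
        masses=np.array([12.0, 16.0, 14.0, 1.0]),
        frequencies=np.array([500.0, 1700.0, 1841.0, 3400.0]),
        modes=q.T[:4],
    )


@pytest.fixture()
def three_atom_traj():
    """Two-frame, three-atom trajectory with state metadata."""
    from tirspec.io import AtomFrame, Trajectory

    frames = [
        AtomFrame(["O", "C", "O"], np.array([[0.0, 0, 0], [1.2, 0, 0], [2.4, 0, 0]]), time=0.0),
        AtomFrame(["O", "C", "O"], np.array([[0.0, 0, 0.1], [1.2, 0, 0], [2.4, 0, 0]]), time=1.0),
    ]
    return Trajectory(frames, dt=1.0, state_series=[2, 1], id="toy")
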
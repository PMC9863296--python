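"""Internal-coordinate geometry kernels and circular ensemble statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tirspec.coords import (
    CoordinateSpec,
    GeometryError,
    antisym_stretch,
    bend_angle,
    deviation_from_plane,
    dihedral,
    ensemble_track_stats,
    fold_angle,
    track,
)
from tirspec.io import AtomFrame, Ensemble, Trajectory


def _quartet(rng):
    """Random non-degenerate 4-atom geometry."""
    while True:
        c = rng.uniform(-3, 3, size=(4, 3))
        b1, b2, b3 = np.diff(c, axis=0)
        if (
            np.linalg.norm(np.cross(b1, b2)) > 1e-2
            and np.linalg.norm(np.cross(b2, b3)) > 1e-2
        ):
            return c


def _oracle_dihedral(c):
    """Independent construction: angle between plane normals, signed by the
    orientation of n1×n2 against the central bond."""
    b1, b2, b3 = np.diff(c, axis=0)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


def test_planar_anti_and_syn_arrangements():
    anti = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], dtype=float)
    syn = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
    assert dihedral(anti, 0, 1, 2, 3) == pytest.approx(180.0)
    assert dihedral(syn, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-10)


def test_dihedral_against_plane_normal_oracle(rng):
    for _ in range(100):
        c = _quartet(rng)
        got = dihedral(c, 0, 1, 2, 3)
        want = _oracle_dihedral(c)
        # compare circularly to be safe at the ±180° branch
        assert abs(fold_angle(got - want)) < 1e-8


def test_dihedral_rigid_motion_invariance(rng):
    from scipy.spatial.transform import Rotation

    for _ in range(25):
        c = _quartet(rng)
        ref = dihedral(c, 0, 1, 2, 3)
        R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 31)))).as_matrix()
        moved = c @ R.T + rng.uniform(-5, 5, size=3)
        assert abs(fold_angle(dihedral(moved, 0, 1, 2, 3) - ref)) < 1e-8


def test_dihedral_reversal_and_mirror_symmetries(rng):
    """Reading the chain backwards leaves the signed dihedral unchanged
    (the sighting direction and the outer-atom order flip together);
    mirror reflection flips its sign."""
    for _ in range(25):
        c = _quartet(rng)
        d1 = dihedral(c, 0, 1, 2, 3)
        assert abs(fold_angle(dihedral(c, 3, 2, 1, 0) - d1)) < 1e-8
        mirrored = c * np.array([1.0, 1.0, -1.0])
        assert abs(fold_angle(dihedral(mirrored, 0, 1, 2, 3) + d1)) < 1e-8 or abs(abs(d1) - 180.0) < 1e-8


def test_dihedral_collinear_raises():
    c = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
    with pytest.raises(GeometryError):
        dihedral(c, 0, 1, 2, 3)


def test_bend_angle_special_cases():
    collinear = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    right = np.array([[1, 0, 0], [0, 0, 0], [0, 1, 0]], dtype=float)
    assert bend_angle(collinear, 0, 1, 2) == pytest.approx(180.0)
    assert bend_angle(right, 0, 1, 2) == pytest.approx(90.0)
    with pytest.raises(GeometryError):
        bend_angle(np.zeros((3, 3)), 0, 1, 2)


def test_bend_angle_law_of_cosines_oracle(rng):
    for _ in range(100):
        c = rng.uniform(-2, 2, size=(3, 3))
        a = np.linalg.norm(c[0] - c[1])
        b = np.linalg.norm(c[2] - c[1])
        o = np.linalg.norm(c[0] - c[2])
        if a < 1e-2 or b < 1e-2:
            continue
        want = np.degrees(np.arccos(np.clip((a**2 + b**2 - o**2) / (2 * a * b), -1, 1)))
        assert bend_angle(c, 0, 1, 2) == pytest.approx(want, abs=1e-8)


def test_antisym_stretch_arithmetic():
    c = np.array([[0, 0, 0], [1.25, 0, 0], [5, 0, 0], [6.15, 0, 0]], dtype=float)
    assert antisym_stretch(c, (0, 1), (2, 3)) == pytest.approx(0.05)
    assert antisym_stretch(c, (2, 3), (0, 1)) == pytest.approx(-0.05)
    sym = np.array([[0, 0, 0], [1.2, 0, 0], [5, 0, 0], [6.2, 0, 0]], dtype=float)
    assert antisym_stretch(sym, (0, 1), (2, 3)) == pytest.approx(0.0)


@pytest.mark.parametrize(
    "d,expected", [(115.0, 65.0), (245.0, 65.0), (180.0, 0.0), (-115.0, 65.0), (0.0, 180.0)]
)
def test_deviation_from_plane_worked_examples(d, expected):
    assert deviation_from_plane(d) == pytest.approx(expected)


@given(st.floats(min_value=-720, max_value=720, allow_nan=False))
def test_deviation_from_plane_is_even(d):
    assert deviation_from_plane(d) == pytest.approx(deviation_from_plane(-d), abs=1e-9)
    assert 0.0 <= deviation_from_plane(d) <= 180.0


def _dihedral_traj(value_deg, n_frames=3, traj_id="t"):
    """Planar 4-atom chain twisted to the requested dihedral."""
    frames = []
    phi = np.radians(value_deg)
    for k in range(n_frames):
        c = np.array(
            [
                [0.0, 1.0, 0.0],
                [0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0],
                [1.0 + 0.0, np.cos(phi), np.sin(phi)],
            ]
        )
        frames.append(AtomFrame(["N", "C", "N", "N"], c, time=float(k)))
    return Trajectory(frames, dt=1.0, id=traj_id)


def test_track_constant_geometry_zero_sigma():
    spec = CoordinateSpec("d", "dihedral", (0, 1, 2, 3))
    ens = Ensemble([_dihedral_traj(115.0, traj_id="a"), _dihedral_traj(115.0, traj_id="b")])
    _, mean, std = ensemble_track_stats(ens, spec)
    assert np.allclose(np.abs(fold_angle(mean)), 115.0, atol=1e-6)
    assert np.allclose(std, 0.0, atol=1e-6)


def test_branch_straddling_dihedrals_average_circularly():
    spec = CoordinateSpec("d", "dihedral", (0, 1, 2, 3))
    ens = Ensemble([_dihedral_traj(170.0, traj_id="a"), _dihedral_traj(-170.0, traj_id="b")])
    _, mean, _ = ensemble_track_stats(ens, spec)
    assert np.allclose(np.abs(fold_angle(mean)), 180.0, atol=1e-6)


def test_track_values_match_per_frame_evaluation(three_atom_traj):
    spec = CoordinateSpec("a", "angle", (0, 1, 2))
    tr = track(three_atom_traj, spec)
    assert len(tr.values) == three_atom_traj.n_frames
    assert tr.values[0] == pytest.approx(bend_angle(three_atom_traj.frames[0].coords, 0, 1, 2))


def test_spec_validation():
    with pytest.raises(ValueError):
        CoordinateSpec("x", "dihedral", (0, 1, 2))
    with pytest.raises(ValueError):
        CoordinateSpec("x", "angle", (0, 1, 1))
    with pytest.raises(ValueError):
        CoordinateSpec("x", "unknown", (0, 1))
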
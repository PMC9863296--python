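"""Internal coordinates that fingerprint the photoswitching mechanism.

For the azodicarboxamide-type N=N switch the relevant coordinates are the two
amide-side dihedrals (alpha, beta) and the central C-N=N-C dihedral (gamma):
a concerted alpha/beta torsion at planar gamma is the volume-conserving
pedalo-type motion, while a gamma twist marks trans-cis isomerization.
The two C=O distances and their anti-symmetric combination
(CO1 - CO2)/2 serve as the IR-active spectator coordinate.

All geometry kernels are vectorized over leading axes, so a whole trajectory
evaluates in one call. Dihedrals are signed, in (-180, 180], right-hand
(IUPAC) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import circmean, circstd

__all__ = [
    "CoordinateSpec",
    "CoordinateTrack",
    "GeometryError",
    "dihedral",
    "bend_angle",
    "bond_length",
    "antisym_stretch",
    "deviation_from_plane",
    "fold_angle",
    "track",
    "ensemble_track_stats",
    "unwrap_degrees",
]

_KIND_NATOMS = {"dihedral": 4, "angle": 3, "bond": 2, "antisym_pair": 4}
_ANGULAR_KINDS = ("dihedral", "angle")
_DEGENERACY_TOL = 1e-10


class GeometryError(ValueError):
    """Degenerate geometry (collinear atoms, zero-length bond vector)."""


@dataclass(frozen=True)
class CoordinateSpec:
    """A named internal coordinate defined by 0-based atom indices.

    For ``kind='antisym_pair'`` the four indices are read as two bond pairs
    ``(i1, j1, i2, j2)`` and the coordinate is (d(i1,j1) - d(i2,j2)) / 2.
    """

    name: str
    kind: str  # dihedral | angle | bond | antisym_pair
    atom_indices: tuple

    def __post_init__(self):
        if self.kind not in _KIND_NATOMS:
            raise ValueError(f"unknown coordinate kind '{self.kind}'")
        idx = tuple(int(i) for i in self.atom_indices)
        object.__setattr__(self, "atom_indices", idx)
        if len(idx) != _KIND_NATOMS[self.kind]:
            raise ValueError(
                f"{self.kind} needs {_KIND_NATOMS[self.kind]} atom indices, got {len(idx)}"
            )
        if self.kind != "antisym_pair" and len(set(idx)) != len(idx):
            raise ValueError("atom indices must be distinct")
        if any(i < 0 for i in idx):
            raise ValueError("atom indices must be non-negative")

    @property
    def is_angular(self) -> bool:
        return self.kind in _ANGULAR_KINDS

    @property
    def unit(self) -> str:
        return "deg" if self.is_angular else "angstrom"


@dataclass
class CoordinateTrack:
    """Time series of one internal coordinate along one trajectory."""

    spec: CoordinateSpec
    times: np.ndarray  # fs
    values: np.ndarray  # deg or Å
    trajectory_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def _norm(v, axis=-1, keepdims=True):
    return np.linalg.norm(v, axis=axis, keepdims=keepdims)


def dihedral(coords, i, j, k, l) -> np.ndarray | float:
    """Signed dihedral i-j-k-l in degrees, in (-180, 180].

    Computed with the atan2 construction on the two plane normals; the sign
    follows the right-hand convention (positive = clockwise rotation of l
    relative to i when sighting from j to k).
    """
    coords = np.asarray(coords, dtype=float)
    b1 = coords[..., j, :] - coords[..., i, :]
    b2 = coords[..., k, :] - coords[..., j, :]
    b3 = coords[..., l, :] - coords[..., k, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(_norm(n1) < _DEGENERACY_TOL) or np.any(_norm(n2) < _DEGENERACY_TOL):
        raise GeometryError("collinear atoms: dihedral undefined")
    b2n = b2 / _norm(b2)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # canonical branch (-180, 180]
    ang = np.where(ang <= -180.0 + 1e-12, ang + 360.0, ang)
    return float(ang) if np.ndim(ang) == 0 else ang


def bend_angle(coords, i, j, k) -> np.ndarray | float:
    """Bond angle i-j-k in degrees, in [0, 180]."""
    coords = np.asarray(coords, dtype=float)
    v1 = coords[..., i, :] - coords[..., j, :]
    v2 = coords[..., k, :] - coords[..., j, :]
    n1, n2 = _norm(v1), _norm(v2)
    if np.any(n1 < _DEGENERACY_TOL) or np.any(n2 < _DEGENERACY_TOL):
        raise GeometryError("zero-length bond vector: angle undefined")
    cosang = np.clip(np.sum((v1 / n1) * (v2 / n2), axis=-1), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return float(ang) if np.ndim(ang) == 0 else ang


def bond_length(coords, i, j) -> np.ndarray | float:
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords[..., i, :] - coords[..., j, :], axis=-1)
    return float(d) if np.ndim(d) == 0 else d


def antisym_stretch(coords, pair1, pair2) -> np.ndarray | float:
    """Anti-symmetric combination (d(pair1) - d(pair2)) / 2 in Å.

    For the two C=O bonds this is the IR-active spectator coordinate; a
    symmetric stretch leaves it unchanged and it flips sign when the pairs
    are swapped.
    """
    d1 = bond_length(coords, *pair1)
    d2 = bond_length(coords, *pair2)
    return (d1 - d2) / 2.0


def fold_angle(d) -> np.ndarray | float:
    """Fold any angle in degrees onto the canonical branch (-180, 180]."""
    d = np.asarray(d, dtype=float)
    out = ((d - 180.0) % -360.0) + 180.0
    out = np.where(out <= -180.0, out + 360.0, out)
    return float(out) if out.ndim == 0 else out


def deviation_from_plane(d) -> np.ndarray | float:
    """Absolute deviation of a dihedral from planarity, in [0, 180] degrees.

    115° and 245° both map to 65°: a dihedral and its 360° complement are
    the same distortion on opposite sides of the plane.
    """
    out = 180.0 - np.abs(fold_angle(d))
    return float(out) if np.ndim(out) == 0 else out


def unwrap_degrees(values) -> np.ndarray:
    """Remove 360° jumps from a dihedral time series (circular unwrap)."""
    return np.degrees(np.unwrap(np.radians(np.asarray(values, dtype=float))))


def evaluate(coords, spec: CoordinateSpec):
    """Evaluate a coordinate spec on coordinates of shape (..., n_atoms, 3)."""
    idx = spec.atom_indices
    n_atoms = np.asarray(coords).shape[-2]
    if any(i >= n_atoms for i in idx):
        raise ValueError(f"spec '{spec.name}' indexes beyond {n_atoms} atoms")
    if spec.kind == "dihedral":
        return dihedral(coords, *idx)
    if spec.kind == "angle":
        return bend_angle(coords, *idx)
    if spec.kind == "bond":
        return bond_length(coords, *idx)
    return antisym_stretch(coords, idx[:2], idx[2:])


def track(traj, spec: CoordinateSpec) -> CoordinateTrack:
    """Evaluate one coordinate on every frame of a trajectory."""
    try:
        values = evaluate(traj.coords, spec)
    except GeometryError as exc:
        raise GeometryError(f"trajectory '{traj.id}', coordinate '{spec.name}': {exc}") from exc
    return CoordinateTrack(spec, traj.times, np.atleast_1d(values), trajectory_id=traj.id)


def ensemble_track_stats(ensemble, spec: CoordinateSpec):
    """Framewise ensemble mean and standard deviation of one coordinate.

    Dihedrals are treated circularly: the framewise mean/σ across
    trajectories use circular statistics (two members at 170° and -170°
    average to 180°, not 0°), and the returned mean series is unwrapped in
    time so that branch crossings do not produce 360° jumps.

    Returns ``(times, mean, std)``.
    """
    tracks = [track(tr, spec) for tr in ensemble]
    n = min(len(t.values) for t in tracks)
    times = tracks[0].times[:n]
    vals = np.stack([t.values[:n] for t in tracks])  # (n_traj, n_frames)
    if spec.kind == "dihedral":
        mean = np.degrees(circmean(np.radians(vals), axis=0))
        std = np.degrees(circstd(np.radians(vals), axis=0))
        mean = unwrap_degrees(fold_angle(mean))
    else:
        mean = vals.mean(axis=0)
        std = vals.std(axis=0)
    return times, mean, std
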
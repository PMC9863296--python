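"""Trajectory/state-log/manifest/spectrum I/O and the shared data model.

The on-disk formats are deliberately plain text so that output of any
surface-hopping engine can be converted trivially:

* multi-frame XYZ (atom-count line, comment line, atom records) for geometries,
  with optional ``time=`` / ``state=`` tags on the comment line;
* a delimited state log (``time,state,E0,E1,...``) carrying the active
  electronic state and, optionally, the adiabatic state energies per frame;
* a JSON ensemble manifest listing trajectory/log paths and the time step;
* spectra as two-column CSV with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AtomFrame",
    "Trajectory",
    "Ensemble",
    "Spectrum1D",
    "FormatError",
    "AlignmentError",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_state_log",
    "write_state_log",
    "read_ensemble_manifest",
    "write_ensemble_manifest",
    "read_spectrum",
    "write_spectrum",
]


class FormatError(ValueError):
    """Malformed input file."""


class AlignmentError(ValueError):
    """Companion data does not line up with the trajectory time grid."""


_TIME_TOL_FS = 1e-9


@dataclass
class AtomFrame:
    """One geometry snapshot: element symbols plus Cartesian coordinates in Å."""

    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å
    time: float = 0.0  # fs

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise FormatError("coords must be an (n_atoms, 3) array")
        if len(self.elements) != self.coords.shape[0]:
            raise FormatError("element count does not match coordinate count")
        if self.time < 0:
            raise ValueError("frame time must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class Trajectory:
    """A uniformly sampled trajectory with per-frame electronic-state metadata.

    ``state_series`` holds the active electronic state index per frame
    (0 = ground state); ``energies`` optionally holds the adiabatic state
    energies in eV, one row per frame, one column per state.
    """

    frames: list[AtomFrame]
    dt: float  # fs
    state_series: np.ndarray | None = None
    energies: np.ndarray | None = None  # (n_frames, n_states), eV
    id: str = ""

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        times = np.array([f.time for f in self.frames])
        expected = times[0] + self.dt * np.arange(len(times))
        if np.any(np.abs(times - expected) > _TIME_TOL_FS):
            raise ValueError("frames are not uniformly spaced at dt")
        n0 = self.frames[0].n_atoms
        if any(f.n_atoms != n0 for f in self.frames):
            raise FormatError("inconsistent atom counts across frames")
        if self.state_series is not None:
            self.state_series = np.asarray(self.state_series, dtype=int)
            if len(self.state_series) != len(self.frames):
                raise AlignmentError("state series length does not match frame count")
            if np.any(self.state_series < 0):
                raise ValueError("state indices must be non-negative")
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
            if self.energies.ndim != 2 or self.energies.shape[0] != len(self.frames):
                raise AlignmentError("energies must provide one row of state energies per frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def coords(self) -> np.ndarray:
        """All coordinates stacked as an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coords for f in self.frames])

    @property
    def elements(self) -> list[str]:
        return self.frames[0].elements


@dataclass
class Ensemble:
    """A swarm of trajectories sharing dt and atom ordering.

    ``role`` distinguishes the photoexcited swarm from the ground-state
    reference swarm used for the steady spectrum.
    """

    trajectories: list[Trajectory]
    role: str = "excited"  # "excited" | "reference"

    def __post_init__(self):
        if not self.trajectories:
            raise ValueError("ensemble must be non-empty")
        dt0 = self.trajectories[0].dt
        el0 = self.trajectories[0].elements
        for tr in self.trajectories:
            if abs(tr.dt - dt0) > _TIME_TOL_FS:
                raise ValueError("all ensemble members must share dt")
            if tr.elements != el0:
                raise ValueError("all ensemble members must share atom ordering")
        if self.role not in ("excited", "reference"):
            raise ValueError("role must be 'excited' or 'reference'")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


@dataclass
class Spectrum1D:
    """Intensity versus a frequency/energy axis, with unit metadata."""

    axis: np.ndarray
    intensity: np.ndarray
    axis_unit: str = "cm-1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape:
            raise ValueError("axis and intensity must have the same shape")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")


_TAG_RE = re.compile(r"(\w+)\s*=\s*([-+0-9.eE]+)")


def _parse_comment_tags(comment: str) -> dict:
    return {m.group(1): float(m.group(2)) for m in _TAG_RE.finditer(comment)}


def read_xyz_trajectory(path, dt: float = 1.0) -> Trajectory:
    """Read a multi-frame XYZ file into a Trajectory.

    The comment line of each frame may carry ``time=<fs>`` and
    ``state=<index>`` tags; times found there are checked against the uniform
    grid implied by ``dt``, and states are collected into ``state_series``
    (a separate state log, when present, takes precedence).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[AtomFrame] = []
    states: list[int] = []
    any_state = False
    i = 0
    n_expected = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {i + 1}") from exc
        if n_expected is None:
            n_expected = n_atoms
        elif n_atoms != n_expected:
            raise FormatError(
                f"{path}: frame {len(frames)} declares {n_atoms} atoms, previous frames had {n_expected}"
            )
        if i + 1 + n_atoms >= len(lines) + 1:
            raise FormatError(f"{path}: truncated frame at line {i + 1}")
        tags = _parse_comment_tags(lines[i + 1])
        elements, coords = [], []
        for rec in lines[i + 2 : i + 2 + n_atoms]:
            parts = rec.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: malformed atom record '{rec}'")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric coordinate in '{rec}'") from exc
            elements.append(parts[0])
            coords.append(xyz)
        t = tags.get("time", len(frames) * dt)
        frames.append(AtomFrame(elements, np.array(coords), time=t))
        if "state" in tags:
            any_state = True
            states.append(int(tags["state"]))
        else:
            states.append(0)
        i += 2 + n_atoms
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return Trajectory(
        frames,
        dt=dt,
        state_series=np.array(states) if any_state else None,
        id=path.stem,
    )


def write_xyz_trajectory(path, traj: Trajectory) -> None:
    """Write a Trajectory as multi-frame XYZ with time/state comment tags."""
    path = Path(path)
    out = []
    for k, frame in enumerate(traj.frames):
        out.append(str(frame.n_atoms))
        tags = f"time={frame.time:.6f}"
        if traj.state_series is not None:
            tags += f" state={int(traj.state_series[k])}"
        out.append(tags)
        for el, (x, y, z) in zip(frame.elements, frame.coords):
            out.append(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    path.write_text("\n".join(out) + "\n")


def read_state_log(path, trajectory: Trajectory | None = None):
    """Read a state log (columns ``time,state,E0,E1,...``).

    Returns ``(state_series, energies)`` with ``energies`` None when no
    energy columns are present. If ``trajectory`` is given, the log's time
    grid is checked against the trajectory frames.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip() for c in df.columns]
    if "time" not in df.columns or "state" not in df.columns:
        raise FormatError(f"{path}: state log must have 'time' and 'state' columns")
    times = df["time"].to_numpy(dtype=float)
    states = df["state"].to_numpy(dtype=int)
    e_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"E\d+", c)),
        key=lambda c: int(c[1:]),
    )
    energies = df[e_cols].to_numpy(dtype=float) if e_cols else None
    if trajectory is not None:
        traj_times = trajectory.times
        if len(times) != len(traj_times) or np.any(np.abs(times - traj_times) > _TIME_TOL_FS):
            raise AlignmentError(f"{path}: log time grid does not match trajectory frames")
    return states, energies


def write_state_log(path, times, states, energies=None) -> None:
    data = {"time": np.asarray(times, dtype=float), "state": np.asarray(states, dtype=int)}
    if energies is not None:
        energies = np.asarray(energies, dtype=float)
        for k in range(energies.shape[1]):
            data[f"E{k}"] = energies[:, k]
    pd.DataFrame(data).to_csv(path, index=False)


def attach_state_log(traj: Trajectory, path) -> Trajectory:
    """Return a copy of ``traj`` with state/energy data taken from a log file.

    The log is authoritative: it overrides any states parsed from XYZ
    comment tags.
    """
    states, energies = read_state_log(path, trajectory=traj)
    return Trajectory(traj.frames, dt=traj.dt, state_series=states, energies=energies, id=traj.id)


def write_ensemble_manifest(path, entries, dt: float, role: str = "excited") -> None:
    """Write a JSON manifest: ``{"dt": .., "role": .., "trajectories": [{xyz, log?, id?}]}``."""
    payload = {"dt": dt, "role": role, "trajectories": list(entries)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ensemble_manifest(path) -> Ensemble:
    """Load an Ensemble from a JSON manifest of trajectory/log paths."""
    path = Path(path)
    payload = json.loads(path.read_text())
    dt = float(payload["dt"])
    role = payload.get("role", "excited")
    trajs = []
    for entry in payload["trajectories"]:
        xyz = path.parent / entry["xyz"]
        traj = read_xyz_trajectory(xyz, dt=dt)
        if entry.get("id"):
            traj.id = entry["id"]
        if entry.get("log"):
            traj = attach_state_log(traj, path.parent / entry["log"])
        trajs.append(traj)
    return Ensemble(trajs, role=role)


def write_spectrum(path, spectrum: Spectrum1D) -> None:
    """Write a spectrum as ``axis,intensity`` CSV plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"axis": spectrum.axis, "intensity": spectrum.intensity}).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"axis_unit": spectrum.axis_unit, **spectrum.meta}, indent=2) + "\n")


def read_spectrum(path) -> Spectrum1D:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    unit = meta.pop("axis_unit", "cm-1")
    return Spectrum1D(df["axis"].to_numpy(), df["intensity"].to_numpy(), axis_unit=unit, meta=meta)
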
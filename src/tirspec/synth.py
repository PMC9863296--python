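"""Synthetic trajectory ensembles with known ground truth.

Every downstream operation (coordinate tracking, instantaneous-frequency
extraction, lineshape assembly, hop statistics) is testable without a
quantum-chemistry engine by generating ensembles whose anti-symmetric
carbonyl stretch follows a prescribed instantaneous-frequency profile, whose
dihedrals/bends follow prescribed paths, and whose hop times follow
prescribed distributions.

The stretch signal is phase-exact: q(t) = A·sin(φ₀ + φ(t)) with
φ(t) = 2πc ∫₀ᵗ ν̃(t') dt' integrated analytically per profile segment, so any
error in a recovered frequency is attributable to the estimator, never to
the generator. The generator stores ν̃(t) as ground truth next to each
trajectory.

Geometries are built on a minimal eight-atom azodicarboxamide proxy
(N1-C2(=O2)-N3=N4-C5(=O5)-N6) carrying all named mechanism coordinates: the
two C=O bond lengths realize q(t) as r₀ ± q(t), and the α/β/γ dihedrals and
φ/ϕ bends follow per-trajectory linear ramps between jittered targets. The
default recipe emulates the pedalo-type study conditions: 50 trajectories,
2 ps at 1 fs; an instantaneous red shift of the stretch to 1600 cm⁻¹ at
excitation followed by a linear blue shift to 1800 cm⁻¹ over 200 fs; hops
S₂→S₁ near 100 fs and S₁→S₀ near 300 fs; α planarizing 106°→178° at γ held
planar; a ground-state reference oscillating at 1825 cm⁻¹ throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import wavenumber_to_angular_freq
from .coords import CoordinateSpec
from .hopping import DEFAULT_GAP_THRESHOLD_EV
from .io import AtomFrame, Ensemble, Trajectory

__all__ = [
    "ChirpSegment",
    "ChirpProfile",
    "CoordinateTarget",
    "EnsembleRecipe",
    "generate_stretch_series",
    "generate_ensemble",
    "designed_crossing_energies",
    "pedalo_recipe",
    "PROXY_COORDS",
    "save_ground_truth",
]

#: Named coordinates of the eight-atom proxy (atom order N1 C2 O2 N3 N4 C5 O5 N6).
PROXY_COORDS = {
    "alpha": CoordinateSpec("alpha", "dihedral", (0, 1, 3, 4)),
    "beta": CoordinateSpec("beta", "dihedral", (3, 4, 5, 7)),
    "gamma": CoordinateSpec("gamma", "dihedral", (1, 3, 4, 5)),
    "phi_bend": CoordinateSpec("phi_bend", "angle", (1, 3, 4)),
    "psi_bend": CoordinateSpec("psi_bend", "angle", (3, 4, 5)),
    "CO1": CoordinateSpec("CO1", "bond", (1, 2)),
    "CO2": CoordinateSpec("CO2", "bond", (5, 6)),
    "q_antisym": CoordinateSpec("q_antisym", "antisym_pair", (1, 2, 5, 6)),
}

_PROXY_ELEMENTS = ["N", "C", "O", "N", "N", "C", "O", "N"]
_R_NN = 1.25  # Å, N=N
_R_CN = 1.40  # Å, C-N(azo)
_R_CN_AMIDE = 1.35  # Å, C-N(amide)
_R_CO_EQ = 1.20  # Å, C=O equilibrium


@dataclass(frozen=True)
class ChirpSegment:
    t_start: float  # fs
    t_end: float  # fs
    omega_start: float  # cm⁻¹
    omega_end: float  # cm⁻¹
    interpolation: str = "linear"  # "linear" | "hold"

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")
        if self.omega_start <= 0 or self.omega_end <= 0:
            raise ValueError("frequencies must be positive")
        if self.interpolation not in ("linear", "hold"):
            raise ValueError("interpolation must be 'linear' or 'hold'")


@dataclass
class ChirpProfile:
    """Piecewise instantaneous-frequency profile with analytic phase."""

    segments: list[ChirpSegment]
    amplitude: float = 0.05  # Å
    noise_sd: float = 0.0  # Å

    def __post_init__(self):
        if not self.segments:
            raise ValueError("profile needs at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if abs(b.t_start - a.t_end) > 1e-9:
                raise ValueError("segments must be contiguous and time-ordered")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")

    def omega(self, t) -> np.ndarray:
        """Instantaneous frequency ν̃(t) in cm⁻¹ (constant beyond the ends)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        first, last = self.segments[0], self.segments[-1]
        out[t <= first.t_start] = first.omega_start
        last_omega = last.omega_start if last.interpolation == "hold" else last.omega_end
        out[t >= last.t_end] = last_omega
        for seg in self.segments:
            m = (t >= seg.t_start) & (t < seg.t_end)
            if seg.interpolation == "hold":
                out[m] = seg.omega_start
            else:
                frac = (t[m] - seg.t_start) / (seg.t_end - seg.t_start)
                out[m] = seg.omega_start + frac * (seg.omega_end - seg.omega_start)
        return out

    def phase(self, t) -> np.ndarray:
        """Exact accumulated phase φ(t) = 2πc ∫₀ᵗ ν̃ dt' in rad (analytic per segment)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        phase = np.zeros_like(t)
        # phase at segment boundaries
        boundary_phase = 0.0
        t0_first = self.segments[0].t_start
        # before the first segment: constant omega_start
        m = t < t0_first
        phase[m] = wavenumber_to_angular_freq(self.segments[0].omega_start) * (t[m] - t0_first)
        for seg in self.segments:
            w0 = wavenumber_to_angular_freq(seg.omega_start)
            w1 = wavenumber_to_angular_freq(seg.omega_end if seg.interpolation == "linear" else seg.omega_start)
            dur = seg.t_end - seg.t_start
            slope = (w1 - w0) / dur
            m = (t >= seg.t_start) & (t < seg.t_end)
            dt_loc = t[m] - seg.t_start
            phase[m] = boundary_phase + w0 * dt_loc + 0.5 * slope * dt_loc**2
            boundary_phase += w0 * dur + 0.5 * slope * dur**2
        last = self.segments[-1]
        w_last = wavenumber_to_angular_freq(last.omega_start if last.interpolation == "hold" else last.omega_end)
        m = t >= last.t_end
        phase[m] = boundary_phase + w_last * (t[m] - last.t_end)
        return phase

    def shifted(self, d_omega: float) -> "ChirpProfile":
        """Profile rigidly shifted in frequency by d_omega cm⁻¹."""
        segs = [
            replace(s, omega_start=s.omega_start + d_omega, omega_end=s.omega_end + d_omega)
            for s in self.segments
        ]
        return ChirpProfile(segs, amplitude=self.amplitude, noise_sd=self.noise_sd)


def constant_profile(omega_cm1: float, duration: float, amplitude: float = 0.05, noise_sd: float = 0.0) -> ChirpProfile:
    return ChirpProfile(
        [ChirpSegment(0.0, duration, omega_cm1, omega_cm1, "hold")],
        amplitude=amplitude,
        noise_sd=noise_sd,
    )


def generate_stretch_series(profile: ChirpProfile, dt: float, duration: float, phase0: float = 0.0, rng=None):
    """Oscillating stretch coordinate q(t) = A sin(φ₀ + φ(t)) + jitter.

    The jitter is band-limited (white noise smoothed with a ~2 fs Gaussian
    kernel, rescaled to ``noise_sd``): molecular-dynamics coordinates are
    smooth in time, and per-frame white noise would fabricate sub-period
    extrema no real trajectory exhibits. Returns ``(times, q, omega_truth)``
    with the generator's exact ν̃(t) as ground truth.
    """
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    q = profile.amplitude * np.sin(phase0 + profile.phase(times))
    if profile.noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        white = rng.normal(0.0, 1.0, size=len(times))
        k = np.exp(-0.5 * (np.arange(-6, 7) * dt / 2.0) ** 2)
        smooth_noise = np.convolve(white, k / k.sum(), mode="same")
        sd = smooth_noise.std()
        if sd > 0:
            q = q + profile.noise_sd * smooth_noise / sd
    return times, q, profile.omega(times)


@dataclass(frozen=True)
class CoordinateTarget:
    """Per-coordinate linear ramp between per-trajectory jittered endpoints."""

    name: str
    start: float
    end: float
    t_start: float
    t_end: float
    start_sd: float = 0.0
    end_sd: float = 0.0

    def path(self, times: np.ndarray, rng) -> np.ndarray:
        a = self.start + (rng.normal(0.0, self.start_sd) if self.start_sd > 0 else 0.0)
        b = self.end + (rng.normal(0.0, self.end_sd) if self.end_sd > 0 else 0.0)
        if self.t_end <= self.t_start:
            return np.full_like(times, a)
        frac = np.clip((times - self.t_start) / (self.t_end - self.t_start), 0.0, 1.0)
        return a + frac * (b - a)


@dataclass
class EnsembleRecipe:
    """Study conditions for a synthetic ensemble (defaults: pedalo-type run)."""

    n_traj: int = 50
    duration: float = 2000.0  # fs
    dt: float = 1.0  # fs
    initial_state: int = 2
    # per-transition hop-time law: ("fixed", t) | ("exponential", mean) | ("normal", mean, sd)
    hop_schedule: dict = field(
        default_factory=lambda: {(2, 1): ("normal", 100.0, 30.0), (1, 0): ("normal", 300.0, 50.0)}
    )
    excited_profile: ChirpProfile | None = None
    reference_omega: float = 1825.0  # cm⁻¹, GS stretch
    freq_offset_sd: float = 10.0  # cm⁻¹, static per-trajectory inhomogeneity
    coordinate_targets: list[CoordinateTarget] = field(default_factory=list)
    with_energies: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_traj < 1:
            raise ValueError("need at least one trajectory")
        if self.excited_profile is None:
            # instantaneous red shift to 1600 cm⁻¹ at excitation, linear blue
            # shift back to 1800 cm⁻¹ over 200 fs, then steady oscillation
            if self.duration > 200.0:
                segments = [
                    ChirpSegment(0.0, 200.0, 1600.0, 1800.0, "linear"),
                    ChirpSegment(200.0, self.duration, 1800.0, 1800.0, "hold"),
                ]
            else:  # short runs keep the same 1 cm⁻¹/fs chirp rate
                segments = [ChirpSegment(0.0, self.duration, 1600.0, 1600.0 + self.duration, "linear")]
            self.excited_profile = ChirpProfile(segments, amplitude=0.05, noise_sd=0.002)
        if not self.coordinate_targets:
            self.coordinate_targets = _default_pedalo_targets()
        names = {t.name for t in self.coordinate_targets}
        required = {"alpha", "beta", "gamma", "phi_bend", "psi_bend"}
        if not required <= names:
            raise ValueError(f"coordinate targets must cover {sorted(required)}")
        for t in self.coordinate_targets:
            if not (0.0 <= t.t_start <= self.duration and t.t_start <= t.t_end <= self.duration):
                raise ValueError(f"target '{t.name}' times outside the trajectory duration")


def _default_pedalo_targets() -> list[CoordinateTarget]:
    # GS values and planarized endpoints; jitter widths follow the ~10°
    # equilibrium spread of the floppy amide dihedrals vs the stiff γ
    return [
        CoordinateTarget("alpha", 106.4, 178.0, 0.0, 100.0, start_sd=8.0, end_sd=4.0),
        CoordinateTarget("beta", -107.4, -180.0, 0.0, 100.0, start_sd=8.0, end_sd=4.0),
        CoordinateTarget("gamma", 179.9, 179.9, 0.0, 0.0, start_sd=2.0),
        CoordinateTarget("phi_bend", 109.7, 125.2, 0.0, 100.0, start_sd=1.5, end_sd=1.5),
        CoordinateTarget("psi_bend", 109.8, 123.6, 0.0, 100.0, start_sd=1.5, end_sd=1.5),
    ]


def pedalo_recipe(**overrides) -> EnsembleRecipe:
    """The default pedalo-type study recipe, with keyword overrides."""
    return EnsembleRecipe(**overrides)


def _nerf_place(a, b, c, r, theta_deg, phi_deg):
    """Place atom d at distance r from c, angle d-c-b = theta, dihedral
    d-c-b-a = phi. All reference positions broadcast over leading axes."""
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    r = np.asarray(r, dtype=float)
    bc = c - b
    bc_h = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc_h)
    n_h = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n_h, bc_h)
    d_local = (
        (-r * np.cos(theta))[..., None] * bc_h
        + (r * np.sin(theta) * np.cos(phi))[..., None] * m
        + (r * np.sin(theta) * np.sin(phi))[..., None] * n_h
    )
    return c + d_local


def build_proxy_frames(times, alpha, beta, gamma, phi_bend, psi_bend, q):
    """Cartesian frames of the eight-atom proxy realizing the requested
    internal coordinates; returns an (n_frames, 8, 3) array."""
    n = len(times)
    ones = np.ones(n)
    coords = np.zeros((n, 8, 3))
    # N3 at origin, N4 on +x
    coords[:, 3] = 0.0
    coords[:, 4] = np.array([_R_NN, 0.0, 0.0])
    # C2 in the xy-plane: angle C2-N3-N4 = phi_bend
    ang = np.radians(phi_bend)
    coords[:, 1, 0] = _R_CN * np.cos(ang)
    coords[:, 1, 1] = _R_CN * np.sin(ang)
    # C5: angle N3-N4-C5 = psi_bend, dihedral C2-N3-N4-C5 = gamma
    coords[:, 5] = _nerf_place(coords[:, 1], coords[:, 3], coords[:, 4], _R_CN * ones, psi_bend, gamma)
    # N1: dihedral N1-C2-N3-N4 = alpha
    coords[:, 0] = _nerf_place(coords[:, 4], coords[:, 3], coords[:, 1], _R_CN_AMIDE * ones, 120.0 * ones, alpha)
    # O2 opposite N1; CO1 = r0 + q realizes the anti-symmetric stretch
    coords[:, 2] = _nerf_place(coords[:, 4], coords[:, 3], coords[:, 1], _R_CO_EQ + q, 120.0 * ones, alpha + 180.0)
    # N6: dihedral N3-N4-C5-N6 = beta (placed as N6-C5-N4-N3, same value)
    coords[:, 7] = _nerf_place(coords[:, 3], coords[:, 4], coords[:, 5], _R_CN_AMIDE * ones, 120.0 * ones, beta)
    # O5 opposite N6; CO2 = r0 - q
    coords[:, 6] = _nerf_place(coords[:, 3], coords[:, 4], coords[:, 5], _R_CO_EQ - q, 120.0 * ones, beta + 180.0)
    return coords


def _coords_to_trajectory(times, coords, dt, state_series, energies, traj_id) -> Trajectory:
    frames = [AtomFrame(_PROXY_ELEMENTS, coords[k], time=times[k]) for k in range(len(times))]
    return Trajectory(frames, dt=dt, state_series=state_series, energies=energies, id=traj_id)


def _draw_hop_time(law, rng) -> float:
    kind = law[0]
    if kind == "fixed":
        return float(law[1])
    if kind == "exponential":
        return float(rng.exponential(law[1]))
    if kind == "normal":
        return float(rng.normal(law[1], law[2]))
    raise ValueError(f"unknown hop-time law '{kind}'")


def _hop_chain(recipe: EnsembleRecipe, rng):
    """Draw ordered hop times for the cascade initial_state → … → 0."""
    hops = {}
    t_prev = 0.0
    for s in range(recipe.initial_state, 0, -1):
        key = (s, s - 1)
        if key not in recipe.hop_schedule:
            raise ValueError(f"hop schedule missing transition {key}")
        t = _draw_hop_time(recipe.hop_schedule[key], rng)
        t = max(t, t_prev + recipe.dt)  # enforce causal ordering on the grid
        if t > recipe.duration:
            break  # trajectory ends before this hop
        hops[key] = t
        t_prev = t
    return hops


def _state_series_from_hops(times, initial_state, hops, dt) -> np.ndarray:
    s = np.full(len(times), initial_state, dtype=int)
    for (frm, to), t in sorted(hops.items(), key=lambda kv: kv[1]):
        f = int(round(t / dt))
        s[f:] = to
    return s


def _energies_from_hops(times, n_states, hops, dt, threshold=DEFAULT_GAP_THRESHOLD_EV, base_gap=0.8):
    """Adiabatic energies whose inter-state gaps dip below the threshold at
    exactly the designed hop frames, so a gap-criterion replay reproduces
    the state series."""
    n = len(times)
    gaps = np.full((n, n_states - 1), base_gap)
    for (frm, _to), t in hops.items():
        f = int(round(t / dt))
        g = frm - 1  # gap index between states frm and frm-1
        lo, hi = max(0, f - 1), min(n - 1, f + 1)
        gaps[lo, g] = 1.5 * threshold
        gaps[hi, g] = 1.5 * threshold
        gaps[f, g] = 0.5 * threshold
    energies = np.zeros((n, n_states))
    energies[:, 1:] = np.cumsum(gaps, axis=1)
    return energies


def generate_ensemble(recipe: EnsembleRecipe):
    """Generate the excited and reference ensembles plus a ground-truth record.

    The excited swarm carries the chirped stretch, the coordinate ramps and
    the hop cascade; the reference swarm holds the ground-state frequency
    and the ground-state geometry throughout. The ground truth (exact ν̃(t),
    hop times, coordinate paths per trajectory) supports oracle tests.
    Identical seeds give bitwise-identical output.
    """
    rng = np.random.default_rng(recipe.seed)
    times = np.arange(0.0, recipe.duration + 0.5 * recipe.dt, recipe.dt)
    targets = {t.name: t for t in recipe.coordinate_targets}
    gs_targets = {
        name: CoordinateTarget(name, t.start, t.start, 0.0, 0.0, start_sd=t.start_sd)
        for name, t in targets.items()
    }
    excited_trajs, reference_trajs = [], []
    truth = {"times": times, "trajectories": []}
    n_states = recipe.initial_state + 1
    for i in range(recipe.n_traj):
        offset = rng.normal(0.0, recipe.freq_offset_sd) if recipe.freq_offset_sd > 0 else 0.0
        phase0_ex = rng.uniform(0.0, 2.0 * np.pi)
        phase0_ref = rng.uniform(0.0, 2.0 * np.pi)
        hops = _hop_chain(recipe, rng)
        # excited trajectory
        profile_ex = recipe.excited_profile.shifted(offset)
        _, q_ex, omega_ex = generate_stretch_series(profile_ex, recipe.dt, recipe.duration, phase0_ex, rng)
        paths = {name: targets[name].path(times, rng) for name in targets}
        coords_ex = build_proxy_frames(
            times, paths["alpha"], paths["beta"], paths["gamma"], paths["phi_bend"], paths["psi_bend"], q_ex
        )
        state_series = _state_series_from_hops(times, recipe.initial_state, hops, recipe.dt)
        energies = (
            _energies_from_hops(times, n_states, hops, recipe.dt) if recipe.with_energies else None
        )
        excited_trajs.append(
            _coords_to_trajectory(times, coords_ex, recipe.dt, state_series, energies, f"ex{i:03d}")
        )
        # reference trajectory: GS geometry, GS stretch frequency
        profile_ref = constant_profile(
            recipe.reference_omega + offset,
            recipe.duration,
            amplitude=recipe.excited_profile.amplitude,
            noise_sd=recipe.excited_profile.noise_sd,
        )
        _, q_ref, omega_ref = generate_stretch_series(profile_ref, recipe.dt, recipe.duration, phase0_ref, rng)
        gs_paths = {name: gs_targets[name].path(times, rng) for name in gs_targets}
        coords_ref = build_proxy_frames(
            times, gs_paths["alpha"], gs_paths["beta"], gs_paths["gamma"], gs_paths["phi_bend"], gs_paths["psi_bend"], q_ref
        )
        reference_trajs.append(
            _coords_to_trajectory(
                times, coords_ref, recipe.dt, np.zeros(len(times), dtype=int), None, f"ref{i:03d}"
            )
        )
        truth["trajectories"].append(
            {
                "id": f"ex{i:03d}",
                "freq_offset_cm1": float(offset),
                "phase0": float(phase0_ex),
                "hop_times_fs": {f"{a}->{b}": float(t) for (a, b), t in hops.items()},
                "omega_excited_cm1": omega_ex,
                "omega_reference_cm1": omega_ref,
                "coordinate_paths": paths,
            }
        )
    return (
        Ensemble(excited_trajs, role="excited"),
        Ensemble(reference_trajs, role="reference"),
        truth,
    )


def designed_crossing_energies(
    n_frames: int,
    crossing_frame: int,
    threshold: float = DEFAULT_GAP_THRESHOLD_EV,
    base_gap: float = 0.5,
    step: float = None,
) -> np.ndarray:
    """Two-state energy trace whose gap first drops below the threshold at
    exactly ``crossing_frame``: a linear approach calibrated so the gap at
    that frame is threshold − step/2."""
    if not 0 < crossing_frame < n_frames:
        raise ValueError("crossing frame must be inside the trajectory")
    if step is None:
        step = min(threshold, (base_gap - threshold) / max(crossing_frame, 1))
    k = np.arange(n_frames)
    gap = threshold + (crossing_frame - k - 0.5) * step
    gap = np.minimum(gap, base_gap)
    energies = np.zeros((n_frames, 2))
    energies[:, 1] = gap
    return energies


def save_ground_truth(path, truth: dict) -> None:
    """Serialize a ground-truth record (arrays become lists) to JSON."""

    def convert(obj):
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    Path(path).write_text(json.dumps(convert(truth)) + "\n")
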
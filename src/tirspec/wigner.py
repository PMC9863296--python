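"""Finite-temperature harmonic Wigner sampling of nuclear initial conditions.

For each normal mode k of (angular) frequency ω_k, the thermal Wigner
function of the harmonic oscillator is a Gaussian in the mass-weighted
coordinate Q_k and conjugate momentum P_k with

    Var(Q_k) = (ħ / 2ω_k) · coth(ħω_k / 2k_BT)
    Var(P_k) = (ħω_k / 2) · coth(ħω_k / 2k_BT)

which interpolates between the zero-point widths (T → 0, coth → 1) and the
classical equipartition limit (k_BT ≫ ħω, Var(Q) → k_BT/ω²). Q and P are
independent. Samples are transformed to Cartesian displacements and
velocities through the mass-weighted displacement vectors.

High-frequency X–H stretches are customarily excluded from the sampling
(their zero-point motion is large and they are spectroscopically inert for
the processes of interest); exclusion is by frequency cutoff or an explicit
index list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import HBAR_AMU_A2_PER_FS, KB_AMU_A2_PER_FS2_PER_K, wavenumber_to_angular_freq

__all__ = [
    "NormalModeSet",
    "InitialCondition",
    "wigner_sample",
    "wigner_variances",
    "mode_exclusion_by_frequency",
    "read_normal_modes",
    "write_normal_modes",
]

_ORTHO_TOL = 1e-6


@dataclass
class NormalModeSet:
    """Harmonic normal modes: frequencies plus mass-weighted displacement vectors.

    ``modes`` has shape (n_modes, 3·n_atoms); rows are mutually orthonormal
    in the mass-weighted metric. ``ref_coords`` (n_atoms, 3, Å) is the
    equilibrium geometry the displacements are applied to.
    """

    masses: np.ndarray  # (n_atoms,), amu
    frequencies: np.ndarray  # (n_modes,), cm⁻¹
    modes: np.ndarray  # (n_modes, 3 * n_atoms), mass-weighted, orthonormal
    ref_coords: np.ndarray | None = None  # (n_atoms, 3), Å
    mode_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        n_atoms = len(self.masses)
        if self.modes.shape != (len(self.frequencies), 3 * n_atoms):
            raise ValueError("modes must be (n_modes, 3*n_atoms)")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(len(self.frequencies)), atol=_ORTHO_TOL):
            raise ValueError("mode vectors must be mutually orthonormal (tol 1e-6)")
        if self.ref_coords is None:
            self.ref_coords = np.zeros((n_atoms, 3))
        else:
            self.ref_coords = np.asarray(self.ref_coords, dtype=float)
            if self.ref_coords.shape != (n_atoms, 3):
                raise ValueError("ref_coords must be (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)


@dataclass
class InitialCondition:
    """One sampled nuclear phase-space point."""

    coords: np.ndarray  # (n_atoms, 3), Å — reference + displacement
    velocities: np.ndarray  # (n_atoms, 3), Å/fs
    temperature: float  # K
    seed: int

    def __post_init__(self):
        if not (np.all(np.isfinite(self.coords)) and np.all(np.isfinite(self.velocities))):
            raise ValueError("non-finite initial condition")


def wigner_variances(frequencies_cm1, temperature: float):
    """Theoretical Var(Q) and Var(P) per mode (mass-weighted units:
    amu·Å² and amu·Å²/fs²)."""
    omega = wavenumber_to_angular_freq(np.asarray(frequencies_cm1, dtype=float))  # rad/fs
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if temperature == 0.0:
        coth = np.ones_like(omega)
    else:
        x = HBAR_AMU_A2_PER_FS * omega / (2.0 * KB_AMU_A2_PER_FS2_PER_K * temperature)
        coth = 1.0 / np.tanh(x)
    var_q = HBAR_AMU_A2_PER_FS / (2.0 * omega) * coth
    var_p = HBAR_AMU_A2_PER_FS * omega / 2.0 * coth
    return var_q, var_p


def mode_exclusion_by_frequency(modes: NormalModeSet, cutoff: float = 2700.0) -> list[int]:
    """Indices of modes above the cutoff (default 2700 cm⁻¹, the typical
    floor of X–H stretching frequencies)."""
    return [int(i) for i in np.flatnonzero(modes.frequencies > cutoff)]


def wigner_sample(
    modes: NormalModeSet,
    temperature: float,
    n_samples: int,
    seed: int,
    excluded_modes=(),
    extra_velocities: np.ndarray | None = None,
) -> list[InitialCondition]:
    """Draw initial conditions from the thermal harmonic Wigner distribution.

    Excluded modes contribute zero displacement and velocity. Imaginary or
    non-positive frequencies must be excluded explicitly (error otherwise).
    ``extra_velocities`` (n_atoms, 3, Å/fs) is an interface hook for
    velocities of environment atoms supplied by an external equilibration;
    they are added to every sample.
    """
    excluded = set(int(i) for i in excluded_modes)
    sampled = [k for k in range(modes.n_modes) if k not in excluded]
    bad = [k for k in sampled if modes.frequencies[k] <= 0]
    if bad:
        raise ValueError(f"non-positive frequencies in sampled modes {bad}; exclude them explicitly")
    rng = np.random.default_rng(seed)
    var_q, var_p = wigner_variances(modes.frequencies[sampled], temperature)
    n_k = len(sampled)
    q = rng.standard_normal((n_samples, n_k)) * np.sqrt(var_q)
    p = rng.standard_normal((n_samples, n_k)) * np.sqrt(var_p)
    # back-transform: x = ref + M^{-1/2} Lᵀ Q ; v = M^{-1/2} Lᵀ P
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(modes.masses, 3))  # (3N,)
    L = modes.modes[sampled]  # (n_k, 3N)
    disp = (q @ L) * inv_sqrt_m  # (n_samples, 3N)
    vel = (p @ L) * inv_sqrt_m
    out = []
    n_atoms = modes.n_atoms
    for s in range(n_samples):
        v = vel[s].reshape(n_atoms, 3)
        if extra_velocities is not None:
            v = v + np.asarray(extra_velocities, dtype=float)
        out.append(
            InitialCondition(
                coords=modes.ref_coords + disp[s].reshape(n_atoms, 3),
                velocities=v,
                temperature=temperature,
                seed=seed,
            )
        )
    return out


def sample_qp(modes: NormalModeSet, temperature: float, n_samples: int, seed: int, excluded_modes=()):
    """Mass-weighted (Q, P) samples per mode, for statistical validation.

    Returns arrays of shape (n_samples, n_modes) with zeros in excluded
    columns; uses the same draw order as :func:`wigner_sample`.
    """
    excluded = set(int(i) for i in excluded_modes)
    sampled = [k for k in range(modes.n_modes) if k not in excluded]
    rng = np.random.default_rng(seed)
    var_q, var_p = wigner_variances(modes.frequencies[sampled], temperature)
    q = np.zeros((n_samples, modes.n_modes))
    p = np.zeros((n_samples, modes.n_modes))
    q[:, sampled] = rng.standard_normal((n_samples, len(sampled))) * np.sqrt(var_q)
    p[:, sampled] = rng.standard_normal((n_samples, len(sampled))) * np.sqrt(var_p)
    return q, p


def write_normal_modes(path, modes: NormalModeSet) -> None:
    payload = {
        "masses_amu": modes.masses.tolist(),
        "frequencies_cm1": modes.frequencies.tolist(),
        "modes_mass_weighted": modes.modes.tolist(),
        "ref_coords_angstrom": modes.ref_coords.tolist(),
        "mode_labels": modes.mode_labels,
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def read_normal_modes(path) -> NormalModeSet:
    payload = json.loads(Path(path).read_text())
    return NormalModeSet(
        masses=np.array(payload["masses_amu"]),
        frequencies=np.array(payload["frequencies_cm1"]),
        modes=np.array(payload["modes_mass_weighted"]),
        ref_coords=np.array(payload["ref_coords_angstrom"]),
        mode_labels=payload.get("mode_labels", []),
    )
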
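"""Nuclear-ensemble linear absorption spectrum.

Each sampled geometry contributes one Gaussian per excited state, centred at
the vertical excitation energy with height proportional to the oscillator
strength:

    I(ω) ∝ Σ_n Σ_e f_{e←g}(R_n) exp(−(ΔE_ge(R_n) − ω)² / 2σ²)

The Gaussian is unnormalized (height = f, no 1/σ√2π), matching the
proportionality as written; σ is a phenomenological broadening, 0.1 eV by
default. Also provided: selection of the initial state for surface-hopping
runs as the brightest member of a candidate manifold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ev_to_nm
from .io import Spectrum1D

__all__ = [
    "StickState",
    "StickSpectrum",
    "BroadeningParams",
    "linear_spectrum",
    "select_initial_state",
    "read_sticks_csv",
]


@dataclass(frozen=True)
class StickState:
    energy_ev: float  # vertical excitation energy ΔE_ge
    f: float  # oscillator strength
    label: str = ""

    def __post_init__(self):
        if self.energy_ev <= 0:
            raise ValueError("excitation energy must be positive")
        if self.f < 0:
            raise ValueError("oscillator strength must be non-negative")


@dataclass
class StickSpectrum:
    """Vertical excitations of one sampled geometry."""

    geometry_id: str
    states: list[StickState] = field(default_factory=list)


@dataclass
class BroadeningParams:
    sigma: float = 0.1  # eV
    axis: tuple = (2.0, 6.0, 0.005)  # eV: (min, max, step)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("broadening sigma must be positive")

    @property
    def energy_axis(self) -> np.ndarray:
        lo, hi, step = self.axis
        return np.arange(lo, hi + 0.5 * step, step)


def linear_spectrum(sticks, params: BroadeningParams | None = None, normalize: str | None = None) -> Spectrum1D:
    """Sum-of-Gaussians ensemble spectrum on an eV axis.

    ``normalize``: None (raw proportionality), "max" (unit maximum) or
    "area" (unit integral). The nm companion axis is available through
    :func:`tirspec.constants.ev_to_nm` on the returned axis.
    """
    params = params or BroadeningParams()
    sticks = list(sticks)
    if not sticks or all(not s.states for s in sticks):
        raise ValueError("need at least one geometry with at least one state")
    axis = params.energy_axis
    intensity = np.zeros_like(axis)
    for geom in sticks:
        for st in geom.states:
            intensity += st.f * np.exp(-((st.energy_ev - axis) ** 2) / (2.0 * params.sigma**2))
    if normalize == "max":
        peak = intensity.max()
        if peak > 0:
            intensity = intensity / peak
    elif normalize == "area":
        area = np.trapezoid(intensity, axis)
        if area > 0:
            intensity = intensity / area
    elif normalize is not None:
        raise ValueError("normalize must be None, 'max' or 'area'")
    return Spectrum1D(axis, intensity, axis_unit="eV", meta={"sigma_ev": params.sigma, "normalize": normalize})


def select_initial_state(states, candidates) -> int:
    """Index (into ``states``) of the brightest candidate state.

    Surface-hopping runs start in the brightest member of the pumped
    manifold. Ties break toward the lower-energy state; if every candidate
    is dark (f = 0) the lowest-energy candidate is returned with a warning.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    cand = [(i, states[i]) for i in candidates]
    if all(st.f == 0 for _, st in cand):
        warnings.warn("all candidate states are dark; returning the lowest-energy one", stacklevel=2)
        return min(cand, key=lambda p: p[1].energy_ev)[0]
    return max(cand, key=lambda p: (p[1].f, -p[1].energy_ev))[0]


def read_sticks_csv(path) -> list[StickSpectrum]:
    """Read sticks from CSV with columns geometry_id, state, E_eV, f."""
    df = pd.read_csv(path)
    out = []
    for gid, grp in df.groupby("geometry_id", sort=False):
        states = [
            StickState(float(r.E_eV), float(r.f), label=str(r.state))
            for r in grp.itertuples()
        ]
        out.append(StickSpectrum(str(gid), states))
    return out


def spectrum_nm_axis(s: Spectrum1D) -> Spectrum1D:
    """Re-express an eV spectrum on a wavelength (nm) axis."""
    if s.axis_unit != "eV":
        raise ValueError("expected an eV-axis spectrum")
    nm = ev_to_nm(s.axis)[::-1]
    return Spectrum1D(nm, s.intensity[::-1], axis_unit="nm", meta=dict(s.meta))
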
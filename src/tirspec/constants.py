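"""Single authority for physical constants and unit conversions.

Internal unit conventions, used package-wide:

* time            femtoseconds (fs)
* length          Ångström (Å)
* vibrational frequency   wavenumbers (cm⁻¹)
* electronic energy       electronvolt (eV)
* mass            atomic mass units (amu)

Every conversion between these systems goes through the constants defined
here; no other module holds a unit literal.
"""

from __future__ import annotations

import numpy as np

#: hc in eV·nm — photon energy/wavelength conversion.
HC_EV_NM = 1239.84193

#: Speed of light in cm/fs; a mode with period T fs has wavenumber 1/(c·T) cm⁻¹.
C_CM_PER_FS = 2.99792458e-5

#: 1 kcal/mol expressed in eV.
KCALMOL_TO_EV = 0.0433641

#: ħ in amu·Å²/fs — action in the internal mechanics units.
HBAR_AMU_A2_PER_FS = 1.054571817e-34 / 1.66053906660e-27 * 1.0e5

#: Boltzmann constant in amu·Å²·fs⁻²·K⁻¹.
KB_AMU_A2_PER_FS2_PER_K = 1.380649e-23 / 1.66053906660e-27 * 1.0e-10


class DomainError(ValueError):
    """Raised when a physical quantity is outside its admissible domain."""


def ev_to_nm(energy_ev):
    """Convert photon energy in eV to wavelength in nm (bijective on E > 0)."""
    energy_ev = np.asarray(energy_ev, dtype=float)
    if np.any(energy_ev <= 0):
        raise DomainError("photon energy must be positive")
    out = HC_EV_NM / energy_ev
    return float(out) if out.ndim == 0 else out


def nm_to_ev(wavelength_nm):
    """Convert wavelength in nm to photon energy in eV (exact inverse of ev_to_nm)."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(wavelength_nm <= 0):
        raise DomainError("wavelength must be positive")
    out = HC_EV_NM / wavelength_nm
    return float(out) if out.ndim == 0 else out


def period_to_wavenumber(period_fs):
    """Oscillation period in fs → wavenumber in cm⁻¹, via 1/(c·T)."""
    period_fs = np.asarray(period_fs, dtype=float)
    if np.any(period_fs <= 0):
        raise DomainError("period must be positive")
    out = 1.0 / (C_CM_PER_FS * period_fs)
    return float(out) if out.ndim == 0 else out


def wavenumber_to_period(wavenumber_cm1):
    """Wavenumber in cm⁻¹ → oscillation period in fs (inverse of period_to_wavenumber)."""
    wavenumber_cm1 = np.asarray(wavenumber_cm1, dtype=float)
    if np.any(wavenumber_cm1 <= 0):
        raise DomainError("wavenumber must be positive")
    out = 1.0 / (C_CM_PER_FS * wavenumber_cm1)
    return float(out) if out.ndim == 0 else out


def wavenumber_to_angular_freq(wavenumber_cm1):
    """Wavenumber in cm⁻¹ → angular frequency in rad/fs (2π c ν̃)."""
    return 2.0 * np.pi * C_CM_PER_FS * np.asarray(wavenumber_cm1, dtype=float)
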
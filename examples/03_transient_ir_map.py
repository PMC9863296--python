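"""Transient UV-pump/IR-probe difference spectrum of the pedalo ensemble.

Runs the full semiclassical protocol on 50 synthetic trajectories: phase
accumulation of the probe coherence with the time-local stretch frequency,
ensemble-averaged polarization, damped half-sided Fourier transform
(T1 = 300 fs), and subtraction of the steady ground-state spectrum of a
50-trajectory reference swarm oscillating at 1825 cm⁻¹. Negative features
are the ground-state bleach; the positive excited-state band blue-shifts
as the ensemble relaxes.
"""

import warnings

import numpy as np

from tirspec.lineshape import LineshapeParams, difference_map, peak_position, reference_spectrum
from tirspec.synth import PROXY_COORDS, generate_ensemble, pedalo_recipe

recipe = pedalo_recipe(n_traj=50, duration=2000.0, seed=3)
excited, reference, _ = generate_ensemble(recipe)
params = LineshapeParams(delta_t_grid=(50.0, 150.0, 250.0, 350.0))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    i0 = reference_spectrum(reference, PROXY_COORDS["q_antisym"], params)
    tmap = difference_map(excited, reference, PROXY_COORDS["q_antisym"], params)

print(f"steady ground-state IR peak: {peak_position(i0):.1f} cm-1 "
      f"(reference ensemble oscillates at {recipe.reference_omega:.0f} cm-1)")
print()
print(" dt/fs   ESA max/cm-1   bleach min/cm-1   ESA centroid/cm-1")
for i, d in enumerate(tmap.delays):
    row = tmap.intensity[i]
    pos = np.clip(row, 0.0, None)
    centroid = (tmap.omega_axis * pos).sum() / pos.sum()
    print(
        f"{d:6.0f} {tmap.omega_axis[row.argmax()]:13.1f} "
        f"{tmap.omega_axis[row.argmin()]:16.1f} {centroid:18.1f}"
    )
print()
print("the positive excited-state band climbs toward the bleach as the")
print("stretch blue-shifts back to its relaxed value — the spectroscopic")
print("readout of the planarization dynamics.")
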
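# tirspec

Trajectory-based theoretical spectroscopy for nonadiabatic molecular
dynamics: from swarms of surface-hopping trajectories (real or synthetic),
compute the internal-coordinate fingerprints of a photoswitching mechanism,
the instantaneous frequency of an IR-active spectator mode, transient
UV-pump/IR-probe difference spectra, nuclear-ensemble linear absorption
spectra, Wigner-sampled initial conditions, and hopping/population
statistics.

## The problem

Azo-based photoswitches such as azodicarboxamide can deactivate through two
competing funnels after UV excitation: volume-demanding *trans–cis*
isomerization about the central C–N=N–C dihedral (γ), or a volume-conserving
*pedalo*-type motion in which the two amide-side dihedrals (α, β) planarize
concertedly while γ stays planar. Transient IR spectroscopy can distinguish
the two because the anti-symmetric carbonyl stretch — a spectator mode, not
itself part of either motion — shifts in frequency as the electronic
structure changes along the decay. This package implements the full
post-processing protocol that turns trajectory ensembles into that
spectroscopic observable, plus the surrounding analyses (mechanism
dihedrals, hop statistics, initial-condition sampling). It contains no
electronic-structure code: energies, gradients and oscillator strengths are
inputs.

## The core model

For each trajectory *n*, the time-local frequency ω(R(t)) of the spectator
mode is estimated from the intervals between consecutive same-type extrema
of the anti-symmetric stretch coordinate q = (CO₁ − CO₂)/2, giving one
estimate per half period (~10 fs), smoothed over five samples. The
probe-induced coherence then accumulates phase with that frequency, and the
macroscopic polarization is the ensemble mean

  P(Δt, τ) = (1/N) Σₙ exp[−i ∫_Δt^{Δt+τ} ωₙ(t′) dt′]

The transient spectrum at pump–probe delay Δt is the damped half-sided
Fourier transform

  I(Δt, ω) = 2 Re ∫₀^∞ P(Δt, τ) e^{+iωτ} e^{−τ/2T₁} dτ,  T₁ = 300 fs

and the difference spectrum δI(Δt, ω) = I(Δt, ω) − I₀(ω) subtracts the
steady ground-state spectrum of a reference ensemble run entirely in the
ground state. Negative δI features are the ground-state bleach; positive
features are the shifted excited-state absorption. Linear absorption uses
the nuclear-ensemble sum I(ω) ∝ Σₙ Σₑ f_{e←g}(Rₙ) exp(−(ΔE_ge(Rₙ)−ω)²/2σ²)
with σ = 0.1 eV, and initial conditions come from the thermal harmonic
Wigner distribution, Var(Q_k) = (ħ/2ω_k) coth(ħω_k/2k_BT).

A first-class synthetic generator (`tirspec.synth`) produces ensembles with
phase-exact chirped stretch signals, prescribed dihedral ramps, stochastic
hop cascades and serialized ground truth, so the entire pipeline is testable
without a quantum-chemistry engine.

## Worked example

```python
import warnings
from tirspec.lineshape import LineshapeParams, difference_map, peak_position, reference_spectrum
from tirspec.synth import PROXY_COORDS, generate_ensemble, pedalo_recipe

recipe = pedalo_recipe(n_traj=50, duration=2000.0, seed=3)
excited, reference, _ = generate_ensemble(recipe)
params = LineshapeParams(delta_t_grid=(50.0, 150.0, 250.0, 350.0))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    i0 = reference_spectrum(reference, PROXY_COORDS["q_antisym"], params)
    tmap = difference_map(excited, reference, PROXY_COORDS["q_antisym"], params)
print(peak_position(i0))
```

prints `1823.7` — the steady ground-state IR peak of a reference ensemble
oscillating at 1825 cm⁻¹ (the 1.3 cm⁻¹ deviation is the estimator's
half-period discretization). The difference map rows
(`examples/03_transient_ir_map.py`) show the excited-state band climbing
from a centroid of 1705 cm⁻¹ at Δt = 50 fs to 1785 cm⁻¹ at 350 fs while the
bleach stays pinned near 1825 cm⁻¹: the blue-shifting positive lobe is the
spectroscopic readout of the planarization, and its collision with the
bleach reproduces the destructive interference seen in measured transient
spectra. The other examples each exercise one capability (coordinates,
frequency tracking, absorption, Wigner sampling, hop statistics) and print
a few annotated numbers in under a minute.

The command-line entry point mirrors the library:

```sh
tirspec synth --out demo/           # synthetic ensemble + ground truth
tirspec coords demo/ex000.xyz --spec coords.yaml
tirspec tir --manifest demo/excited.json --ref demo/reference.json
```

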
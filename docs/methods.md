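# Methods

This note records the models implemented in `tirspec`, the numerical choices
behind them, and what the synthetic test conditions do and do not establish
about real trajectory data.

## Scope and data model

The package post-processes nonadiabatic molecular-dynamics output; it never
computes electronic structure. A `Trajectory` is a uniformly sampled series
of Cartesian frames (Å, default step 1 fs) with a per-frame active
electronic state (0 = ground state) and, optionally, per-frame adiabatic
state energies (eV). An `Ensemble` is a swarm of such trajectories sharing
the time step and atom ordering; the `excited` role carries the photoexcited
swarm, the `reference` role a swarm propagated entirely in the ground state
for the steady spectrum. Units are fixed package-wide (fs, Å, cm⁻¹, eV, amu)
and every conversion goes through `tirspec.constants`; a test asserts that
no other module duplicates those literals.

On-disk formats are plain text (multi-frame XYZ, delimited state logs, JSON
manifests, CSV spectra) so output of any hopping engine can be adapted with
a trivial converter. When both an XYZ comment tag and a state log carry
state information, the log wins.

## Internal coordinates

Dihedrals are signed, right-hand convention, canonical branch (−180°, 180°],
computed with the atan2 construction on the two plane normals; bends from
the normalized dot product; the anti-symmetric stretch as
(d₁ − d₂)/2. The 0–360° rendering used in some distribution plots is a
presentation transform of the same canonical value, and
`deviation_from_plane` folds any dihedral to its distance from planarity
(115° and 245° both → 65°). Note one identity worth stating because it is
often misquoted: reading a chain backwards (i,j,k,l → l,k,j,i) leaves the
signed dihedral *unchanged* — the sighting direction and outer-atom order
flip together; the sign flips under mirror reflection. Property tests assert
rigid-motion invariance (1e-8°), reversal symmetry and mirror antisymmetry.

Ensemble statistics of dihedrals are circular: framewise circular mean and
circular standard deviation across trajectories (members at 170° and −170°
average to 180°, not 0°), with the mean series unwrapped in time. Bends and
bonds use ordinary moments. Atom indices for named coordinates come from
configuration, not hardcoded numbering, so the protocol transfers to any
switching unit with an IR-active spectator mode.

## Instantaneous frequency (extrema-interval estimator)

The time-local frequency of an oscillating coordinate is estimated as the
inverse interval between two consecutive maxima (or two consecutive minima),
converted via ν̃ = 1/(cT); max- and min-derived samples merge to roughly one
estimate per half period. Choices:

- **Parabolic vertex refinement.** Raw 1 fs sampling quantizes an ~18.5 fs
  period at the ±5% level; a three-point parabola through each extremum
  recovers sub-step timing. Measured recovery error on harmonic signals with
  periods 10–40 fs is below 0.1%, and below 2% pointwise on a
  1 cm⁻¹/fs linear chirp.
- **Plateaus** collapse to a single extremum at their midpoint (no
  refinement); monotone or constant tracks yield "no oscillation".
- **Smoothing** is a five-sample centered boxcar, as the averaging rule is
  written, even though samples arrive every half period so five samples span
  ~2.5 periods; the window is a parameter. Edges use the truncated window so
  the early-time samples — which dominate the transient signal — are kept.
- **No detrending** by default: the anti-symmetric difference coordinate is
  zero-mean by construction. (A drifting mode would need detrending before
  extrema search; that is out of scope here.)

The Hilbert/wavelet families and mode-tracking procedures are deliberately
not implemented; the interval estimator is the protocol under study.

## Transient-IR lineshape

Per trajectory, the smoothed frequency samples are linearly interpolated
onto the propagation grid (constant extrapolation outside the sampled
range), converted to angular frequency ω_ang = 2πc ν̃, and integrated with
the trapezoid rule to give the coherence phase
φ(τ) = ∫_Δt^{Δt+τ} ω_ang dt′. The polarization is the unweighted mean of
the unit-modulus coherences e^{−iφ}: the IR transition dipole is taken
coordinate-independent, so the constant prefactors drop and spectra are in
arbitrary units. The spectrum is the damped half-sided Fourier sum,
evaluated directly on the requested wavenumber grid (trapezoid weights, kernel
e^{+iωτ}); the sign convention is fixed so that a monochromatic trajectory
gives a *positive* absorptive Lorentzian — the formal i-prefactor of the
polarization would render the 2Re transform dispersive, and the absorptive
convention is the one that reproduces observed band shapes.

Numerical parameters (`LineshapeParams`):

- **T₁ = 300 fs** — phenomenological coherence lifetime; damping e^{−τ/2T₁}
  gives a homogeneous FWHM of 1/(2πcT₁) = 17.7 cm⁻¹.
- **τ grid = trajectory dt (1 fs), tau_max = 3072 fs.** The window must be
  long against T₁: truncating at ~3.4 T₁ still leaves 18% of the envelope
  and broadens a monochromatic line to 26 cm⁻¹; at ~10 T₁ the residual is
  <0.7% and the measured FWHM is 17.67 cm⁻¹. Zero padding cannot substitute
  — it refines the grid but does not remove truncation broadening, which is
  why the transform is evaluated directly on the output grid (exact for any
  grid) and no padding knob exists.
- **Coherence windows extending beyond the data** hold the last frequency
  constant (with a warning). Trajectories here keep oscillating at the
  relaxed frequency after decay, so the extension is physically benign and
  avoids ensemble-size discontinuities across Δt.
- **Output grid** 1500–2000 cm⁻¹ at 0.5 cm⁻¹ by default.

The difference map δI(Δt, ω) = I(Δt, ω) − I₀(ω) uses the same pipeline at
Δt = 0 on the reference ensemble for I₀. When the excited band approaches
the bleach, their overlap partially fills the negative lobe and displaces
its apparent minimum by roughly a linewidth — destructive interference, not
an artifact; tests locate the bleach within 40 cm⁻¹ of the reference
frequency rather than at its exact position. Because each trajectory's
coherence starts at phase zero at τ = 0, a monochromatic ensemble is fully
phase-coherent regardless of the oscillator phases, and static frequency
disorder produces the expected Gaussian inhomogeneous decay of |P|.

## Linear absorption and initial-state selection

The nuclear-ensemble spectrum is a double sum of *unnormalized* Gaussians
(height = oscillator strength, no 1/σ√2π), matching the proportionality as
written; σ = 0.1 eV default, axis 2.0–6.0 eV at 5 meV. Both max- and
area-normalization are offered since conventions differ between plots.
Surface-hopping runs start in the brightest state of the pumped manifold;
ties break to the lower state, and an all-dark manifold returns the lowest
candidate with a warning (deterministic behavior over silent arbitrariness).

## Hopping analysis

The simplified hopping scheme is deterministic: at each frame, if the energy
gap between the active state and the adjacent lower state is under the
threshold (2 kcal/mol = 0.086728 eV, stored in eV), the trajectory hops down
with probability one. Up-hops among excited states use the same gap rule
(the exact back-hop criterion is not specified by the scheme's description;
applying the same rule is this package's choice), down-hops take priority
within a frame, and a trajectory that has reached the ground state never
leaves it. "Adjacent" means ±1 state index only — at 1 fs steps a double
crossing within one step is negligible. The hop timestamp is the first frame
satisfying the criterion, and the replay is idempotent on its own output.
Population curves are right-continuous step functions whose rows sum to one;
hop-geometry statistics use circular moments for dihedrals.

## Wigner sampling

Initial conditions are drawn per normal mode from the thermal harmonic
Wigner function: independent Gaussians in the mass-weighted coordinate and
momentum with Var(Q) = (ħ/2ω)coth(ħω/2k_BT), Var(P) = (ħω/2)coth(ħω/2k_BT)
(coth → 1 at T = 0; equipartition in the classical limit). The finite-T coth
form is the standard choice where the alternative would be zero-point-only
widths. Mode exclusion — conventionally the C–H/N–H stretches — is by
frequency cutoff (default 2700 cm⁻¹, the floor of X–H stretches) with an
explicit index list as the exact override, since identity-based exclusion
would require connectivity. Imaginary/non-positive frequencies must be
excluded explicitly. Merging with environment-atom velocities from an
external equilibration is supported only as a hook that adds supplied
velocities; the sampler itself stays engine-free. Sampling is bitwise
reproducible for a fixed seed.

## Synthetic study conditions

The generator's defaults encode the study conditions: 50 trajectories, 2 ps
at 1 fs; the stretch red-shifted to 1600 cm⁻¹ at excitation, blue-shifting
linearly to 1800 cm⁻¹ over 200 fs, then steady; hop cascades S₂→S₁ near
100 fs (normal, σ 30 fs) and S₁→S₀ near 300 fs (normal, σ 50 fs), the
second consistent with ground-state repopulation completing within ~400 fs;
a ground-state reference at 1825 cm⁻¹; per-trajectory static frequency
offsets of σ = 10 cm⁻¹ as inhomogeneity; α planarizing 106.4°→178°, β
−107.4°→−180°, γ held at 179.9°, bends opening 110°→125°, with endpoint
jitter matching the ~10° equilibrium spread of the floppy dihedrals.

Design choices worth recording:

- **Phase-exact synthesis.** q(t) = A sin(φ₀ + φ(t)) with φ integrated
  analytically per profile segment, so estimator error is attributable to
  the estimator alone; the generator stores its exact ν̃(t) as ground truth.
- **Band-limited jitter.** Coordinate noise is white noise smoothed with a
  ~2 fs Gaussian kernel and rescaled. Per-frame white noise would fabricate
  sub-period extrema that no continuous MD coordinate exhibits (positions
  are smooth in time); band-limited jitter emulates weak coupling to other
  modes without breaking the extrema topology.
- **Eight-atom proxy geometry.** N1–C2(=O2)–N3=N4–C5(=O5)–N6 is the minimal
  structure carrying every named coordinate; atoms are placed by natural-
  extension-reference-frame construction, vectorized over frames, and the
  two C=O lengths realize the stretch as r₀ ± q(t) so the anti-symmetric
  coordinate reproduces q exactly. Energies, when requested, are built so
  each inter-state gap dips below the hop threshold at exactly the designed
  hop frame, making the gap-criterion replay an exact cross-check.

What passing tests on this generator show: the estimator, lineshape,
statistics and bookkeeping are correct against closed forms and known
ground truth. What they do not show: fidelity of any real system's
frequencies or time scales (those require electronic structure), mode
coupling beyond a prescribed profile, coordinate-dependent IR dipoles,
orientational averaging, or finite pulse bandwidths — all outside this
package's model.

## Problem sizes and determinism

Default analyses run on 50-trajectory, 2 ps ensembles; statistical
validations use n = 10⁴ Wigner draws; the full test suite and the
acceptance script each complete in well under a minute on one CPU. All
stochastic paths take explicit seeds (numpy `default_rng`); fixed seeds give
bitwise-identical ensembles. Statistical assertions use 3-standard-error or
5% bands; estimators at n = 50 can legitimately land 2σ from a design value
(the hop-time example script shows one such draw), which is why tests
compare against standard errors, not point values.
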
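"""Semiclassical lineshape: phase accumulation, dephasing, Fourier limits."""

import warnings

import numpy as np
import pytest

from tirspec.constants import wavenumber_to_angular_freq
from tirspec.freqtrack import FrequencyTrack
from tirspec.lineshape import (
    LineshapeParams,
    TransientMap,
    accumulate_phase,
    difference_map,
    ensemble_polarization,
    full_width_half_max,
    lorentzian_fwhm,
    peak_position,
    resample_omega,
    spectrum,
)

WINDOW = dict(omega_window=(1600.0, 1950.0))


def _const_omega(value, n=5000):
    return np.full(n, value)


def test_resample_linear_interpolation_and_extrapolation():
    ft = FrequencyTrack(np.array([10.0, 30.0]), np.array([1600.0, 1800.0]))
    dense = resample_omega(ft, dt=1.0, span=40.0)
    assert dense[20] == pytest.approx(1700.0)
    assert dense[5] == pytest.approx(1600.0)  # constant before first sample
    assert dense[40] == pytest.approx(1800.0)  # constant after last
    const = resample_omega(FrequencyTrack(np.array([5.0, 15.0]), np.array([1700.0, 1700.0])), 1.0, 30.0)
    assert np.allclose(const, 1700.0)


def test_phase_advances_two_pi_per_period():
    p = LineshapeParams(**WINDOW)
    coh = accumulate_phase(_const_omega(1667.8), 1.0, 0.0, p.tau_grid)
    # 1667.8 cm⁻¹ has a 20 fs period: the coherence returns to its start
    assert abs(coh[20] - coh[0]) < 1e-3
    assert np.allclose(np.abs(coh), 1.0, atol=1e-12)


def test_zero_frequency_gives_unit_coherence():
    p = LineshapeParams(**WINDOW)
    coh = accumulate_phase(np.zeros(4000), 1.0, 0.0, p.tau_grid)
    assert np.allclose(coh, 1.0)


def test_polarization_of_identical_trajectories_equals_single():
    p = LineshapeParams(**WINDOW)
    single = accumulate_phase(_const_omega(1800.0), 1.0, 0.0, p.tau_grid)
    P = ensemble_polarization([_const_omega(1800.0)] * 7, 1.0, 0.0, p)
    assert np.allclose(P, single)


def test_gaussian_inhomogeneous_dephasing(rng):
    """50 static frequencies drawn N(1800, 20²) dephase the ensemble
    coherence as the Gaussian e^{-σ_ang² τ²/2} (up to sampling error)."""
    p = LineshapeParams(tau_max=400.0, **WINDOW)
    freqs = rng.normal(1800.0, 20.0, size=50)
    P = ensemble_polarization([_const_omega(f, 1000) for f in freqs], 1.0, 0.0, p)
    sigma_ang = wavenumber_to_angular_freq(float(np.std(freqs)))
    mean_ang = wavenumber_to_angular_freq(float(np.mean(freqs)))
    tau = p.tau_grid
    predicted = np.exp(-0.5 * sigma_ang**2 * tau**2)
    # compare the envelopes where the Gaussian is still well above noise
    m = predicted > 0.2
    assert np.allclose(np.abs(P)[m], predicted[m], atol=0.12)


def test_monochromatic_lorentzian_limit():
    p = LineshapeParams(**WINDOW)
    s = spectrum(accumulate_phase(_const_omega(1800.0), 1.0, 0.0, p.tau_grid), p)
    assert s.intensity.max() > 0
    assert peak_position(s) == pytest.approx(1800.0, abs=1.0)
    assert full_width_half_max(s) == pytest.approx(lorentzian_fwhm(300.0), abs=1.0)


def test_halving_t1_doubles_the_width():
    p1 = LineshapeParams(T1=300.0, **WINDOW)
    p2 = LineshapeParams(T1=150.0, **WINDOW)
    w1 = full_width_half_max(spectrum(accumulate_phase(_const_omega(1800.0), 1.0, 0.0, p1.tau_grid), p1))
    w2 = full_width_half_max(spectrum(accumulate_phase(_const_omega(1800.0), 1.0, 0.0, p2.tau_grid), p2))
    assert w2 / w1 == pytest.approx(2.0, rel=0.05)


def test_two_subensembles_two_equal_peaks():
    p = LineshapeParams(**WINDOW)
    P = ensemble_polarization([_const_omega(1700.0)] * 5 + [_const_omega(1850.0)] * 5, 1.0, 0.0, p)
    s = spectrum(P, p)
    i1 = s.intensity[np.abs(s.axis - 1700.0) < 2.0].max()
    i2 = s.intensity[np.abs(s.axis - 1850.0) < 2.0].max()
    assert i1 == pytest.approx(i2, rel=0.02)
    assert i1 == pytest.approx(s.intensity.max(), rel=1e-9)


def test_linearity_in_the_ensemble():
    p = LineshapeParams(**WINDOW)
    a = [_const_omega(1700.0)] * 3
    b = [_const_omega(1850.0)] * 6
    s_merged = spectrum(ensemble_polarization(a + b, 1.0, 0.0, p), p)
    s_a = spectrum(ensemble_polarization(a, 1.0, 0.0, p), p)
    s_b = spectrum(ensemble_polarization(b, 1.0, 0.0, p), p)
    expected = (3 * s_a.intensity + 6 * s_b.intensity) / 9
    assert np.allclose(s_merged.intensity, expected, atol=1e-9 * np.abs(expected).max())


def test_difference_spectrum_signs_and_conservation():
    """Shifted excited band: positive lobe at the new frequency, bleach at
    the reference; the difference integrates to ~0 when both bands lie
    inside the window."""
    p = LineshapeParams(**WINDOW)
    s_ex = spectrum(ensemble_polarization([_const_omega(1700.0)] * 4, 1.0, 0.0, p), p)
    s_ref = spectrum(ensemble_polarization([_const_omega(1825.0)] * 4, 1.0, 0.0, p), p)
    delta = s_ex.intensity - s_ref.intensity
    assert s_ex.axis[delta.argmax()] == pytest.approx(1700.0, abs=1.5)
    assert s_ex.axis[delta.argmin()] == pytest.approx(1825.0, abs=1.5)
    assert abs(np.trapezoid(delta, s_ex.axis)) < 0.05 * np.trapezoid(np.abs(delta), s_ex.axis)


def test_difference_map_of_identical_ensembles_is_zero():
    from tirspec.synth import pedalo_recipe, generate_ensemble, PROXY_COORDS

    recipe = pedalo_recipe(n_traj=3, duration=400.0, seed=5)
    _, ref, _ = generate_ensemble(recipe)
    p = LineshapeParams(delta_t_grid=(0.0, 50.0), tau_max=256.0, **WINDOW)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tm = difference_map(ref, ref, PROXY_COORDS["q_antisym"], p)
    assert tm.kind == "difference"
    # at Δt = 0 the rows are identical by definition
    assert np.allclose(tm.intensity[0], 0.0, atol=1e-9)


def test_order_invariance_of_the_polarization():
    p = LineshapeParams(**WINDOW)
    tracks = [_const_omega(1700.0), _const_omega(1800.0), _const_omega(1850.0)]
    P1 = ensemble_polarization(tracks, 1.0, 0.0, p)
    P2 = ensemble_polarization(tracks[::-1], 1.0, 0.0, p)
    # identical up to float summation order
    assert np.allclose(P1, P2, rtol=0.0, atol=1e-12)


def test_transient_map_validation():
    with pytest.raises(ValueError):
        TransientMap(np.array([0.0, 50.0]), np.array([1700.0, 1800.0]), np.zeros((3, 2)))
    with pytest.raises(ValueError):
        ensemble_polarization([], 1.0, 0.0, LineshapeParams(**WINDOW))
    with pytest.raises(ValueError):
        accumulate_phase(_const_omega(1800.0), 1.0, -5.0, LineshapeParams(**WINDOW).tau_grid)
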
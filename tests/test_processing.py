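"""Apodization, transforms, phase correction, denoising, baselines."""

import numpy as np
import pytest

from ftms2d.geometry import PRESETS, fold_frequency, vertical_axis
from ftms2d.processing import (
    PhaseModel,
    apodize,
    baseline_correct,
    fit_phase,
    ft_2d,
    sane_denoise,
    sine_bell,
    zero_fill,
)
from ftms2d.simulate import (
    SignalComponent,
    SimulationPlan,
    simulate_2d,
    simulate_reference_msms,
)


# ---------------------------------------------------------------------------
# windows and zero-filling
# ---------------------------------------------------------------------------

def test_sine_bell_shape():
    w = sine_bell(1001, max_position=0.15)
    assert w[0] == pytest.approx(0.0, abs=1e-12)
    assert w[-1] == pytest.approx(0.0, abs=1e-12)
    assert w[150] == pytest.approx(1.0, abs=1e-6)  # maximum at the 0.15 fraction
    assert np.max(w) <= 1.0 + 1e-12


def test_sine_bell_discrete_sum_matches_integral():
    # integral of sin(pi*h(u)) du over [0,1] is 2/pi for any max position
    for mp in (0.15, 0.3, 0.5):
        w = sine_bell(20001, max_position=mp)
        assert np.mean(w) == pytest.approx(2 / np.pi, rel=1e-3)


def test_apodize_constant_returns_window():
    out = apodize(np.ones(512), 0.15)
    assert np.allclose(out, sine_bell(512, 0.15))
    with pytest.raises(ValueError):
        apodize(np.ones(16), max_position=1.5)


def test_zero_fill_basics():
    x = np.arange(1024.0)
    assert zero_fill(x, 0) is not None and zero_fill(x, 0).size == 1024
    y = zero_fill(x, 1)
    assert y.size == 2048 and np.all(y[1024:] == 0) and np.all(y[:1024] == x)
    with pytest.raises(ValueError):
        zero_fill(x, -1)


def test_zero_fill_preserves_centroid():
    """Zero-filling refines the grid without moving the (centroided) peak."""
    from ftms2d.metrology import ScanProfile, pick_peaks

    t = np.arange(2048) / 2048.0
    sig = np.cos(2 * np.pi * 333.3 * t) * np.exp(-3 * t)
    cents = []
    for zf in (1, 2):
        spec = np.abs(np.fft.rfft(zero_fill(apodize(sig, 0.15), zf)))
        axis = np.arange(spec.size) * 2048.0 / (2048 * 2**zf)
        peak = max(pick_peaks(ScanProfile(axis, spec), 3), key=lambda p: p.height)
        cents.append(peak.centroid)
    assert cents[0] == pytest.approx(cents[1], abs=0.05)


# ---------------------------------------------------------------------------
# 2D transform chain
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("preset", ["nb10k", "nb4k", "nb2k", "nb1k"])
def test_noiseless_peak_recovered_on_grid(calibration, preset):
    """Ground-truth 2D position recovered within one grid point, all presets."""
    params = PRESETS[preset].replace(detect_points=1024, n_increments=256)
    comp = SignalComponent("x", 219_272.0, 200_000.0, 1.0)
    tr = simulate_2d(SimulationPlan([comp], params, calibration, decay_rate=20.0))
    spec = ft_2d(tr)
    # ignore the modulation DC ridge at the bottom of the vertical axis
    guard = np.searchsorted(spec.v_axis, 0.05 * params.nyquist_vertical)
    i, j = np.unravel_index(np.argmax(spec.matrix[guard:]), spec.matrix[guard:].shape)
    i += guard
    fold = fold_frequency(219_272.0, params)
    dv = spec.v_axis[1] - spec.v_axis[0]
    dh = spec.h_axis[1] - spec.h_axis[0]
    assert abs(spec.v_axis[i] - fold.reduced_frequency) <= dv
    assert abs(spec.h_axis[j] - 200_000.0) <= dh
    # provenance records every applied step
    assert [s["step"] for s in spec.provenance][:2] == ["apodize_h", "zero_fill_h"]


def test_vertical_grid_matches_axis_bookkeeping(calibration):
    params = PRESETS["nb4k"].replace(detect_points=256)
    comp = SignalComponent("x", 219_272.0, 200_000.0, 1.0)
    spec = ft_2d(simulate_2d(SimulationPlan([comp], params, calibration)))
    va = vertical_axis(params)
    assert spec.matrix.shape[0] == va.n_points == 2048
    assert spec.v_axis[1] - spec.v_axis[0] == pytest.approx(va.point_spacing)
    assert va.point_spacing == pytest.approx(2.0, abs=0.05)


def test_magnitude_bounds_absorption(calibration):
    params = PRESETS["nb4k"].replace(detect_points=512, n_increments=128)
    comp = SignalComponent("x", 219_272.0, 200_000.0, 1.0)
    tr = simulate_2d(SimulationPlan([comp], params, calibration))
    x = apodize(tr.matrix, 0.15, axis=1)
    c = np.fft.rfft(zero_fill(x, 2, axis=1), axis=1)
    assert np.all(np.abs(c) >= c.real - 1e-12)


def test_processing_is_deterministic(calibration):
    params = PRESETS["nb4k"].replace(detect_points=512, n_increments=128)
    comp = SignalComponent("x", 219_272.0, 200_000.0, 1.0)
    tr = simulate_2d(SimulationPlan([comp], params, calibration, noise_sd=0.5, seed=7))
    a = ft_2d(tr, sane_rank=10, seed=3)
    b = ft_2d(tr, sane_rank=10, seed=3)
    assert np.array_equal(a.matrix, b.matrix)
    assert a.provenance == b.provenance


def test_demodulated_band_matches_printed_foldovers(calibration):
    """The folded peak of a 219.27 kHz precursor lands in the printed band."""
    for preset, folds in [("nb10k", 14), ("nb4k", 36), ("nb2k", 72), ("nb1k", 144)]:
        params = PRESETS[preset].replace(detect_points=256, n_increments=256)
        comp = SignalComponent("x", 219_270.0, 200_000.0, 1.0)
        spec = ft_2d(simulate_2d(SimulationPlan([comp], params, calibration)))
        guard = np.searchsorted(spec.v_axis, 0.05 * params.nyquist_vertical)
        col = np.argmin(np.abs(spec.h_axis - 200_000.0))
        i = guard + np.argmax(spec.matrix[guard:, col])
        fold = fold_frequency(219_270.0, params)
        assert fold.band_index == folds
        tv = spec.true_vertical_axis(fold.band_index)
        k = i if fold.band_index % 2 == 0 else spec.matrix.shape[0] - 1 - i
        assert abs(tv[k] - 219_270.0) <= 2 * (spec.v_axis[1] - spec.v_axis[0])


# ---------------------------------------------------------------------------
# phase model
# ---------------------------------------------------------------------------

def _reference(calibration, phase, n_peaks=9, noise=0.0):
    params = PRESETS["nb10k"].replace(detect_points=16384)
    comps = [
        SignalComponent(f"p{i}", 219_272.0, f, 1.0)
        for i, f in enumerate(np.linspace(90_000, 340_000, n_peaks))
    ]
    plan = SimulationPlan(comps, params, calibration, phase=phase, noise_sd=noise, seed=5)
    return simulate_reference_msms(plan), [c.f_horizontal for c in comps]


def test_injected_quadratic_phase_recovered(calibration):
    truth = PhaseModel(horizontal=(2e-11, 1.2e-5, 0.3))
    ref, freqs = _reference(calibration, truth, noise=0.01)
    fit = fit_phase(ref, freqs, zero_fills=2)
    for got, want in zip(fit.horizontal, truth.horizontal):
        assert got == pytest.approx(want, rel=0.01)


def test_zero_phase_gives_near_zero_coefficients(calibration):
    ref, freqs = _reference(calibration, None)
    fit = fit_phase(ref, freqs, zero_fills=2)
    grid = np.linspace(90_000, 340_000, 40)
    assert np.max(np.abs(fit.horizontal_phase(grid))) < 0.02


def test_three_peaks_determine_the_quadratic_exactly(calibration):
    truth = PhaseModel(horizontal=(1e-11, -8e-6, 0.2))
    ref, freqs = _reference(calibration, truth, n_peaks=3)
    fit = fit_phase(ref, freqs, zero_fills=3)
    grid = np.linspace(95_000, 335_000, 40)
    assert np.max(np.abs(fit.horizontal_phase(grid) - truth.horizontal_phase(grid))) < 0.02


def test_zero_injected_phase_spectrum_symmetric(calibration):
    """Absorption peaks of an unphased reference are locally symmetric."""
    params = PRESETS["nb10k"].replace(detect_points=16384)
    # put the carrier exactly on a spectral bin so the lineshape itself,
    # not off-bin sampling, decides the symmetry; decay well inside the record
    n = 16384 * 4
    f0 = 18350 * params.detect_sample_rate / n
    comp = SignalComponent("p", 219_272.0, f0, 1.0)
    ref = simulate_reference_msms(SimulationPlan([comp], params, calibration, tau2=2e-3))
    spec = np.fft.rfft(zero_fill(ref.signal, 2)).real
    j = int(np.argmax(spec))
    left, right = spec[j - 8 : j], spec[j + 1 : j + 9][::-1]
    assert np.allclose(left, right, atol=0.02 * spec[j])


# ---------------------------------------------------------------------------
# SANE denoising
# ---------------------------------------------------------------------------

def test_sane_exact_on_low_rank_data():
    rng = np.random.default_rng(0)
    u = rng.standard_normal((256, 3))
    v = rng.standard_normal((3, 512))
    x = u @ v
    for rank in (3, 10):
        out = sane_denoise(x, rank, seed=1)
        assert np.linalg.norm(out - x) / np.linalg.norm(x) < 1e-6


def test_sane_invalid_rank():
    x = np.zeros((16, 32))
    with pytest.raises(ValueError):
        sane_denoise(x, 0)
    with pytest.raises(ValueError):
        sane_denoise(x, 16)


def test_sane_reduces_noise_floor_without_moving_peaks(calibration):
    """Noise floor down >= 2x, peak centroids moved < 0.1 grid point."""
    from ftms2d.metrology import ScanProfile, noise_level, pick_peaks

    params = PRESETS["nb10k"].replace(detect_points=1024, n_increments=1024)
    comp = SignalComponent("x", 219_272.0, 200_000.0, 10.0)
    base = SimulationPlan([comp], params, calibration, decay_rate=20.0)
    noisy = SimulationPlan([comp], params, calibration, decay_rate=20.0, noise_sd=1.0, seed=2)
    spec_clean = ft_2d(simulate_2d(base))
    spec_raw = ft_2d(simulate_2d(noisy))
    spec_den = ft_2d(simulate_2d(noisy), sane_rank=30, seed=2)
    col = np.argmin(np.abs(spec_raw.h_axis - 200_000.0))
    guard = np.searchsorted(spec_raw.v_axis, 0.05 * params.nyquist_vertical)

    def vertical_centroid(spec):
        prof = ScanProfile(spec.v_axis[guard:], spec.matrix[guard:, col])
        return max(pick_peaks(prof, 3.0), key=lambda p: p.height).centroid

    off_peak = np.s_[guard:, col + 50]
    floor_raw = noise_level(spec_raw.matrix[off_peak])
    floor_den = noise_level(spec_den.matrix[off_peak])
    assert floor_raw / floor_den >= 2.0
    dv = spec_raw.v_axis[1] - spec_raw.v_axis[0]
    assert abs(vertical_centroid(spec_den) - vertical_centroid(spec_clean)) < 0.1 * dv


# ---------------------------------------------------------------------------
# baseline correction
# ---------------------------------------------------------------------------

def test_baseline_flat_offset_removed_exactly():
    y = np.full(1000, 7.3)
    assert np.allclose(baseline_correct(y), 0.0, atol=1e-12)


def test_baseline_linear_ramp_mostly_removed():
    y = np.linspace(0.0, 10.0, 2000)
    resid = baseline_correct(y)
    assert np.max(np.abs(resid)) < 0.01 * 10.0


def test_baseline_preserves_peak_height():
    x = np.arange(4000)
    peak = 5.0 * np.exp(-0.5 * ((x - 2000) / 6.0) ** 2)
    out = baseline_correct(peak)
    assert out.max() == pytest.approx(5.0, rel=0.02)
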
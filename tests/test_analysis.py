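"""Added-up spectra, assignment/coverage, quantification, correlation, decay."""

import numpy as np
import pytest

from ftms2d.analysis import (
    added_up_spectrum,
    assign_fragments,
    correlation_populations,
    decay_envelope,
    quantify,
    to_mz_profile,
)
from ftms2d.chemistry import paired_ladders
from ftms2d.geometry import PRESETS, Calibration, fold_frequency
from ftms2d.metrology import PeakMeasurement, ScanProfile, measure_snr, pick_peaks
from ftms2d.processing import Spectrum2D, ft_2d
from ftms2d.simulate import SignalComponent, SimulationPlan, plan_from_peptides, simulate_2d


def _peak_at(mz, height=10.0):
    return PeakMeasurement(centroid=mz, height=height, fwhm=0.01, snr=100.0, index=0)


# ---------------------------------------------------------------------------
# added-up spectrum
# ---------------------------------------------------------------------------

def _toy_spectrum(matrix):
    ny, nx = matrix.shape
    return Spectrum2D(
        matrix=matrix,
        v_axis=np.arange(ny, dtype=float),
        h_axis=np.arange(nx, dtype=float) + 1.0,
        params=PRESETS["nb4k"],
    )


def test_added_up_single_row_identity():
    rng = np.random.default_rng(0)
    m = rng.standard_normal((8, 300))
    spec = _toy_spectrum(m)
    from ftms2d.processing import baseline_correct

    prof = added_up_spectrum(spec, [3])
    assert np.allclose(prof.intensity, baseline_correct(m[3]))
    with pytest.raises(IndexError):
        added_up_spectrum(spec, [99])


def test_added_up_snr_gain_scales_like_sqrt_n():
    """Four rows of i.i.d. noise with a common peak: ~2x S/N gain."""
    gains = []
    for seed in range(12):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((4, 3000))
        m[:, 1500:1503] += [20.0, 40.0, 20.0]
        spec = _toy_spectrum(m)
        single = added_up_spectrum(spec, [0])
        summed = added_up_spectrum(spec, [0, 1, 2, 3])
        pk1 = max(pick_peaks(single, 5.0), key=lambda p: p.height)
        pk4 = max(pick_peaks(summed, 5.0), key=lambda p: p.height)
        gains.append(measure_snr(summed, pk4) / measure_snr(single, pk1))
    assert np.mean(gains) == pytest.approx(2.0, rel=0.25)


# ---------------------------------------------------------------------------
# assignment and coverage
# ---------------------------------------------------------------------------

def test_complete_ladder_gives_full_coverage(histone_pair):
    k7, k16 = histone_pair
    lad_a, lad_b = paired_ladders(k7, k16, charges=(1,))
    peaks = [_peak_at(f.monoisotopic_mz) for f in lad_a + lad_b]
    res = assign_fragments(peaks, lad_a, lad_b, tol_ppm=1.0)
    assert res.coverage["K7ac"] == 1.0
    assert res.coverage["K16me3"] == 1.0
    assert not res.unassigned


def test_one_missing_bond_gives_96_percent(histone_pair):
    """Removing both fragments of one bond: 24/25 bonds = 96% coverage."""
    k7, k16 = histone_pair
    lad_a, lad_b = paired_ladders(k7, k16, charges=(1,))
    L = len(k7)
    drop_bond = 12
    keep = [
        f
        for f in lad_a + lad_b
        if not (
            (f.kind == "c" and f.length == drop_bond)
            or (f.kind == "z" and L - f.length == drop_bond)
        )
    ]
    peaks = [_peak_at(f.monoisotopic_mz) for f in keep]
    res = assign_fragments(peaks, lad_a, lad_b, tol_ppm=1.0)
    assert res.coverage["K7ac"] == pytest.approx(24 / 25)
    assert res.coverage["K7ac"] == pytest.approx(0.96)


def test_category3_members_attributed_by_mass_offset(histone_pair):
    """36.4 mDa/charge category-3 partners land on the right peptides."""
    k7, k16 = histone_pair
    lad_a, lad_b = paired_ladders(k7, k16, charges=(1,))
    c20a = next(f for f in lad_a if (f.kind, f.length) == ("c", 20))
    c20b = next(f for f in lad_b if (f.kind, f.length) == ("c", 20))
    assert c20a.category == 3
    peaks = [_peak_at(c20a.monoisotopic_mz), _peak_at(c20b.monoisotopic_mz)]
    res = assign_fragments(peaks, lad_a, lad_b, tol_ppm=5.0)
    assert {a.peptide for a in res.assignments} == {"K7ac", "K16me3"}
    for a in res.assignments:
        assert abs(a.mass_error_ppm) < 0.1


def test_coverage_monotone_in_assigned_peaks(histone_pair):
    k7, k16 = histone_pair
    lad_a, lad_b = paired_ladders(k7, k16, charges=(1,))
    rng = np.random.default_rng(4)
    frags = list(lad_a)
    rng.shuffle(frags)
    prev = 0.0
    for n in (5, 10, 20, 30, len(frags)):
        peaks = [_peak_at(f.monoisotopic_mz) for f in frags[:n]]
        cov = assign_fragments(peaks, lad_a, lad_b, tol_ppm=1.0).coverage["K7ac"]
        assert cov >= prev
        prev = cov


def test_shared_fragments_labelled_shared(histone_pair):
    k7, k16 = histone_pair
    lad_a, lad_b = paired_ladders(k7, k16, charges=(1,))
    c3 = next(f for f in lad_a if (f.kind, f.length) == ("c", 3))
    res = assign_fragments([_peak_at(c3.monoisotopic_mz)], lad_a, lad_b, tol_ppm=1.0)
    assert res.assignments[0].peptide == "shared"


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def _mock_assignments(histone_pair, heights_a, heights_b):
    k7, k16 = histone_pair
    lad_a, lad_b = paired_ladders(k7, k16, charges=(1,))
    from ftms2d.analysis import Assignment

    out = []
    cat3_a = [f for f in lad_a if f.category == 3][: len(heights_a)]
    cat3_b = [f for f in lad_b if f.category == 3][: len(heights_b)]
    for f, h in zip(cat3_a, heights_a):
        out.append(Assignment(_peak_at(f.monoisotopic_mz, h), f, "K7ac", 0.0))
    for f, h in zip(cat3_b, heights_b):
        out.append(Assignment(_peak_at(f.monoisotopic_mz, h), f, "K16me3", 0.0))
    return out


def test_quantify_symmetry_and_rescaling(histone_pair):
    a = _mock_assignments(histone_pair, [5.0, 7.0, 3.0], [5.0, 7.0, 3.0])
    q = quantify(a)
    assert q.site_fractions["K7ac"] == pytest.approx(0.5)
    scaled = _mock_assignments(histone_pair, [50.0, 70.0, 30.0], [50.0, 70.0, 30.0])
    q2 = quantify(scaled)
    assert q2.site_fractions == q.site_fractions


def test_quantify_single_peptide(histone_pair):
    a = _mock_assignments(histone_pair, [5.0, 7.0], [])
    q = quantify(a)
    assert q.site_fractions["K7ac"] == 1.0


def test_quantify_pair_fractions_sum_to_one(histone_pair):
    a = _mock_assignments(histone_pair, [6.0, 2.0], [2.0, 6.0])
    q = quantify(a)
    fr = q.pairs["fraction_K16me3"]
    assert np.allclose(fr + (1 - fr), 1.0)
    assert q.site_fractions["K16me3"] + q.site_fractions["K7ac"] == pytest.approx(1.0)


def test_mixture_ratio_recovered_from_simulation(histone_pair, calibration):
    """1:3 acetyl:trimethyl mixture recovered from category-3 pairs.

    Heterodyne long-record detection resolves the 36.4 mDa/charge pairs;
    the recovered acetyl fraction over seeds must land within 0.05 of 0.25.
    """
    k7, k16 = histone_pair
    lad_a, lad_b = paired_ladders(k7, k16, charges=(3, 4))
    cat3 = [
        f
        for f in lad_a + lad_b
        if f.category == 3 and f.kind == "c" and f.length in (16, 17, 18)
    ]
    params = PRESETS["nb4k"].replace(
        n_increments=64, detect_points=262144, detect_sample_rate=250_000.0
    )
    f_pre = calibration.mz_to_frequency(k7.mz(6))
    fold = fold_frequency(f_pre, params)
    fractions = []
    for seed in range(20):
        plan = plan_from_peptides(
            [(k7, 6, 1.0), (k16, 6, 3.0)],
            cat3,
            params,
            calibration,
            noise_sd=0.05,
            h_mixdown=175_000.0,
            seed=seed,
            include_precursor_channels=False,
        )
        spec = ft_2d(simulate_2d(plan))
        row = int(np.argmin(np.abs(spec.v_axis - fold.reduced_frequency)))
        mz_prof = to_mz_profile(added_up_spectrum(spec, [row]), calibration)
        res = assign_fragments(pick_peaks(mz_prof, 5.0), lad_a, lad_b, tol_ppm=8.0)
        q = quantify(res.assignments, categories=(3,))
        fractions.append(q.site_fractions["K7ac"])
    assert np.mean(fractions) == pytest.approx(0.25, abs=0.05)


# ---------------------------------------------------------------------------
# correlation populations
# ---------------------------------------------------------------------------

def test_group_means_match_per_fragment_table(nb4k_correlation_dataset, nb4k_assignments):
    d = nb4k_correlation_dataset
    rep = correlation_populations(
        d["spectrum"], nb4k_assignments.assignments, d["fold"].band_index
    )
    for name, grp in rep.table.groupby("peptide"):
        assert rep.group_means[name] == pytest.approx(grp["true_hz"].mean())
    a, b = sorted(rep.group_means)
    assert rep.mean_difference == pytest.approx(
        abs(rep.group_means[a] - rep.group_means[b])
    )


def test_single_precursor_groups_show_no_gap(histone_pair, calibration):
    """Both fragment groups driven by one precursor: difference ~ 0.

    The regular pair's category-2 fragments are simulated, but every
    fragment channel is modulated at the acetyl precursor's frequency, so
    the two attributed populations must coincide within fit precision.
    """
    from ftms2d.simulate import SignalComponent, SimulationPlan

    k7, k16 = histone_pair
    params = PRESETS["nb4k"].replace(detect_points=2048, n_increments=512)
    lad_a, lad_b = paired_ladders(k7, k16, charges=(2,))
    frags = [f for f in lad_a if f.category == 2][:8] + [
        f for f in lad_b if f.category == 2
    ][:8]
    f_pre = calibration.mz_to_frequency(k7.mz(6))
    comps = [
        SignalComponent(
            f.label, f_pre, calibration.mz_to_frequency(f.monoisotopic_mz), 0.2
        )
        for f in frags
    ]
    plan = SimulationPlan(comps, params, calibration, noise_sd=0.2, seed=5)
    spec = ft_2d(simulate_2d(plan))
    fold = fold_frequency(f_pre, params)
    row = int(np.argmin(np.abs(spec.v_axis - fold.reduced_frequency)))
    mz_prof = to_mz_profile(added_up_spectrum(spec, [row]), calibration)
    res = assign_fragments(pick_peaks(mz_prof, 5.0), lad_a, lad_b, tol_ppm=200.0)
    rep = correlation_populations(spec, res.assignments, fold.band_index)
    assert rep.mean_difference < 0.3
    assert rep.ranges_overlap


# ---------------------------------------------------------------------------
# decay envelope
# ---------------------------------------------------------------------------

def test_decay_rate_zero_cases(histone_pair, calibration):
    k7, _ = histone_pair
    params = PRESETS["nb1k"].replace(detect_points=1024)
    f_pre = calibration.mz_to_frequency(k7.mz(6))
    plan = plan_from_peptides([(k7, 6, 1.0)], [], params, calibration, decay_rate=0.0)
    lam, _ = decay_envelope(simulate_2d(plan), f_pre)
    assert abs(lam) < 0.5


def test_decay_rate_recovered(histone_pair, calibration):
    k7, _ = histone_pair
    params = PRESETS["nb1k"].replace(detect_points=2048)
    f_pre = calibration.mz_to_frequency(k7.mz(6))
    for seed in (0, 1):
        plan = plan_from_peptides(
            [(k7, 6, 1.0)], [], params, calibration, noise_sd=0.5, seed=seed
        )
        lam, table = decay_envelope(simulate_2d(plan), f_pre)
        assert lam == pytest.approx(20.0, abs=2.0)
        assert {"t1", "amplitude", "fit"} <= set(table.columns)
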
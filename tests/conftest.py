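import numpy as np
import pytest

from ftms2d.chemistry import paired_ladders
from ftms2d.geometry import PRESETS, fold_frequency
from ftms2d.pipeline import fixture_suite
from ftms2d.simulate import plan_from_peptides, simulate_2d


@pytest.fixture(scope="session")
def histone_pair():
    return fixture_suite("histone_pair")


@pytest.fixture(scope="session")
def calibration():
    return fixture_suite("calibration")


@pytest.fixture(scope="session")
def nb4k_correlation_dataset(histone_pair, calibration):
    """Seeded nb4k simulation of the peptide pair with all category-2
    fragments at charge 2, processed with the full chain including SANE.

    Shared by the correlation/assignment tests; noise is set so the fragment
    vertical S/N sits in the study's observed range (several tens).
    """
    from ftms2d.processing import ft_2d

    k7, k16 = histone_pair
    params = PRESETS["nb4k"].replace(detect_points=4096)
    lad_a, lad_b = paired_ladders(k7, k16, charges=(2,))
    frags = [f for f in lad_a + lad_b if f.category == 2]
    plan = plan_from_peptides(
        [(k7, 6, 1.0), (k16, 6, 1.0)],
        frags,
        params,
        calibration,
        noise_sd=0.5,
        seed=11,
    )
    transient = simulate_2d(plan)
    spectrum = ft_2d(transient, sane_rank=30, seed=11)
    f_pre = calibration.mz_to_frequency(k7.mz(6))
    fold = fold_frequency(f_pre, params)
    return {
        "transient": transient,
        "spectrum": spectrum,
        "ladders": (lad_a, lad_b),
        "fold": fold,
        "params": params,
        "f_precursor": f_pre,
        "true_gap_hz": f_pre - calibration.mz_to_frequency(k16.mz(6)),
    }


@pytest.fixture(scope="session")
def nb4k_assignments(nb4k_correlation_dataset, calibration):
    from ftms2d.analysis import added_up_spectrum, assign_fragments, to_mz_profile
    from ftms2d.metrology import pick_peaks

    d = nb4k_correlation_dataset
    row = int(np.argmin(np.abs(d["spectrum"].v_axis - d["fold"].reduced_frequency)))
    profile = added_up_spectrum(d["spectrum"], [row])
    mz_profile = to_mz_profile(profile, calibration)
    peaks = pick_peaks(mz_profile, snr_threshold=5.0)
    lad_a, lad_b = d["ladders"]
    return assign_fragments(peaks, lad_a, lad_b, tol_ppm=200.0)
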
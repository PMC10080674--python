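"""Correlation, coverage and label-free quantification on 2D spectra.

This is the study-level layer: summing precursor isotope rows into an
"added-up" MS/MS-equivalent spectrum, assigning c/z fragment peaks to the
two near-isobaric peptides (with the three-category mass scheme), per-site
label-free quantification from paired fragment intensities, Lorentzian
population statistics of fitted vertical frequencies (the sub-grid
precursor-fragment correlation measurement), and extraction of the t1
coherence-decay rate from the precursor channel.

Peptide attribution never uses the vertical position of a peak: it relies
only on the horizontal fragment mass category, so the fitted vertical
frequencies remain a measured outcome that can legitimately demonstrate
sub-grid correlation of unresolved precursors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal as sps

from .chemistry import FragmentIon
from .geometry import unfold_frequency
from .metrology import (
    PeakMeasurement,
    ScanProfile,
    extract_scan,
    lorentzian_fit,
    pick_peaks,
)
from .processing import Spectrum2D, baseline_correct

__all__ = [
    "to_mz_profile",
    "Assignment",
    "AssignmentResult",
    "QuantReport",
    "CorrelationReport",
    "added_up_spectrum",
    "assign_fragments",
    "quantify",
    "correlation_populations",
    "decay_envelope",
]


def to_mz_profile(profile: ScanProfile, calibration) -> ScanProfile:
    """Convert a frequency-axis scan to an increasing m/z axis.

    Frequency is inversely related to m/z, so the record is reversed; any
    non-positive frequency bins (the DC end of the axis) are dropped.
    """
    keep = profile.axis > 0
    mz = calibration.frequency_to_mz(profile.axis[keep])
    return ScanProfile(
        axis=mz[::-1],
        intensity=profile.intensity[keep][::-1],
        orientation=profile.orientation,
        source_coordinate=profile.source_coordinate,
    )


@dataclass(frozen=True)
class Assignment:
    peak: PeakMeasurement
    fragment: FragmentIon
    peptide: str          # parent peptide name, or "shared" for category 1
    mass_error_ppm: float
    isotope_shift: int = 0


@dataclass
class AssignmentResult:
    assignments: list[Assignment]
    coverage: dict[str, float]        # peptide name -> covered bonds / (L-1)
    unassigned: list[PeakMeasurement] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "fragment": a.fragment.label,
                "peptide": a.peptide,
                "mz": a.peak.centroid,
                "theoretical_mz": a.fragment.monoisotopic_mz,
                "error_ppm": a.mass_error_ppm,
                "category": a.fragment.category,
                "height": a.peak.height,
            }
            for a in self.assignments
        ]
        return pd.DataFrame(rows)


def added_up_spectrum(spectrum: Spectrum2D, rows) -> ScanProfile:
    """Sum baseline-corrected horizontal scans over precursor isotope rows.

    ``rows`` are vertical grid indices (e.g. the M..M+3 isotope rows of a
    precursor).  In narrowband mode those rows are far apart on the folded
    axis, so their noise is uncorrelated and the summed scan gains S/N like
    sqrt(n_rows) — the 2D equivalent of isolating the whole isotopic
    envelope in a quadrupole before MS/MS.
    """
    rows = list(rows)
    n_v = spectrum.matrix.shape[0]
    for r in rows:
        if not 0 <= int(r) < n_v:
            raise IndexError(f"row {r} outside 0..{n_v - 1}")
    acc = np.zeros(spectrum.matrix.shape[1])
    for r in rows:
        acc += baseline_correct(spectrum.matrix[int(r), :])
    return ScanProfile(
        axis=spectrum.h_axis.copy(),
        intensity=acc,
        orientation="horizontal",
        source_coordinate=float(np.mean([spectrum.v_axis[int(r)] for r in rows])),
    )


def assign_fragments(
    peaks: list[PeakMeasurement],
    ladder_a: list[FragmentIon],
    ladder_b: list[FragmentIon],
    tol_ppm: float,
) -> AssignmentResult:
    """Nearest-mass assignment of picked peaks (centroids on the m/z scale).

    Category-1 fragments are identical in both peptides and are labelled
    "shared"; ties between equal-mass candidates are broken by ppm error,
    then in favour of the shared label.  Sequence coverage counts the
    inter-residue bonds supported by at least one assigned c or z fragment,
    divided by L-1.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    candidates = list(ladder_a) + list(ladder_b)
    cand_mz = np.array([f.monoisotopic_mz for f in candidates])
    order = np.argsort(cand_mz)
    cand_mz = cand_mz[order]
    candidates = [candidates[i] for i in order]

    assignments: list[Assignment] = []
    unassigned: list[PeakMeasurement] = []
    for peak in peaks:
        err_ppm = (peak.centroid - cand_mz) / cand_mz * 1e6
        best = None
        for j in np.argsort(np.abs(err_ppm))[:4]:
            e = err_ppm[j]
            if abs(e) > tol_ppm:
                break
            frag = candidates[j]
            key = (abs(e), 0 if frag.category == 1 else 1)
            if best is None or key < best[0]:
                best = (key, frag, e)
        if best is None:
            unassigned.append(peak)
            continue
        _, frag, e = best
        peptide = "shared" if frag.category == 1 else frag.peptide
        assignments.append(
            Assignment(peak=peak, fragment=frag, peptide=peptide, mass_error_ppm=float(e))
        )

    coverage: dict[str, float] = {}
    for ladder in (ladder_a, ladder_b):
        if not ladder:
            continue
        name = ladder[0].peptide
        length = max(f.length for f in ladder) + 1
        bonds: set[int] = set()
        for a in assignments:
            if a.peptide not in (name, "shared"):
                continue
            f = a.fragment
            if a.peptide == "shared" or f.peptide == name:
                bonds.add(f.length if f.kind == "c" else length - f.length)
        coverage[name] = len(bonds) / (length - 1)
    return AssignmentResult(assignments=assignments, coverage=coverage, unassigned=unassigned)


@dataclass
class QuantReport:
    """Label-free relative abundances from paired fragment intensities."""

    pairs: pd.DataFrame                 # one row per fragment pair
    site_fractions: dict[str, float]    # peptide name -> mean fraction
    site_sd: dict[str, float]

    def fraction(self, peptide: str) -> float:
        return self.site_fractions[peptide]


def quantify(assignments: list[Assignment], categories: tuple[int, ...] = (3,)) -> QuantReport:
    """Relative quantification from fragment pairs that separate the peptides.

    For every fragment index (kind, length, charge) assigned in both
    peptides with a category in ``categories`` (default: the 36 mDa
    category-3 pairs), the intensity fraction ``I_a / (I_a + I_b)`` is
    computed; the site-level abundance is the unweighted mean over pairs.
    """
    by_key: dict[tuple[str, int, int], dict[str, float]] = {}
    names: list[str] = []
    for a in assignments:
        f = a.fragment
        if f.category not in categories or a.peptide == "shared":
            continue
        height = a.peak.lorentzian[2] if a.peak.lorentzian else a.peak.height
        by_key.setdefault((f.kind, f.length, f.charge), {})[a.peptide] = float(height)
        if a.peptide not in names:
            names.append(a.peptide)
    if len(names) == 1:
        # single-form sample: every pair is trivially all one peptide
        rows = [
            {"kind": k, "length": ln, "charge": z, names[0]: v[names[0]],
             f"fraction_{names[0]}": 1.0}
            for (k, ln, z), v in sorted(by_key.items())
        ]
        if not rows:
            raise ValueError("no quantifiable fragment pairs assigned")
        return QuantReport(pairs=pd.DataFrame(rows), site_fractions={names[0]: 1.0}, site_sd={names[0]: 0.0})
    if len(names) != 2:
        raise ValueError("quantification needs fragments of one or two peptides")
    a_name, b_name = sorted(names)
    rows = []
    for (k, ln, z), v in sorted(by_key.items()):
        if a_name not in v or b_name not in v:
            continue
        ia, ib = v[a_name], v[b_name]
        rows.append(
            {
                "kind": k,
                "length": ln,
                "charge": z,
                a_name: ia,
                b_name: ib,
                f"fraction_{a_name}": ia / (ia + ib),
            }
        )
    if not rows:
        raise ValueError("no quantifiable fragment pairs assigned")
    df = pd.DataFrame(rows)
    fr = df[f"fraction_{a_name}"].to_numpy()
    return QuantReport(
        pairs=df,
        site_fractions={a_name: float(fr.mean()), b_name: float(1.0 - fr.mean())},
        site_sd={a_name: float(fr.std(ddof=0)), b_name: float(fr.std(ddof=0))},
    )


@dataclass
class CorrelationReport:
    """Fitted vertical frequencies grouped by peptide attribution."""

    table: pd.DataFrame                # per fragment: peptide, fitted frequencies
    group_means: dict[str, float]      # true-frequency mean per peptide
    group_sd: dict[str, float]
    mean_difference: float             # |mean_a - mean_b|, Hz
    ranges_overlap: bool


def correlation_populations(
    spectrum: Spectrum2D,
    assignments: list[Assignment],
    band_index: int,
    search_window: tuple[float, float] | None = None,
    snr_threshold: float = 3.0,
) -> CorrelationReport:
    """Lorentzian-fit vertical centers per assigned fragment, by peptide.

    For each non-shared assignment the vertical precursor scan at the
    fragment's horizontal position is extracted, baseline-corrected, the
    precursor peak picked inside ``search_window`` (reduced Hz; default:
    everything above 5% of the band, to skip the modulation DC ridge) and
    refined with a Lorentzian fit.  Fitted centers are unfolded to true
    frequency with the given band index and grouped by the peptide
    attribution that came from the horizontal mass category alone.
    """
    if spectrum.calibration is None:
        raise ValueError("spectrum needs a calibration to locate fragment columns")
    lo, hi = search_window or (0.05 * spectrum.params.nyquist_vertical, float(spectrum.v_axis[-1]))
    rows = []
    for a in assignments:
        if a.peptide == "shared":
            continue
        f_h = spectrum.calibration.mz_to_frequency(a.fragment.monoisotopic_mz)
        scan = extract_scan(spectrum, "vertical", f_h)
        scan = baseline_correct(scan)
        peaks = [
            p
            for p in pick_peaks(scan, snr_threshold=snr_threshold)
            if lo <= p.centroid <= hi
        ]
        if not peaks:
            continue
        seed = max(peaks, key=lambda p: p.height)
        fit = lorentzian_fit(scan, seed)
        center = fit.lorentzian[0] if fit.lorentzian else fit.centroid
        if not lo <= center <= hi:
            continue
        rows.append(
            {
                "fragment": a.fragment.label,
                "peptide": a.peptide,
                "reduced_hz": center,
                "true_hz": unfold_frequency(center, band_index, spectrum.params),
                "fwhm_hz": fit.fwhm,
            }
        )
    df = pd.DataFrame(rows)
    groups = {} if df.empty else dict(iter(df.groupby("peptide")))
    if len(groups) < 2 or any(len(g) < 2 for g in groups.values()):
        raise ValueError("need at least two fitted fragments per peptide group")
    names = sorted(groups)
    means = {n: float(groups[n]["true_hz"].mean()) for n in names}
    sds = {n: float(groups[n]["true_hz"].std(ddof=0)) for n in names}
    spans = {n: (groups[n]["true_hz"].min(), groups[n]["true_hz"].max()) for n in names}
    a, b = names[:2]
    overlap = spans[a][0] <= spans[b][1] and spans[b][0] <= spans[a][1]
    return CorrelationReport(
        table=df,
        group_means=means,
        group_sd=sds,
        mean_difference=abs(means[a] - means[b]),
        ranges_overlap=bool(overlap),
    )


def decay_envelope(transient, f_horizontal: float) -> tuple[float, pd.DataFrame]:
    """Fit the t1 coherence-decay rate from one horizontal channel.

    The per-increment amplitude of the channel at ``f_horizontal`` (true Hz)
    is measured by projecting each t2 row onto a complex exponential; the
    modulation maxima trace the envelope ``A*exp(-lambda*t1)``, which is fit
    by least squares.  Returns ``(lambda, table)`` with the envelope points.
    """
    p = transient.params
    t2 = transient.t2
    probe = np.exp(-2j * np.pi * (f_horizontal - transient.h_mixdown) * t2)
    amp = np.abs(transient.matrix @ probe) * (2.0 / t2.size)
    t1 = transient.t1
    idx, _ = sps.find_peaks(amp)
    if idx.size < 3:
        # nearly unmodulated channel: use all points as the envelope
        idx = np.arange(amp.size)
    te, ae = t1[idx], amp[idx]

    def model(t, a0, lam):
        return a0 * np.exp(-lam * t)

    popt, _ = optimize.curve_fit(
        model, te, ae, p0=(float(ae.max()), 1.0), maxfev=20000
    )
    table = pd.DataFrame({"t1": te, "amplitude": ae, "fit": model(te, *popt)})
    return float(popt[1]), table
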
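"""ICR frequency geometry: calibration, narrowband foldovers, axis bookkeeping.

In FT-ICR MS the observable is the cyclotron frequency f = qB/(2*pi*m),
inversely proportional to m/z.  In narrowband 2D MS the encoding delay t1 is
incremented coarsely, so the precursor modulation frequency is undersampled:
after digital demodulation by the lowest pulse frequency the signal folds
into the band [0, fN] a known integer number of times.  This module owns the
m/z <-> frequency calibration, the fold/unfold arithmetic, vertical-axis
resolution bookkeeping, and the closed-form acquisition-duration model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Calibration",
    "AcquisitionParams",
    "FoldoverResult",
    "VerticalAxis",
    "PRESETS",
    "fold_frequency",
    "unfold_frequency",
    "vertical_axis",
    "acquisition_duration",
]


@dataclass(frozen=True)
class Calibration:
    """m/z <-> cyclotron-frequency conversion.

    One-term mode: ``f = A / (m/z)`` (equivalently A*z/M on the mass scale).
    Quadratic mode: ``m/z = A/f + B/f**2`` - the standard internal quadratic
    calibration; its inverse is the exact positive root of the quadratic in f.

    The default is anchored so that the 6+ monoisotopic precursor of the
    acetylated study peptide (m/z 493.9466) sits at 219,272 Hz on a 7 T
    magnet.
    """

    A: float
    B: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("calibration coefficient A must be positive")

    @classmethod
    def anchored(cls, mz: float = 493.9466, frequency: float = 219_272.0) -> "Calibration":
        return cls(A=mz * frequency)

    @classmethod
    def from_anchors(cls, p1: tuple[float, float], p2: tuple[float, float]) -> "Calibration":
        """Quadratic coefficients from two (frequency, m/z) anchor points."""
        (f1, mz1), (f2, mz2) = p1, p2
        # mz = A/f + B/f^2  ->  linear 2x2 system in (A, B)
        m = np.array([[1 / f1, 1 / f1**2], [1 / f2, 1 / f2**2]])
        a, b = np.linalg.solve(m, np.array([mz1, mz2]))
        return cls(A=float(a), B=float(b))

    def mz_to_frequency(self, mz, z: int = 1):
        """Cyclotron frequency of an ion at ``mz`` (per-charge mass scale).

        ``z`` is accepted so callers can pass (neutral-mass, charge) via
        ``mz = (M + z*proton)/z`` upstream; the conversion itself depends
        only on m/z.
        """
        mz = np.asarray(mz, dtype=float)
        if np.any(mz <= 0):
            raise ValueError("m/z must be positive")
        if self.B == 0.0:
            f = self.A / mz
        else:
            # mz*f^2 - A*f - B = 0, positive root
            f = (self.A + np.sqrt(self.A**2 + 4.0 * mz * self.B)) / (2.0 * mz)
        return float(f) if f.ndim == 0 else f

    def frequency_to_mz(self, f):
        f = np.asarray(f, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequency must be positive")
        mz = self.A / f + self.B / f**2
        return float(mz) if mz.ndim == 0 else mz


@dataclass(frozen=True)
class AcquisitionParams:
    """One narrowband acquisition geometry.

    ``nyquist_vertical`` (fN, Hz) is the vertical band width; real sampling
    of that band requires ``t1_increment = 1/(2*fN)``.  ``pulse_f_low`` /
    ``pulse_f_high`` bound the frequency range of all pulses; the vertical
    signal is demodulated by ``pulse_f_low`` before sampling, so a species
    at true frequency f folds ``floor((f - pulse_f_low)/fN)`` times.
    """

    name: str
    nyquist_vertical: float      # fN, Hz
    t1_increment: float          # s
    n_increments: int            # N
    pulse_f_low: float           # Hz
    pulse_f_high: float          # Hz
    detect_points: int = 16384
    detect_sample_rate: float = 714_285.714  # Hz (horizontal)
    per_scan_overhead: float = 1.0           # s: accumulation+transfer+irradiation+pulses+delays

    def __post_init__(self) -> None:
        if self.n_increments < 2:
            raise ValueError("need at least two t1 increments")
        if self.pulse_f_low >= self.pulse_f_high:
            raise ValueError("pulse_f_low must be below pulse_f_high")
        expected = 1.0 / (2.0 * self.nyquist_vertical)
        if not math.isclose(self.t1_increment, expected, rel_tol=1e-9):
            raise ValueError(
                "t1_increment must equal 1/(2*fN) for real sampling of the band"
            )

    @property
    def detect_length(self) -> float:
        return self.detect_points / self.detect_sample_rate

    @property
    def max_t1(self) -> float:
        return self.n_increments * self.t1_increment

    def replace(self, **kw) -> "AcquisitionParams":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


def _preset(name, f_n_khz, dt1_us, f_low_khz, f_high_khz=357.143) -> AcquisitionParams:
    return AcquisitionParams(
        name=name,
        nyquist_vertical=f_n_khz * 1e3,
        t1_increment=dt1_us * 1e-6,
        n_increments=1024,
        pulse_f_low=f_low_khz * 1e3,
        pulse_f_high=f_high_khz * 1e3,
    )


#: The four narrowband geometries of the study: Nyquist 10/4/2/1 kHz with
#: t1 increments 50/125/250/500 us and per-experiment pulse bands.
PRESETS: dict[str, AcquisitionParams] = {
    "nb10k": _preset("nb10k", 10, 50, 74.660),
    "nb4k": _preset("nb4k", 4, 125, 72.171),
    "nb2k": _preset("nb2k", 2, 250, 73.895),
    "nb1k": _preset("nb1k", 1, 500, 74.402),
}


@dataclass(frozen=True)
class FoldoverResult:
    band_index: int          # number of foldovers n >= 0
    reduced_frequency: float # Hz, within [0, fN]
    band_f_low: float
    band_f_high: float


def fold_frequency(f_true: float, params: AcquisitionParams) -> FoldoverResult:
    """Fold a true cyclotron frequency into the sampled vertical band.

    After demodulation by ``pulse_f_low`` the offset frequency is
    ``fd = f_true - pulse_f_low``; band index ``n = floor(fd/fN)``.  Real
    sampling at 2*fN aliases the in-band remainder ``r`` to ``r`` for even
    bands and ``fN - r`` for odd bands (mirror parity).
    """
    fn = params.nyquist_vertical
    fd = f_true - params.pulse_f_low
    if fd < 0:
        raise ValueError("frequency below the pulse band")
    n = int(fd // fn)
    r = fd - n * fn
    reduced = r if n % 2 == 0 else fn - r
    return FoldoverResult(
        band_index=n,
        reduced_frequency=reduced,
        band_f_low=params.pulse_f_low + n * fn,
        band_f_high=params.pulse_f_low + (n + 1) * fn,
    )


def unfold_frequency(reduced: float, band_index: int, params: AcquisitionParams) -> float:
    """Inverse of :func:`fold_frequency` given the band index."""
    fn = params.nyquist_vertical
    if not 0.0 <= reduced <= fn:
        raise ValueError("reduced frequency outside [0, fN]")
    r = reduced if band_index % 2 == 0 else fn - reduced
    return params.pulse_f_low + band_index * fn + r


@dataclass(frozen=True)
class VerticalAxis:
    point_spacing: float   # Hz between adjacent spectral points
    min_peak_fwhm: float   # Hz, 1/max(t1) transform-limited linewidth
    max_t1: float          # s
    n_points: int


def vertical_axis(params: AcquisitionParams, zero_fills: int = 2) -> VerticalAxis:
    """Vertical (precursor) axis bookkeeping.

    With N real samples at 2*fN, ``zero_fills`` record doublings give
    ``N * 2**zero_fills / 2`` spectral points over [0, fN], i.e. spacing
    ``2*fN / (N * 2**zero_fills)``.  The transform-limited peak width
    ``1/(N*dt1)`` is set by the physical record and is zero-fill independent.
    """
    if zero_fills < 0:
        raise ValueError("zero_fills must be >= 0")
    n_pts = params.n_increments * 2**zero_fills // 2
    return VerticalAxis(
        point_spacing=2.0 * params.nyquist_vertical / (params.n_increments * 2**zero_fills),
        min_peak_fwhm=1.0 / params.max_t1,
        max_t1=params.max_t1,
        n_points=n_pts,
    )


def acquisition_duration(params: AcquisitionParams) -> float:
    """Total wall-clock duration of a 2D acquisition, in seconds.

    ``T = N*(overhead + T_detect) + dt1*N*(N-1)/2``: the per-scan costs plus
    the triangular sum of the incremented encoding delay, which grows as
    O(N^2) and dominates for narrow bands (large dt1).
    """
    n = params.n_increments
    return n * (params.per_scan_overhead + params.detect_length) + (
        params.t1_increment * n * (n - 1) / 2.0
    )
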
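"""Forward model of the narrowband 2D FT-ICR experiment.

The pulse sequence modulates each precursor's radius with its own cyclotron
frequency as a function of the encoding delay t1; because electron-capture
dissociation yield is radius dependent, every fragment's abundance is
modulated at its precursor's frequency.  The simulator renders this as

    s(t1, t2) = sum_k A_k * g_k(t1) * exp(-lambda*t1)
                      * cos(2*pi*fh_k*t2 + phi_k) * exp(-t2/tau2)  + noise

with a raised-cosine modulation law ``g = (1 + cos(2*pi*fd*t1))/2`` for
fragment channels (maximal fragmentation at t1 = 0) and its complement
``1 - g`` for the surviving-precursor channel, so the two channels are in
antiphase and sum to the unmodulated envelope.  ``fd`` is the precursor
frequency after digital demodulation by the lowest pulse frequency; coarse
t1 sampling then aliases it into [0, fN] exactly as the fold arithmetic in
:mod:`ftms2d.geometry` predicts.  Coherence loss of the ion packet during
the encoding delay is a single exponential on the t1 envelope (default rate
20 1/s, i.e. a 50 ms characteristic time).

Horizontal detection is broadband real sampling by default; an optional
heterodyne offset (``h_mixdown``) shifts the detected band down so that
desk-scale records can resolve the 36 mDa near-isobaric fragment pairs
without the instrument's half-million-point transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemistry import FragmentIon, Peptide
from .geometry import AcquisitionParams, Calibration
from .processing import PhaseModel

__all__ = [
    "SignalComponent",
    "SimulationPlan",
    "Transient2D",
    "ReferenceTransient",
    "simulate_2d",
    "simulate_reference_msms",
    "plan_from_peptides",
]


@dataclass(frozen=True)
class SignalComponent:
    """One precursor-fragment correlation channel of the forward model."""

    label: str
    f_vertical: float       # true precursor cyclotron frequency, Hz
    f_horizontal: float     # true detected (fragment or precursor) frequency, Hz
    amplitude: float
    channel: str = "fragment"   # "fragment" (g) or "precursor" (1 - g)
    phase: float = 0.0          # detection phase at t2 = 0, rad

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("component amplitude must be positive")
        if self.channel not in ("fragment", "precursor"):
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass
class SimulationPlan:
    """Everything needed to render one 2D transient with known ground truth."""

    components: list[SignalComponent]
    params: AcquisitionParams
    calibration: Calibration
    decay_rate: float = 20.0     # lambda, 1/s, t1 coherence decay
    tau2: float = 0.5            # s, horizontal (detection) damping constant
    noise_sd: float = 0.0        # additive white noise, intensity units
    h_mixdown: float = 0.0       # Hz, heterodyne offset of horizontal detection
    phase: PhaseModel | None = None  # injected instrument phase (ground truth)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_rate < 0 or self.noise_sd < 0 or self.tau2 <= 0:
            raise ValueError("decay_rate/noise_sd must be >= 0 and tau2 > 0")


@dataclass
class Transient2D:
    """Raw time-domain matrix (t1 rows x t2 columns) plus ground truth."""

    matrix: np.ndarray
    params: AcquisitionParams
    h_mixdown: float
    ground_truth: list[dict] = field(default_factory=list)
    seed: int = 0
    noise_sd: float = 0.0
    calibration: Calibration | None = None

    @property
    def t1(self) -> np.ndarray:
        return np.arange(self.params.n_increments) * self.params.t1_increment

    @property
    def t2(self) -> np.ndarray:
        return np.arange(self.matrix.shape[1]) / self.params.detect_sample_rate


@dataclass
class ReferenceTransient:
    """Single-scan MS/MS transient used to calibrate the phase model."""

    signal: np.ndarray
    sample_rate: float
    h_mixdown: float
    peaks: list[dict]   # per peak: true frequency, amplitude, injected phase


def _check_in_band(f: float, params: AcquisitionParams, what: str) -> None:
    if not params.pulse_f_low <= f <= params.pulse_f_high:
        raise ValueError(
            f"{what} frequency {f:.1f} Hz outside pulse band "
            f"[{params.pulse_f_low:.1f}, {params.pulse_f_high:.1f}]"
        )


def simulate_2d(plan: SimulationPlan) -> Transient2D:
    """Render the 2D transient for a plan.  Same seed, same bits."""
    p = plan.params
    t1 = np.arange(p.n_increments) * p.t1_increment
    t2 = np.arange(p.detect_points) / p.detect_sample_rate
    damp2 = np.exp(-t2 / plan.tau2)
    damp1 = np.exp(-plan.decay_rate * t1)

    rows = np.empty((len(plan.components), t1.size))
    cols = np.empty((len(plan.components), t2.size))
    truth = []
    for i, c in enumerate(plan.components):
        _check_in_band(c.f_vertical, p, "vertical")
        _check_in_band(c.f_horizontal, p, "horizontal")
        fh = c.f_horizontal - plan.h_mixdown
        if not 0.0 < fh < p.detect_sample_rate / 2.0:
            raise ValueError(
                f"detected frequency {fh:.1f} Hz outside (0, fs/2) after mixdown"
            )
        fd = c.f_vertical - p.pulse_f_low
        g = 0.5 * (1.0 + np.cos(2.0 * np.pi * fd * t1))
        if c.channel == "precursor":
            g = 1.0 - g
        phi = c.phase
        if plan.phase is not None:
            phi = phi + plan.phase.horizontal_phase(c.f_horizontal)
        rows[i] = c.amplitude * g * damp1
        cols[i] = np.cos(2.0 * np.pi * fh * t2 + phi) * damp2
        truth.append(
            {
                "label": c.label,
                "f_vertical": c.f_vertical,
                "f_horizontal": c.f_horizontal,
                "amplitude": c.amplitude,
                "channel": c.channel,
                "phase": phi,
            }
        )
    s = rows.T @ cols
    if plan.noise_sd > 0:
        rng = np.random.default_rng(plan.seed)
        s = s + rng.normal(0.0, plan.noise_sd, size=s.shape)
    if not np.all(np.isfinite(s)):  # pragma: no cover - defensive
        raise FloatingPointError("non-finite transient")
    return Transient2D(
        matrix=s,
        params=p,
        h_mixdown=plan.h_mixdown,
        ground_truth=truth,
        seed=plan.seed,
        noise_sd=plan.noise_sd,
        calibration=plan.calibration,
    )


def simulate_reference_msms(plan: SimulationPlan) -> ReferenceTransient:
    """Single-row transient with the plan's phase model injected.

    Stands in for the conventional MS/MS reference acquisitions from which
    the horizontal quadratic phase-correction coefficients are determined.
    """
    p = plan.params
    t2 = np.arange(p.detect_points) / p.detect_sample_rate
    damp2 = np.exp(-t2 / plan.tau2)
    sig = np.zeros_like(t2)
    peaks = []
    for c in plan.components:
        _check_in_band(c.f_horizontal, p, "horizontal")
        fh = c.f_horizontal - plan.h_mixdown
        if not 0.0 < fh < p.detect_sample_rate / 2.0:
            raise ValueError("detected frequency outside (0, fs/2) after mixdown")
        phi = c.phase
        if plan.phase is not None:
            phi = phi + plan.phase.horizontal_phase(c.f_horizontal)
        sig += c.amplitude * np.cos(2.0 * np.pi * fh * t2 + phi) * damp2
        peaks.append(
            {"f_horizontal": c.f_horizontal, "amplitude": c.amplitude, "phase": phi}
        )
    if plan.noise_sd > 0:
        rng = np.random.default_rng(plan.seed)
        sig = sig + rng.normal(0.0, plan.noise_sd, size=sig.shape)
    return ReferenceTransient(
        signal=sig,
        sample_rate=p.detect_sample_rate,
        h_mixdown=plan.h_mixdown,
        peaks=peaks,
    )


def plan_from_peptides(
    precursors: list[tuple[Peptide, int, float]],
    fragments: list[FragmentIon],
    params: AcquisitionParams,
    calibration: Calibration,
    fragmentation_efficiency: float = 0.2,
    include_precursor_channels: bool = True,
    **plan_kwargs,
) -> SimulationPlan:
    """Build a simulation plan from peptide chemistry.

    Each fragment is attributed to its parent precursor by peptide name; its
    vertical modulation frequency is the parent's cyclotron frequency and
    its amplitude the parent abundance times the fragmentation efficiency.
    """
    by_name = {}
    components: list[SignalComponent] = []
    for pep, z, abundance in precursors:
        f_p = calibration.mz_to_frequency(pep.mz(z))
        by_name[pep.name] = (f_p, abundance)
        if include_precursor_channels:
            components.append(
                SignalComponent(
                    label=f"{pep.name} [M+{z}H]{z}+",
                    f_vertical=f_p,
                    f_horizontal=f_p,
                    amplitude=abundance,
                    channel="precursor",
                )
            )
    for frag in fragments:
        if frag.peptide not in by_name:
            raise ValueError(f"fragment {frag.label} has no precursor {frag.peptide!r}")
        f_p, abundance = by_name[frag.peptide]
        components.append(
            SignalComponent(
                label=f"{frag.peptide} {frag.label}",
                f_vertical=f_p,
                f_horizontal=calibration.mz_to_frequency(frag.monoisotopic_mz),
                amplitude=abundance * fragmentation_efficiency,
                channel="fragment",
            )
        )
    return SimulationPlan(
        components=components, params=params, calibration=calibration, **plan_kwargs
    )
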
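# Methods

## Signal model

The simulator renders the narrowband 2D FT-ICR pulse sequence as a sum of
separable precursor–fragment channels:

```
s(t₁, t₂) = Σ_k A_k · g_k(t₁) · e^(−λ t₁) · cos(2π f_h,k t₂ + φ_k) · e^(−t₂/τ₂) + ε
```

- **Modulation law.** Fragment channels use a raised cosine
  `g(t₁) = (1 + cos 2π f_d t₁)/2` at the precursor's demodulated frequency
  `f_d = f_p − f_low` (`f_low` = lowest pulse frequency); the surviving
  precursor channel uses the complement `1 − g`, so the two channels are in
  antiphase and sum to the unmodulated envelope. The underlying physics
  (radius-dependent ECD yield) prescribes periodic modulation at *f_p* but
  no specific functional form; the raised cosine is the minimal bounded
  law and reproduces the observed phenomenology. The modulation phase at
  `t₁ = 0` is fixed at maximal fragmentation, `g(0) = 1`.
- **Coherence decay.** Ion-packet decoherence during the encoding delay is
  a single exponential on the *t₁* envelope with rate λ (default
  **20 s⁻¹**, i.e. a 50 ms characteristic time — the study condition).
  Decay acts on *t₁* only; *t₂* damping is a separate constant τ₂
  (default 0.5 s, unprinted, chosen so horizontal lines are
  transform-limited on desk-scale records; only trends, never absolute
  linewidths, are asserted against it).
- **Noise** is i.i.d. Gaussian, seeded. The default `noise_sd = 0.5` in
  the end-to-end configuration was calibrated so that the fragment
  vertical S/N of the 4 kHz simulation falls in the several-tens range the
  study reports for that geometry; with the same seed the transient is
  bit-identical.
- **Undersampling.** The vertical dimension is sampled at `Δt₁ = 1/(2 f_N)`.
  The simulator evaluates the modulation at the true demodulated frequency;
  coarse sampling then aliases it exactly as the fold arithmetic predicts
  (band `n = floor(f_d/f_N)`, mirror parity for odd bands). Fold and unfold
  are exact inverses and are exercised by round-trip property tests.
- **Heterodyne option.** Horizontal detection is broadband real sampling
  (714.286 kHz) by default. An optional mixdown offset shifts the detected
  band so that desk-scale records (≤ 256k points) reach the line spacing
  needed to resolve the 36.4 mDa/charge category-3 pairs, which the
  instrument resolves with 512k-point broadband transients. Ground truth
  and axes carry the offset, so downstream *m/z* calibration is unchanged.

## Chemistry

Residue compositions and a fixed IUPAC/NIST isotope table are pinned in
`constants.py`; charging uses the proton mass 1.007276 Da with
`m/z = (M + z·p)/z`. ECD conventions: `c_n = Σ res(1..n) + NH₃`,
`z•_m = y_m − NH₂`, giving the exact closure
`c_n + z•_(L−n) = M + H` for every cleavage site. The printed study values
for z13³⁺ and the 6+ precursor are internally inconsistent with the
declared construct at the ~2 mDa/charge level; the conventions, not the
printed absolute *m/z* values, are treated as normative, and the computed
6+ monoisotopic *m/z* is 493.9447 against the printed 493.9466. Relative
quantities (42.0106/42.0470, 36.4 mDa, *m/z* 0.006, 14.0157, 2.7 Hz) all
reproduce.

Isotopologue fine structure is an exhaustive enumeration of heavy-isotope
substitution combinations up to a nominal shift, with multinomial
abundances; the returned (truncated) pattern is renormalized to sum to 1.
An independent brute-force per-atom enumeration validates it for small
formulas. For the acetylated precursor (C₁₂₉H₂₁₆N₄₄O₃₄S) the non-¹³C share
of M+1 computes to 12.9% across a 9.24 mDa spread.

## Calibration and axes

Default calibration is one-term `f = A/(m/z)` anchored at
(*m/z* 493.9466 → 219 272 Hz); the quadratic internal form
`m/z = A/f + B/f²` is available, with coefficients recoverable exactly from
two anchor points and an exact inverse. No calibration constants are
printed in the source material, so the vertical *m/z* ranges of the
narrowband tables are not used as anchors.

Both axes are zero-filled twice (record doubled twice) before the real
FFT, and bins up to Nyquist are kept: for 1024 increments this puts 2048
points across the vertical band — 4.88/1.95/0.98/0.49 Hz point spacing for
the 10/4/2/1 kHz presets. The conventional resolution figure `1/(N·Δt₁)`
(19.5 ms⁻¹ → 19.5 Hz at 10 kHz) is reported as bookkeeping; note the
*measured* absorption-mode FWHM of a truncated record is ~0.6/T and can
legitimately sit below that figure.

## Processing chain

Order: sine-bell apodization (maximum at the 0.15 fraction; squared
variant available for 1D records) → zero-fill → row FFT → quadratic phase
correction to absorption → optional low-rank denoising of the *t₁*
interferogram → sine-bell/zero-fill/FFT along *t₁* → linear vertical
phase. Every step is appended to the spectrum's provenance, and identical
transient + provenance give identical output.

- **Phase model.** The horizontal quadratic is fit from a reference 1D
  MS/MS transient with known peaks: the complex spectrum's argument is
  sampled at the sub-bin peak position (parabolic interpolation of the
  magnitude, linear interpolation of the unwrapped phase — off-bin
  sampling otherwise mixes dispersion into the estimate), unwrapped across
  peaks, and fit by least squares. Injected quadratics are recovered to
  <1% per coefficient; three exact samples determine the quadratic.
- **Denoising** is a seeded randomized rank-r projection along *t₁* with
  one residual re-injection pass (a second rank-r approximation of the
  residual is added back). It is exact on data of true rank ≤ r and cuts
  the spectral noise floor by >2× at rank 30 on 1024 increments.
  *Limitation:* when two modulation patterns are nearly parallel (here,
  2.7 Hz apart over a 128 ms record) and the S/N is low, the
  difference-direction singular value can fall below the noise floor and
  be truncated, biasing the two fitted populations toward each other. At
  the default (study-condition) S/N the residual compression is ≤ 0.1 Hz.
- **Baseline correction** subtracts a rolling 20th-percentile baseline
  with a window of 1/50 of the record (unspecified upstream; chosen so
  narrow peaks do not drag the baseline).

## Metrology

Noise is `1.4826 × MAD` of the signal-free region (5σ clipped,
iterated). Peaks are local maxima above `threshold × noise`, centroided by
a three-point parabola (the polynomial order of the original workflow is
unstated; the parabola is the recorded default), then optionally refined
by a least-squares Lorentzian over a ±3 FWHM window. Resolving power is
centroid/FWHM by construction. Edge peaks are measured but flagged;
a fit whose RMS residual exceeds 5× the scan noise is flagged as a poor
single-Lorentzian model (e.g. an unresolved doublet).

## Analysis

- **Added-up spectra** sum baseline-corrected horizontal scans over
  precursor isotope rows; in narrowband mode the rows' noise is
  uncorrelated, so S/N grows like √n (verified at n = 4).
- **Assignment** is nearest-mass within a ppm tolerance against both
  ladders; category-1 matches are labelled "shared". Coverage counts
  inter-residue bonds supported by ≥1 assigned c or z fragment over
  L−1 = 25 bonds (24/25 = 96%).
- **Quantification** pairs each fragment index assigned in both forms
  (default: category 3) and averages `I_a/(I_a+I_b)` unweighted — per-pair
  weights are not specified upstream. Fractions are invariant under global
  intensity rescaling. Desk-scale recovery of a 1:3 mixture gives
  0.224 ± 0.001 against a true 0.25: a small systematic underestimate from
  residual lineshape interference of pairs spaced 4–6.5 Hz on ~1 s
  records.
- **Correlation populations**: for each non-shared assignment, the
  vertical scan at the fragment's column is baseline-corrected, the
  precursor peak picked away from the modulation DC ridge, Lorentzian
  fitted, and the center unfolded to true frequency. Grouping uses *only*
  the horizontal mass category — never the vertical position — so the
  fitted frequencies are a genuine measurement of the correlation.
  Quantification defaults to the M..M+3 added-up rows while correlation
  uses monoisotopic rows only; both are configurable.
- **Decay extraction** projects each *t₂* row onto the channel's complex
  carrier, takes the modulation maxima as the envelope, and fits
  `A·e^(−λt₁)`; on 1 kHz-preset data with λ = 20 s⁻¹ the fit returns
  19.3–19.6 s⁻¹ across seeds.

## Problem sizes

Desk-scale defaults were chosen so the whole suite runs in minutes on one
core: 1024 increments × 4096 detection points for the correlation
demonstration (vs the instrument's 1024 × 512k), 2048-point detection for
trend tests, and 64 × 256k heterodyne records for the near-isobaric
quantification. A full-size 512k-point horizontal record is a parameter
away (`detect_points`) but not exercised by the tests.

## What the synthetic data does and does not show

The generator reproduces the modulation mechanism, undersampling/foldover
arithmetic, coherence decay, line shapes and additive noise — enough to
validate the processing chain and the sub-grid correlation claim on known
ground truth. It does not model ion optics, space charge, isotopic
envelopes of fragments (fragment channels are monoisotopic unless
explicitly planned), harmonic/sideband artifacts, or scan-to-scan
variability. Passing tests therefore certify the algorithms, not
instrument performance; the experimental resolving powers and S/N of the
original datasets are expressly not reproduction targets (only their
qualitative trend with narrowing bandwidth is).
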
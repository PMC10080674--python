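"""Pinned physical constants: isotope table, residue compositions, ion-type offsets.

All masses in Da (unified atomic mass units).  The isotope table is a fixed
IUPAC/NIST snapshot pinned here so that fine-structure abundances (e.g. the
share of non-13C isotopologues in an M+1 cluster) are reproducible to the
last digit regardless of upstream library updates.
"""

from __future__ import annotations

# (mass, abundance) per isotope, keyed by element symbol.
# First entry is the most abundant (monoisotopic reference) isotope.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.00307400443, 0.99636), (15.00010889888, 0.00364)],
    "O": [
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ],
    "S": [
        (31.9720711744, 0.9499),
        (32.9714589098, 0.0075),
        (33.967867004, 0.0425),
        (35.96708071, 0.0001),
    ],
    "P": [(30.97376199842, 1.0)],
}

#: Monoisotopic (most abundant isotope) mass per element.
MONO_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

#: Proton mass used for charging: m/z = (M_neutral + z * PROTON) / z.
PROTON = 1.007276466

# Residue (internal amino-acid) elemental compositions, 20-letter alphabet.
RESIDUES: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

# Post-translational modification composition deltas.
MODIFICATIONS: dict[str, dict[str, int]] = {
    "acetyl": {"C": 2, "H": 2, "O": 1},          # +42.0106 Da
    "trimethyl": {"C": 3, "H": 6},               # +42.0470 Da (3x CH2)
    "biotinyl": {"C": 10, "H": 14, "N": 2, "O": 2, "S": 1},
}

# Neutral-fragment assembly constants (ECD c/z-radical convention):
#   peptide neutral M    = sum(residues) + H2O
#   c_n neutral          = sum(residues 1..n) + NH3
#   z*_m neutral         = y_m neutral - NH2  (y_m = sum(residues L-m+1..L) + H2O)
H2O: dict[str, int] = {"H": 2, "O": 1}
NH3: dict[str, int] = {"N": 1, "H": 3}
NH2: dict[str, int] = {"N": 1, "H": 2}
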
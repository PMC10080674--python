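"""Peptide ion chemistry: parsing, masses, ECD fragment ladders, fine structure.

The study system is a pair of 26-residue histone H3 tail peptides (residues
21-44 plus a C-terminal GK carrying a biotinyl tag) that share one sequence
and differ only in a near-isobaric modification: one is acetylated (K7 of the
construct, K27 of histone H3), the other trimethylated (K16, i.e. H3 K36).
Acetylation adds C2H2O (42.0106 Da), trimethylation 3xCH2 (42.0470 Da); the
two constructs therefore differ by 36.385 mDa, which at charge 6 is an m/z
gap of 0.006.

ECD cleaves the backbone N-Calpha bond giving c (amide-terminated N-terminal)
and z-radical (C-terminal) fragments.  For a pair of peptides that differ in
two modification sites, every fragment falls into one of three categories:

1. the fragment span covers neither differential site - identical mass in
   both peptides ("shared");
2. the span covers exactly one site - masses differ by a full modification
   (~42 Da), trivially separated;
3. the span covers both sites - masses differ by trimethyl - acetyl =
   36.385 mDa, the near-isobaric case that stresses the mass analyser.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .constants import H2O, ISOTOPES, MODIFICATIONS, MONO_MASS, NH2, NH3, PROTON, RESIDUES

Formula = dict[str, int]

__all__ = [
    "Peptide",
    "Modification",
    "FragmentIon",
    "IsotopePattern",
    "parse_peptide",
    "read_peptides",
    "monoisotopic_mass",
    "formula_mass",
    "fragment_ladder",
    "paired_ladders",
    "categorize_pair",
    "ladder_frame",
    "isotopologue_pattern",
]


def _merge(*formulas: Formula, scale: int = 1) -> Formula:
    out: Formula = {}
    for f in formulas:
        for el, n in f.items():
            out[el] = out.get(el, 0) + n
    if scale != 1:
        out = {el: n * scale for el, n in out.items()}
    return {el: n for el, n in out.items() if n != 0}


def formula_mass(formula: Formula) -> float:
    """Monoisotopic mass of an elemental formula (most abundant isotopes)."""
    try:
        return sum(MONO_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - trivial re-raise
        raise ValueError(f"unknown element symbol: {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class Modification:
    """A named composition delta attached to one residue."""

    name: str
    composition: Formula

    @classmethod
    def by_name(cls, name: str) -> "Modification":
        key = _MOD_ALIASES.get(name.lower(), name.lower())
        if key not in MODIFICATIONS:
            raise ValueError(f"unknown modification: {name!r}")
        return cls(key, dict(MODIFICATIONS[key]))

    @property
    def mass(self) -> float:
        return formula_mass(self.composition)


_MOD_ALIASES = {
    "ac": "acetyl",
    "acetylation": "acetyl",
    "3m": "trimethyl",
    "me3": "trimethyl",
    "trimethylation": "trimethyl",
    "biot": "biotinyl",
    "biotin": "biotinyl",
    "biotinylation": "biotinyl",
}


@dataclass(frozen=True)
class Peptide:
    """A linear peptide with positioned modifications.

    ``modifications`` maps 1-based residue positions to :class:`Modification`.
    Terminal groups are a free amine / free acid (the neutral mass includes
    one H2O); modified variants are expressed through ``modifications``.
    """

    name: str
    sequence: str
    modifications: dict[int, Modification] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [r for r in self.sequence if r not in RESIDUES]
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(set(bad))}")
        for pos in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def composition(self) -> Formula:
        parts = [RESIDUES[r] for r in self.sequence]
        parts.append(H2O)
        parts.extend(m.composition for m in self.modifications.values())
        return _merge(*parts)

    @property
    def monoisotopic_mass(self) -> float:
        return formula_mass(self.composition())

    def mz(self, charge: int) -> float:
        return (self.monoisotopic_mass + charge * PROTON) / charge

    def span_composition(self, start: int, stop: int) -> Formula:
        """Composition of residues ``start..stop`` (1-based, inclusive), with
        the modifications falling inside the span but without terminal groups."""
        parts = [RESIDUES[r] for r in self.sequence[start - 1 : stop]]
        parts.extend(
            m.composition for p, m in self.modifications.items() if start <= p <= stop
        )
        return _merge(*parts)


def monoisotopic_mass(entity: "Peptide | Modification | Formula | str") -> float:
    """Monoisotopic mass of a peptide, modification, formula dict, or mod name."""
    if isinstance(entity, Peptide):
        return entity.monoisotopic_mass
    if isinstance(entity, Modification):
        return entity.mass
    if isinstance(entity, str):
        return Modification.by_name(entity).mass
    return formula_mass(entity)


_BRACKET = re.compile(r"\[([A-Z])\+([A-Za-z0-9]+)\]|\[([A-Z])\]|([A-Z])")


def parse_peptide(spec: str, name: str = "") -> Peptide:
    """Parse bracket notation, e.g. ``ATKAAR[K+ac]SAPATGGVKKPHRYRPG[G][K+biot]``.

    Plain ``[X]`` brackets are allowed as visual emphasis and are equivalent
    to the bare letter.  A structured multi-line form is also accepted::

        name: K7ac
        sequence: ATKAARKSAPATGGVKKPHRYRPGGK
        mods: 7:acetyl, 26:biotinyl
    """
    spec = spec.strip()
    if "\n" in spec or spec.lower().startswith(("name:", "sequence:")):
        return _parse_block(spec, name)
    seq_parts: list[str] = []
    mods: dict[int, Modification] = {}
    pos = 0
    cursor = 0
    for m in _BRACKET.finditer(spec):
        if m.start() != cursor:
            raise ValueError(f"unparseable peptide spec near {spec[cursor:m.start()]!r}")
        cursor = m.end()
        pos += 1
        letter = m.group(1) or m.group(3) or m.group(4)
        seq_parts.append(letter)
        if m.group(2):
            if pos in mods:
                raise ValueError(f"duplicate modification at position {pos}")
            mods[pos] = Modification.by_name(m.group(2))
    if cursor != len(spec):
        raise ValueError(f"unparseable peptide spec near {spec[cursor:]!r}")
    return Peptide(name=name, sequence="".join(seq_parts), modifications=mods)


def _parse_block(spec: str, name: str) -> Peptide:
    fields: dict[str, str] = {}
    for line in spec.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.strip()
    if "sequence" not in fields:
        raise ValueError("structured peptide block needs a 'sequence:' line")
    mods: dict[int, Modification] = {}
    for item in filter(None, (s.strip() for s in fields.get("mods", "").split(","))):
        p, _, mname = item.partition(":")
        pos = int(p)
        if pos in mods:
            raise ValueError(f"duplicate modification at position {pos}")
        mods[pos] = Modification.by_name(mname.strip())
    return Peptide(
        name=fields.get("name", name),
        sequence=fields["sequence"],
        modifications=mods,
    )


def read_peptides(path) -> list[Peptide]:
    """Read a FASTA-like file of bracket-notation peptides (``>name`` headers)."""
    peptides: list[Peptide] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    peptides.append(parse_peptide("".join(chunks), name=name))
                name, chunks = line[1:].strip(), []
            elif line:
                chunks.append(line)
    if name is not None:
        peptides.append(parse_peptide("".join(chunks), name=name))
    return peptides


@dataclass(frozen=True)
class FragmentIon:
    """One entry of an ECD c / z-radical ladder."""

    kind: str                  # "c" or "z"
    length: int                # residues counted from the respective terminus
    charge: int
    composition: Formula
    peptide: str = ""          # name of the parent peptide
    category: int | None = None

    @property
    def neutral_mass(self) -> float:
        return formula_mass(self.composition)

    @property
    def monoisotopic_mz(self) -> float:
        return (self.neutral_mass + self.charge * PROTON) / self.charge

    @property
    def label(self) -> str:
        return f"{self.kind}{self.length}^{self.charge}+"


def fragment_ladder(
    peptide: Peptide,
    kinds: tuple[str, ...] = ("c", "z"),
    charges: tuple[int, ...] = (1,),
) -> list[FragmentIon]:
    """Full c_n / z*_m ladders (n, m = 1..L-1) at the requested charge states.

    Neutral-mass conventions: ``c_n = sum(residues 1..n) + NH3`` and
    ``z*_m = y_m - NH2`` with ``y_m = sum(residues L-m+1..L) + H2O``, i.e. the
    standard radical z-dot product of N-Calpha cleavage.  Mass closure:
    ``c_n + z*_(L-n) = M + (NH3 - NH2) = M + H`` for every n.
    """
    L = len(peptide)
    out: list[FragmentIon] = []
    for kind in kinds:
        if kind not in ("c", "z"):
            raise ValueError(f"unsupported fragment kind: {kind!r}")
        for n in range(1, L):
            if kind == "c":
                comp = _merge(peptide.span_composition(1, n), NH3)
            else:
                comp = _merge(peptide.span_composition(L - n + 1, L), H2O, _neg(NH2))
            for z in charges:
                out.append(
                    FragmentIon(kind, n, z, comp, peptide=peptide.name)
                )
    return out


def _neg(f: Formula) -> Formula:
    return {el: -n for el, n in f.items()}


def categorize_pair(pep_a: Peptide, pep_b: Peptide, kind: str, length: int) -> int:
    """Scheme of three fragment categories for a same-sequence peptide pair.

    Category 1: the fragment span covers no differential modification site;
    2: it covers the sites of exactly one peptide; 3: it covers differential
    sites of both peptides (near-isobaric pair).
    """
    if pep_a.sequence != pep_b.sequence:
        raise ValueError("category scheme requires a same-sequence peptide pair")
    L = len(pep_a)
    if kind == "c":
        span = range(1, length + 1)
    else:
        span = range(L - length + 1, L + 1)
    diff_a = {
        p for p, m in pep_a.modifications.items() if pep_b.modifications.get(p) != m
    }
    diff_b = {
        p for p, m in pep_b.modifications.items() if pep_a.modifications.get(p) != m
    }
    hit_a = any(p in diff_a for p in span)
    hit_b = any(p in diff_b for p in span)
    if hit_a and hit_b:
        return 3
    if hit_a or hit_b:
        return 2
    return 1


def paired_ladders(
    pep_a: Peptide,
    pep_b: Peptide,
    kinds: tuple[str, ...] = ("c", "z"),
    charges: tuple[int, ...] = (1,),
) -> tuple[list[FragmentIon], list[FragmentIon]]:
    """Fragment ladders of both peptides with their pair categories filled in."""
    lad_a = fragment_ladder(pep_a, kinds, charges)
    lad_b = fragment_ladder(pep_b, kinds, charges)
    lad_a = [
        replace(f, category=categorize_pair(pep_a, pep_b, f.kind, f.length))
        for f in lad_a
    ]
    lad_b = [
        replace(f, category=categorize_pair(pep_a, pep_b, f.kind, f.length))
        for f in lad_b
    ]
    return lad_a, lad_b


def ladder_frame(fragments: list[FragmentIon]) -> pd.DataFrame:
    """Fragment ladder as a DataFrame (CSV-exportable)."""
    rows = []
    for f in fragments:
        formula = "".join(
            f"{el}{n}" for el, n in sorted(f.composition.items()) if n
        )
        rows.append(
            {
                "peptide": f.peptide,
                "kind": f.kind,
                "length": f.length,
                "charge": f.charge,
                "formula": formula,
                "mz": f.monoisotopic_mz,
                "category": f.category,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Isotopologue fine structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Isotopologue:
    label: str          # e.g. "13C" or "13C+15N"
    mass: float         # exact neutral mass, Da
    abundance: float    # fraction of the whole (truncated, renormalized) pattern


@dataclass(frozen=True)
class IsotopePattern:
    """Nominal-shift isotope pattern with per-shift fine structure.

    ``peaks[k]`` is ``(shift, centroid mass, total abundance)`` for nominal
    shift k; ``fine[k]`` lists the individual isotopologues of that shift.
    Abundances are normalized so the truncated pattern sums to one.
    """

    peaks: list[tuple[int, float, float]]
    fine: dict[int, list[Isotopologue]]

    def shift_total(self, shift: int) -> float:
        for s, _, a in self.peaks:
            if s == shift:
                return a
        raise KeyError(shift)


def _element_states(el: str, n_atoms: int, max_shift: int):
    """Enumerate heavy-isotope substitution states of one element pool.

    Yields ``(shift, mass_delta, probability, label_parts)`` where probability
    is the multinomial weight of placing the given heavy-isotope counts among
    ``n_atoms`` atoms.
    """
    isotopes = ISOTOPES[el]
    base_mass, base_ab = isotopes[0]
    heavies = []
    for mass, ab in isotopes[1:]:
        shift = round(mass - base_mass)
        heavies.append((shift, mass - base_mass, ab))
    states = []
    # counts per heavy isotope, bounded by total nominal shift
    ranges = [range(0, min(n_atoms, max_shift // h[0]) + 1) for h in heavies]
    for counts in itertools.product(*ranges):
        k = sum(counts)
        if k > n_atoms:
            continue
        shift = sum(c * h[0] for c, h in zip(counts, heavies))
        if shift > max_shift:
            continue
        delta = sum(c * h[1] for c, h in zip(counts, heavies))
        # multinomial coefficient * abundance product
        prob = base_ab ** (n_atoms - k)
        rem = n_atoms
        for c, h in zip(counts, heavies):
            prob *= math.comb(rem, c) * h[2] ** c
            rem -= c
        labels = []
        for c, h in zip(counts, heavies):
            if c:
                nominal = round(base_mass) + h[0]
                labels.append(f"{nominal}{el}" + (f"{c}" if c > 1 else ""))
        states.append((shift, delta, prob, labels))
    return states


def isotopologue_pattern(formula: Formula, max_shift: int) -> IsotopePattern:
    """Exhaustive isotopologue fine structure up to a nominal mass shift.

    Enumerates every combination of heavy-isotope substitutions whose total
    nominal shift is <= ``max_shift``, with exact masses from the pinned
    isotope table and multinomial abundances.  For large biomolecules the
    M+1 cluster splits into 13C, 2H, 15N, 17O and 33S isotopologues spanning
    >9 mDa - comparable to the 36 mDa acetyl/trimethyl mass gap that this
    package's peptide pair hinges on.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    mono = formula_mass(formula)
    # Combine element pools by dynamic programming over nominal shift.
    combos: list[tuple[int, float, float, tuple[str, ...]]] = [(0, 0.0, 1.0, ())]
    for el, n in sorted(formula.items()):
        if n <= 0:
            continue
        if el not in ISOTOPES:
            raise ValueError(f"unknown element symbol: {el!r}")
        states = _element_states(el, n, max_shift)
        new: list[tuple[int, float, float, tuple[str, ...]]] = []
        for shift0, d0, p0, lab0 in combos:
            for shift1, d1, p1, lab1 in states:
                if shift0 + shift1 > max_shift:
                    continue
                new.append((shift0 + shift1, d0 + d1, p0 * p1, lab0 + tuple(lab1)))
        combos = new
    total = sum(p for _, _, p, _ in combos)
    fine: dict[int, list[Isotopologue]] = {}
    for shift, delta, prob, labels in combos:
        label = "+".join(labels) if labels else "monoisotopic"
        fine.setdefault(shift, []).append(
            Isotopologue(label=label, mass=mono + delta, abundance=prob / total)
        )
    peaks = []
    for shift in sorted(fine):
        iso = sorted(fine[shift], key=lambda i: -i.abundance)
        fine[shift] = iso
        tot = sum(i.abundance for i in iso)
        centroid = sum(i.mass * i.abundance for i in iso) / tot
        peaks.append((shift, centroid, tot))
    return IsotopePattern(peaks=peaks, fine=fine)


def m1_fine_structure_share(formula: Formula, heavy_labels: tuple[str, ...] = ("2H", "15N", "17O", "33S")) -> float:
    """Fraction of the M+1 cluster carried by the listed non-13C isotopologues."""
    pat = isotopologue_pattern(formula, max_shift=1)
    total = pat.shift_total(1)
    part = sum(
        i.abundance for i in pat.fine[1] if i.label in heavy_labels
    )
    return part / total
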
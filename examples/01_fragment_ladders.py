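"""ECD fragment ladders of the acetylated vs trimethylated histone pair.

Builds the two 26-mer constructs, generates their c/z-radical ladders, and
shows the three-category mass scheme: shared fragments (identical mass),
one-site fragments (~42 Da apart), and two-site fragments 36.4 mDa apart —
the near-isobaric pairs that make this peptide pair hard to tell apart.
"""

from ftms2d import paired_ladders
from ftms2d.chemistry import ladder_frame, monoisotopic_mass
from ftms2d.pipeline import fixture_suite

k7ac, k16me3 = fixture_suite("histone_pair")
print(f"{k7ac.name}:   {k7ac.sequence}  mods {sorted(k7ac.modifications)}")
print(f"{k16me3.name}: {k16me3.sequence}  mods {sorted(k16me3.modifications)}")
print(f"neutral masses: {k7ac.monoisotopic_mass:.4f} / {k16me3.monoisotopic_mass:.4f} Da")
print(f"acetyl {monoisotopic_mass('acetyl'):.4f} Da, trimethyl {monoisotopic_mass('trimethyl'):.4f} Da")
print(f"pair mass gap: {(k16me3.monoisotopic_mass - k7ac.monoisotopic_mass)*1e3:.3f} mDa")
print(f"precursor m/z at 6+: {k7ac.mz(6):.4f} / {k16me3.mz(6):.4f} (dm/z {k16me3.mz(6)-k7ac.mz(6):.4f})")

lad_a, lad_b = paired_ladders(k7ac, k16me3, charges=(1, 3))
frame = ladder_frame(lad_a)
print("\nfirst c-ions of K7ac (category 1 = shared, 2 = one site, 3 = both sites):")
print(frame[(frame.kind == "c") & (frame.charge == 1)].head(8).to_string(index=False))

z13a = next(f for f in lad_a if (f.kind, f.length, f.charge) == ("z", 13, 3))
z13b = next(f for f in lad_b if (f.kind, f.length, f.charge) == ("z", 13, 3))
print(f"\nz13(3+) separation (category 2): m/z {z13b.monoisotopic_mz - z13a.monoisotopic_mz:.4f}")
c16a = next(f for f in lad_a if (f.kind, f.length, f.charge) == ("c", 16, 1))
c16b = next(f for f in lad_b if (f.kind, f.length, f.charge) == ("c", 16, 1))
print(f"c16 mass gap (category 3): {(c16b.neutral_mass - c16a.neutral_mass)*1e3:.2f} mDa")
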
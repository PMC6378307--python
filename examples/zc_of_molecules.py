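"""Carbon oxidation state of single molecules and average formulas.

Z_C = (-h + 3n + 2o + 2s)/c spans +4 (CO2) to -4 (CH4) across metabolism;
biomolecules occupy a much narrower band.  Averaging monomer formulas
gives the per-monomer composition of a polymer, whose Z_C is the
carbon-weighted mean of its parts.
"""

from zcmeta import combine, parse_formula, zc, zc_protein

for name, formula in [
    ("methane CH4", "CH4"),
    ("carbon dioxide CO2", "CO2"),
    ("thymine", "C5H6N2O2"),
    ("guanine", "C5H5N5O"),
    ("ribose", "C5H10O5"),
    ("deoxyribose", "C5H10O4"),
    ("glycine", "C2H5NO2"),
    ("alanine", "C3H7NO2"),
    ("leucine", "C6H13NO2"),
]:
    print(f"{name:22s} Z_C = {zc(parse_formula(formula)):+.2f}")

# A hypothetical 50/50 Ala+Gly protein: average formula C2.5H6NO2
avg = combine([(parse_formula("C3H7NO2"), 50), (parse_formula("C2H5NO2"), 50)]) * 0.01
print(f"\nAla50Gly50 average formula: C{avg.c}H{avg.h}N{avg.n}O{avg.o}")
print(f"Ala50Gly50 protein Z_C = {zc_protein({'A': 50, 'G': 50}):+.2f}")
print(f"Ala50Leu50 protein Z_C = {zc_protein({'A': 50, 'L': 50}):+.2f}")
print("\nSwapping Gly for Leu drops Z_C from +0.40 to -0.67: a more reduced")
print("protein, favoured where the environment is more reducing.")
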
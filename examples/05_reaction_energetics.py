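"""Activity-corrected energy yields of the enrichment redox couples.

yield = -(dG0 + RT ln Q) per mole of electron donor, with formation
energies from the packaged table and the enrichment conditions (pH 7.3,
bracketed millimolar/micromolar concentrations, solids and water at
unit activity).  Positive values are thermodynamically favorable.
"""

from trflptools import CONDITIONS, REACTIONS, ThermoTable, delta_g_prime

table = ThermoTable.default()
couples = [
    ("acetate_goethite", "acetate_enrichment"),
    ("lactate_goethite", "lactate_enrichment"),
    ("lactate_sulfate", "lactate_enrichment"),
]
for reaction, conditions in couples:
    value = delta_g_prime(REACTIONS[reaction], table, CONDITIONS[conditions])
    donor = REACTIONS[reaction].basis
    print(f"{reaction:>18}: {value:+7.1f} kJ per mol {donor}")

print("\nAcetate oxidation on goethite is marginal (~0 kJ), which explains")
print("why acetate sustained Fe(III) reduction only on ferrihydrite, while")
print("incomplete lactate oxidation is strongly favorable on both sulfate")
print("and goethite, letting sulfate reducers compete in these enrichments.")
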
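"""Acid-base speciation of DMSA: who holds the protons at which pH.

Loads the packaged H+-DMSA protonation constants (0.15 mol/L NaCl), solves
the mass-balance speciation at fixed pH, and prints the landmark numbers:
the H3L share at pH 3 at two temperatures and the dominant species at
physiological pH.
"""

import numpy as np

import spequil as sq

dmsa = sq.load_packaged_model("dmsa-protonation")
comp = sq.SolutionComposition(C_L=0.002)  # 2 mmol/L ligand

print("H3L share of total DMSA at pH 3.00 (C_L = 2 mmol/L):")
for T in (288.15, 318.15):
    state = sq.solve_free_concentrations(dmsa, comp, T, fixed_pH=3.0)
    frac = sq.species_fractions(state, "L")["H3L"]
    print(f"  T = {T:6.2f} K  ->  {100 * frac:4.1f} %")
print("(the tri-protonated form grows from ~half to ~two thirds on warming)")

state = sq.solve_free_concentrations(dmsa, comp, 298.15, fixed_pH=7.4)
fractions = sq.species_fractions(state, "L")
top = max(fractions, key=fractions.get)
print(f"\nAt physiological pH 7.4 the ligand is {100 * fractions[top]:.1f} % {top}:")
print("  both thiol protons still on, both carboxylates off.")

grid = np.arange(2.0, 10.51, 0.5)
diagram = sq.distribution_diagram(dmsa, comp, grid, 298.15)
print("\nDistribution diagram (fractions of total ligand) every 0.5 pH:")
print(diagram.round(3).to_string())
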
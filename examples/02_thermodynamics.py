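"""Thermodynamic formation parameters of the H+- and As(III)-DMSA species.

The overall constants are tabulated at four temperatures; a van't Hoff
regression of ln beta against 1/T yields the formation enthalpy of each
species, dG follows from log beta at 298.15 K, and TdS = dH - dG.  The
sign pattern is the chemistry headline: ligand protonation is endothermic
(entropy-driven), As(III) complexation is exothermic (enthalpy-driven,
consistent with strong As-S bonding).
"""

import spequil as sq
from spequil.thermo import thermo_frame

model = sq.load_packaged_model("as3-dmsa")
records = sq.thermo_table(model, T=298.15)

frame = thermo_frame(records)
print("Overall thermodynamic formation parameters at 298.15 K (kJ/mol):")
print(frame.round(1).to_string(index=False))

print("\nStepwise protonation constants log K_i at 298.15 K:")
for i, k in enumerate(sq.stepwise_constants(model, 298.15), start=1):
    group = "thiol" if i <= 2 else "carboxylate"
    print(f"  log K{i} = {k:5.2f}   ({group})")

print("\nPartial constants log K for M + LHi = MLHi (metal-binding step only):")
for stoich in ((1, 1, 1), (1, 1, 2), (1, 1, 3)):
    print(f"  MLH{stoich[2]}: {sq.partial_constant(model, stoich, 298.15):.2f}")
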
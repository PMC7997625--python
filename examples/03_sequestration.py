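"""Sequestering ability of DMSA toward trace As(III) at physiological
conditions (pH 7.4, 310.15 K, 0.15 mol/L NaCl).

chi is the mole fraction of a trace metal bound by the ligand as a function
of pL = -log10(total ligand).  pL0.5, where chi = 0.5, is the single-number
summary: here ~5.0, i.e. a total DMSA concentration of ~1e-5 mol/L binds
half of the trace As(III).  Metal side reactions (hydrolysis) lower chi and
can be supplied as extra species lines.
"""

import numpy as np

import spequil as sq
from spequil.core import SpeciesLine

model = sq.load_packaged_model("as3-dmsa")
grid = np.arange(2.0, 9.01, 0.5)

curve = sq.sequestration_curve(model, None, pH=7.4, T=310.15, pL_grid=grid)
print("chi vs pL (no metal side reactions):")
for pl, chi in zip(curve.pL_grid, curve.chi):
    print(f"  pL = {pl:4.1f}   chi = {chi:.3f}")
print(f"\npL0.5 = {curve.pL05:.2f} (bisection), {curve.sigmoid_pL05:.2f} (sigmoid fit)")

# illustrative As(III) hydrolysis side reactions (constants are inputs, not
# packaged: they come from independent determinations)
hydrolysis = [SpeciesLine((1, 0, -1), {310.15: -9.0}),
              SpeciesLine((1, 0, -2), {310.15: -19.0})]
with_side = sq.sequestration_curve(model, hydrolysis, pH=7.4, T=310.15, pL_grid=grid)
print(f"with hydrolysis side reactions: pL0.5 = {with_side.pL05:.2f}")
print("(competing equilibria of the metal always lower the apparent ability)")
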
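"""Choosing the speciation model: the generating species set wins.

Synthetic titration data carry the {MLH, MLH2, MLH3} speciation; three
candidate models are refined against them.  The report ranks candidates by
the weighted fit standard deviation, flags species that never form
appreciably (an over-specified model's extra species), and prefers the
simpler model on near-ties.
"""

import numpy as np

import spequil as sq
from spequil.core import EquilibriumModel, SpeciesLine

model = sq.load_packaged_model("as3-dmsa")
comp = sq.SolutionComposition(C_M=0.001, C_L=0.001, C_HCl=0.008)
protocol = sq.TitrationProtocol(initial=comp, titrant_concentration=0.1,
                                volumes=np.linspace(0.0, 4.0, 51), T=298.15)
dataset = sq.simulate_potentiometric(model, protocol,
                                     sq.ElectrodeParams(E0=400.0), seed=7)


def variant(add=None, drop=()):
    species = [SpeciesLine(s.stoich, dict(s.log_beta_by_T), dict(s.sd_by_T), s.label)
               for s in model.species if s.label not in drop]
    if add is not None:
        species.append(SpeciesLine(*add))
    return EquilibriumModel(list(model.components), species,
                            dict(model.pKw_by_T), model.medium)


free = ["logB:MLH", "logB:MLH2", "logB:MLH3"]
candidates = [
    sq.RefinementSpec(model=model, free=free, name="MLH+MLH2+MLH3 (truth)"),
    sq.RefinementSpec(model=variant(add=((1, 2, 0), {298.15: 20.0})),
                      free=free + ["logB:ML2"], name="plus spurious ML2"),
    sq.RefinementSpec(model=variant(drop=("MLH", "MLH3")),
                      free=["logB:MLH2"], name="MLH2 only"),
]

report = sq.select_model(candidates, dataset)
print(report.to_string(index=False))
print("\nThe generating model ranks first; the spurious ML2 is flagged as")
print("negligible; dropping real species inflates sigma_fit by an order of")
print("magnitude.")
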
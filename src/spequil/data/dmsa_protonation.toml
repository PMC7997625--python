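name = "dmsa-protonation"
provenance = "Overall protonation constants of meso-2,3-dimercaptosuccinic acid (DMSA) in aqueous NaCl at I = 0.15 mol/L, from potentiometric titrations at four temperatures; +/- values are reported standard deviations."

[components]
ligand = "L"
proton = "H"

[medium]
ionic_strength = 0.15
electrolyte = "NaCl"

[pKw]
"288.15" = 14.10
"298.15" = 13.75
"310.15" = 13.37
"318.15" = 13.15

[[species]]
label = "HL"
stoich = [0, 1, 1]
logbeta = { "288.15" = 10.96, "298.15" = 11.01, "310.15" = 11.27, "318.15" = 11.32 }
sd = { "288.15" = 0.02, "298.15" = 0.04, "310.15" = 0.02, "318.15" = 0.03 }

[[species]]
label = "H2L"
stoich = [0, 1, 2]
logbeta = { "288.15" = 20.15, "298.15" = 20.32, "310.15" = 20.64, "318.15" = 20.82 }
sd = { "288.15" = 0.03, "298.15" = 0.03, "310.15" = 0.02, "318.15" = 0.03 }

[[species]]
label = "H3L"
stoich = [0, 1, 3]
logbeta = { "288.15" = 23.51, "298.15" = 23.87, "310.15" = 24.35, "318.15" = 24.61 }
sd = { "288.15" = 0.05, "298.15" = 0.02, "310.15" = 0.02, "318.15" = 0.02 }

[[species]]
label = "H4L"
stoich = [0, 1, 4]
logbeta = { "288.15" = 26.14, "298.15" = 26.39, "310.15" = 26.85, "318.15" = 27.09 }
sd = { "288.15" = 0.04, "298.15" = 0.03, "310.15" = 0.02, "318.15" = 0.02 }
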
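# Sulfur-comproportionation cultivation medium (basal salts per liter of
# 50 mM sulfuric acid; pH adjusted to 1; incubated at 15 C under an
# 80% N2 - 20% CO2 headspace; amended post-autoclave with 10 mM
# bicarbonate and 2 mM sulfide). Trace elements, vitamins and resazurin
# are sub-mmol and redox-inert here; they are excluded from the
# ionic-strength bookkeeping except Na2HPO4's sodium contribution.
name = "comproportionation medium"
T_C = 15.0
pH = 1.0

salts_g_per_L = [
    ["Na2SO4", 2.42],
    ["MgSO4·7H2O", 0.50],
    ["CaCl2·2H2O", 0.025],
    ["KCl", 0.1],
    ["(NH4)2SO4", 0.13],
    ["Na2HPO4", 0.14],
]

acid = ["H2SO4", 0.050]

# component-resolved molar amendments (mol/L): sodium bicarbonate to
# 10 mM (Na + C(IV)), sodium sulfide nonahydrate to 2 mM (2 Na + S(-II))
extras_mol_per_L = [
    ["C(IV)", 0.010],
    ["Na", 0.010],
    ["S(-II)", 0.002],
    ["Na", 0.004],
]

[gases]
"N2(g)" = 0.8104
"CO2(g)" = 0.2026
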
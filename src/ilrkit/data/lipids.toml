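# Packaged acylglycerol registry: the nine pure lipids of the nanoemulsion
# study panel.  Molar masses are computed from molecular formulae (standard
# atomic weights).  Densities (liquid / supercooled melt, g/cm³) and melting
# points (°C) are literature-typical PLACEHOLDER values, flagged via the
# `provenance` key: override them with measured or supplier data (e.g.
# PubChem records) for quantitative surface-area work.
#
# esterification_class: "mono" (1 fatty acid released), "di_1_3" or "tri"
# (2 fatty acids released, sn-1/sn-3 cleavage by pancreatic lipase).

[tricaprylin]
esterification_class = "tri"
fa_per_molecule = 2
acyl_chain_length = 8
double_bonds = 0
molar_mass = 470.69      # C27H50O6
density = 0.956
melting_point = 8.3
provenance = "placeholder"

[tricaprin]
esterification_class = "tri"
fa_per_molecule = 2
acyl_chain_length = 10
double_bonds = 0
molar_mass = 554.85      # C33H62O6
density = 0.945
melting_point = 31.5
provenance = "placeholder"

[trilaurin]
esterification_class = "tri"
fa_per_molecule = 2
acyl_chain_length = 12
double_bonds = 0
molar_mass = 639.02      # C39H74O6
density = 0.935
melting_point = 46.5
provenance = "placeholder"

[triolein]
esterification_class = "tri"
fa_per_molecule = 2
acyl_chain_length = 18
double_bonds = 1
molar_mass = 885.45      # C57H104O6
density = 0.915
melting_point = 5.0
provenance = "placeholder"

[trilinolein]
esterification_class = "tri"
fa_per_molecule = 2
acyl_chain_length = 18
double_bonds = 2
molar_mass = 879.41      # C57H98O6
density = 0.925
melting_point = -13.0
provenance = "placeholder"

[dilaurin_1_3]
esterification_class = "di_1_3"
fa_per_molecule = 2
acyl_chain_length = 12
double_bonds = 0
molar_mass = 456.71      # C27H52O5
density = 0.940
melting_point = 57.0
provenance = "placeholder"

[monocaprylin_1]
esterification_class = "mono"
fa_per_molecule = 1
acyl_chain_length = 8
double_bonds = 0
molar_mass = 218.29      # C11H22O4
density = 1.000
melting_point = 40.0
provenance = "placeholder"

[monocaprin_1]
esterification_class = "mono"
fa_per_molecule = 1
acyl_chain_length = 10
double_bonds = 0
molar_mass = 246.35      # C13H26O4
density = 0.980
melting_point = 53.0
provenance = "placeholder"

[monolaurin_1]
esterification_class = "mono"
fa_per_molecule = 1
acyl_chain_length = 12
double_bonds = 0
molar_mass = 274.40      # C15H30O4
density = 0.970
melting_point = 63.0
provenance = "placeholder"
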
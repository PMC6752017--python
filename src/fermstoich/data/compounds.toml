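# Compound registry: substrates and products of anoxic gut-content
# fermentation balances.  Electrons per carbon follow from the formula by the
# degree-of-reduction rule; only mixtures carry explicit overrides.

[glutamate]
formula = "C5H9NO4"
molar_mass = 147.13

[aspartate]
formula = "C4H7NO4"
molar_mass = 133.10

[threonine]
formula = "C4H9NO3"
molar_mass = 119.12

[alanine]
formula = "C3H7NO2"
molar_mass = 89.09

[glycine]
formula = "C2H5NO2"
molar_mass = 75.07

[valine]
formula = "C5H11NO2"
molar_mass = 117.15

[leucine]
formula = "C6H13NO2"
molar_mass = 131.17

[tyrosine]
formula = "C9H11NO3"
molar_mass = 181.19

[ribose]
formula = "C5H10O5"
molar_mass = 150.13

[glucose]
formula = "C6H12O6"
molar_mass = 180.16

# Acid-hydrolyzed casein: a mixture of free amino acids.  The electrons per
# carbon (4.2) is the study's fixed coefficient; the 4-carbon / 100 g-per-mol
# residue basis is an assumed mean-amino-acid basis, not a measured one.
[casamino_acids]
mixture = true
carbons = 4.0
electrons_per_carbon = 4.2
molar_mass = 100.0

[co2]
formula = "CO2"
molar_mass = 44.01

[h2]
formula = "H2"
molar_mass = 2.016

[acetate]
formula = "C2H4O2"
molar_mass = 60.05

[ethanol]
formula = "C2H6O"
molar_mass = 46.07

[lactate]
formula = "C3H6O3"
molar_mass = 90.08

[succinate]
formula = "C4H6O4"
molar_mass = 118.09

[formate]
formula = "CH2O2"
molar_mass = 46.03

[butyrate]
formula = "C4H8O2"
molar_mass = 88.11

[propionate]
formula = "C3H6O2"
molar_mass = 74.08

[isobutyrate]
formula = "C4H8O2"
molar_mass = 88.11

# Chromatographic name without positional isomer; modeled as 2-methylbutyrate.
[methylbutyrate]
formula = "C5H10O2"
molar_mass = 102.13

[ammonium]
formula = "NH3"
molar_mass = 17.03
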
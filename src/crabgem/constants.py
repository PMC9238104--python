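"""Molar-mass constants (g·mol⁻¹, average atomic weights).

Used for converting measured contents (g per 100 g fresh weight, percent
of feed, g/kg or mg/kg of feed) into mmol·gDW⁻¹ biomass coefficients and
mmol·gDW⁻¹·h⁻¹ demand rates.  Masses refer to the *measured form*: free
amino acids and fatty acids, carrier salts for minerals quoted as such
(calcium carbonate, magnesium L-aspartate), and elemental masses for trace
elements quoted per element (Zn, Se, Cu).
"""

AMINO_ACID_MW: dict[str, float] = {
    "alanine": 89.09,
    "arginine": 174.20,
    "asparagine": 132.12,
    "aspartate": 133.10,
    "cysteine": 121.16,
    "glutamate": 147.13,
    "glutamine": 146.15,
    "glycine": 75.07,
    "histidine": 155.15,
    "isoleucine": 131.17,
    "leucine": 131.17,
    "lysine": 146.19,
    "methionine": 149.21,
    "phenylalanine": 165.19,
    "proline": 115.13,
    "serine": 105.09,
    "threonine": 119.12,
    "tryptophan": 204.23,
    "tyrosine": 181.19,
    "valine": 117.15,
}

FATTY_ACID_MW: dict[str, float] = {
    "linoleic_acid": 280.45,        # 18:2n-6
    "alpha_linolenic_acid": 278.43,  # 18:3n-3
    "gamma_linolenic_acid": 278.43,  # 18:3n-6
    "arachidonic_acid": 304.47,      # 20:4n-6 (ARA)
    # EPA 20:5n-3: free acid 302.45; the ethyl-ester form 330.50 is also
    # common in feed formulations — both recorded, free acid is default.
    "epa": 302.45,
    "epa_ethyl_ester": 330.50,
    "dha": 328.49,                   # 22:6n-3
    "palmitic_acid": 256.43,
    "stearic_acid": 284.48,
    "oleic_acid": 282.46,
}

MINERAL_MW: dict[str, float] = {
    "calcium_carbonate": 100.09,
    "magnesium_l_aspartate": 288.50,
    "zinc": 65.38,
    "selenium": 78.97,
    "copper": 63.55,
    "calcium": 40.08,
    "magnesium": 24.31,
    "iron": 55.85,
    "manganese": 54.94,
}

SACCHARIDE_MW: dict[str, float] = {
    "glucose": 180.16,
    "glycogen_glucosyl": 162.14,  # anhydro-glucose unit
}

MOLAR_MASS: dict[str, float] = {
    **AMINO_ACID_MW, **FATTY_ACID_MW, **MINERAL_MW, **SACCHARIDE_MW,
}

#: measured water fraction of fresh biomass (g water / g fresh weight)
DEFAULT_WATER_FRACTION = 0.516

#: default growth-associated ATP maintenance (mmol ATP per gDW biomass)
DEFAULT_MAINTENANCE_ATP = 30.0
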
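"""Centralised unit conversions.

Extracellular concentrations are held internally in mM (the units of the
glycerol-uptake kinetics) and reported externally in g/L.  All molar masses
are in g/mol; dividing by 1000 gives g/mmol, the mass of one flux unit
(mmol/gDW/h) worth of metabolite.
"""

from __future__ import annotations

#: Molar masses (g/mol) of the extracellular species of the reduced network.
MOLAR_MASS_G_MOL: dict[str, float] = {
    "glycerol": 92.09,
    "pdo": 76.09,  # 1,3-propanediol
    "acetate": 60.05,
    "butyrate": 88.11,
    "lactate": 90.08,
    "ethanol": 46.07,
    "butanol": 74.12,
    "h2": 2.016,
    "co2": 44.01,
    "biomass": 1000.0,  # 1 g/mmol by the FBA normalisation convention
}


def g_per_l_to_mm(value: float, species: str) -> float:
    """Convert a concentration in g/L to mM."""
    return value * 1000.0 / MOLAR_MASS_G_MOL[species]


def mm_to_g_per_l(value: float, species: str) -> float:
    """Convert a concentration in mM to g/L."""
    return value * MOLAR_MASS_G_MOL[species] / 1000.0
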
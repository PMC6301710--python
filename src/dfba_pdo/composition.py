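"""Biomass composition of the reduced *C. butyricum* model.

Biomass is assembled from eight macromolecule classes (mass fractions summing
to one) which are in turn assembled from 44 precursor species: 20 amino acids
(protein), 4+4 nucleotides (RNA/DNA), 7 fatty acids and 3 polar lipids
(lipid), and 6 cofactors (trace pool).  Teichoic acid, peptidoglycan and
carbohydrate are carried as single structural repeating units whose abundance
is set by their macromolecule fraction alone.

Each species is declared by its chemical formula; molar mass, carbon count
and degree of reduction (electron content, reference state CO2/H2O/NH3) are
derived from it, so the carbon and redox demands of biomass synthesis are
consistent with the rest of the network by construction.

The normalisation convention is the usual FBA one: one mmol of biomass weighs
1 g (biomass "molecular weight" 1.000 g/mmol for the unperturbed default), so
the biomass reaction flux in mmol/gDW/h equals the specific growth rate in
1/h.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "BiomassComposition",
    "default_composition",
    "biomass_molecular_weight",
    "perturb_composition",
]

_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999,
                "P": 30.974, "S": 32.06}
# electrons available per atom relative to CO2 / H2O / NH3 / H3PO4 / H2SO4
_ELECTRONS = {"C": 4, "H": 1, "N": -3, "O": -2, "P": 5, "S": 6}


@lru_cache(maxsize=256)
def _parse_formula(formula: str) -> dict[str, int]:
    atoms: dict[str, int] = {}
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if el:
            atoms[el] = atoms.get(el, 0) + (int(num) if num else 1)
    return atoms


@lru_cache(maxsize=256)
def _molar_mass(formula: str) -> float:
    """Molar mass in g/mmol (i.e. kDa-free g/mol divided by 1000)."""
    return sum(_ATOMIC_MASS[el] * n for el, n in _parse_formula(formula).items()) / 1000.0


def _carbons(formula: str) -> int:
    return _parse_formula(formula).get("C", 0)


def _electrons(formula: str) -> int:
    return sum(_ELECTRONS[el] * n for el, n in _parse_formula(formula).items())


# ---------------------------------------------------------------------------
# Species declarations: name -> (formula, macromolecule, default mole share
# within its macromolecule).  Mole shares follow typical bacterial
# compositions and are normalised to mass shares at build time.
# ---------------------------------------------------------------------------

_PRECURSORS: dict[str, tuple[str, str, float]] = {
    # 20 amino acids -> protein
    "ala": ("C3H7NO2", "protein", 0.096),
    "arg": ("C6H14N4O2", "protein", 0.055),
    "asn": ("C4H8N2O3", "protein", 0.045),
    "asp": ("C4H7NO4", "protein", 0.045),
    "cys": ("C3H7NO2S", "protein", 0.017),
    "gln": ("C5H10N2O3", "protein", 0.049),
    "glu": ("C5H9NO4", "protein", 0.049),
    "gly": ("C2H5NO2", "protein", 0.115),
    "his": ("C6H9N3O2", "protein", 0.018),
    "ile": ("C6H13NO2", "protein", 0.054),
    "leu": ("C6H13NO2", "protein", 0.084),
    "lys": ("C6H14N2O2", "protein", 0.064),
    "met": ("C5H11NO2S", "protein", 0.029),
    "phe": ("C9H11NO2", "protein", 0.035),
    "pro": ("C5H9NO2", "protein", 0.041),
    "ser": ("C3H7NO3", "protein", 0.040),
    "thr": ("C4H9NO3", "protein", 0.047),
    "trp": ("C11H12N2O2", "protein", 0.011),
    "tyr": ("C9H11NO3", "protein", 0.026),
    "val": ("C5H11NO2", "protein", 0.079),
    # 4 ribonucleotides -> RNA
    "amp": ("C10H14N5O7P", "rna", 0.26),
    "gmp": ("C10H14N5O8P", "rna", 0.32),
    "cmp": ("C9H14N3O8P", "rna", 0.20),
    "ump": ("C9H13N2O9P", "rna", 0.22),
    # 4 deoxyribonucleotides -> DNA (low-GC clostridial genome)
    "damp": ("C10H14N5O6P", "dna", 0.33),
    "dgmp": ("C10H14N5O7P", "dna", 0.17),
    "dcmp": ("C9H14N3O7P", "dna", 0.17),
    "dtmp": ("C10H15N2O8P", "dna", 0.33),
    # 7 fatty acids -> lipid
    "fa12_0": ("C12H24O2", "lipid", 0.05),
    "fa14_0": ("C14H28O2", "lipid", 0.10),
    "fa16_0": ("C16H32O2", "lipid", 0.35),
    "fa16_1": ("C16H30O2", "lipid", 0.15),
    "fa18_0": ("C18H36O2", "lipid", 0.10),
    "fa18_1": ("C18H34O2", "lipid", 0.15),
    "fa17_cyc": ("C17H32O2", "lipid", 0.10),
    # 3 polar lipids -> lipid
    "pe": ("C37H74NO8P", "lipid", 0.055),
    "pg": ("C38H75O10P", "lipid", 0.025),
    "clpn": ("C77H150O17P2", "lipid", 0.008),
    # 6 cofactors -> trace pool
    "nad": ("C21H27N7O14P2", "trace", 0.23),
    "nadp": ("C21H28N7O17P3", "trace", 0.12),
    "fad": ("C27H33N9O15P2", "trace", 0.10),
    "coa": ("C21H36N7O16P3S", "trace", 0.15),
    "sam": ("C15H22N6O5S", "trace", 0.20),
    "thf": ("C19H23N7O6", "trace", 0.20),
}

# structural repeating units carried by macromolecule fraction alone
_STRUCTURAL_UNITS: dict[str, tuple[str, str]] = {
    "teichoic_unit": ("C9H19O11P", "teichoic_acid"),
    "peptidoglycan_unit": ("C37H60N8O20", "peptidoglycan"),
    "glucan_unit": ("C6H10O5", "carbohydrate"),
}

#: Default macromolecule mass fractions (g per gDW) of a gram-positive
#: anaerobe; they sum to exactly 1.
DEFAULT_MACROMOLECULE_FRACTIONS: dict[str, float] = {
    "protein": 0.52,
    "rna": 0.155,
    "dna": 0.03,
    "lipid": 0.075,
    "teichoic_acid": 0.03,
    "peptidoglycan": 0.06,
    "carbohydrate": 0.10,
    "trace": 0.03,
}

MACROMOLECULES = tuple(DEFAULT_MACROMOLECULE_FRACTIONS)
PRECURSORS = tuple(_PRECURSORS)


def _default_mass_shares() -> dict[str, float]:
    """Within-macromolecule mass shares of the 44 precursors (sum to 1)."""
    shares: dict[str, float] = {}
    for macro in MACROMOLECULES:
        members = [n for n, (_, m, _) in _PRECURSORS.items() if m == macro]
        if not members:
            continue
        masses = {n: _PRECURSORS[n][2] * _molar_mass(_PRECURSORS[n][0]) for n in members}
        total = sum(masses.values())
        for n in members:
            shares[n] = masses[n] / total
    return shares


@dataclass(frozen=True)
class BiomassComposition:
    """Macromolecule fractions plus within-macromolecule precursor shares.

    ``macromolecule_fractions`` are mass fractions per gDW; ``mass_shares``
    give the mass of each precursor per unit mass of its macromolecule.  The
    absolute precursor coefficients in mmol/gDW are derived, not stored.
    """

    macromolecule_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MACROMOLECULE_FRACTIONS))
    mass_shares: dict[str, float] = field(default_factory=_default_mass_shares)
    scale: float = 1.0

    def __post_init__(self) -> None:
        for name, value in {**self.macromolecule_fractions, **self.mass_shares}.items():
            if value < 0:
                raise ValueError(f"negative biomass coefficient for {name!r}")

    # -- derived quantities -------------------------------------------------
    @property
    def precursor_coeffs(self) -> dict[str, float]:
        """Coefficients of the 44 precursors, mmol per gDW."""
        out = {}
        for name, (formula, macro, _) in _PRECURSORS.items():
            out[name] = (self.scale * self.macromolecule_fractions[macro]
                         * self.mass_shares[name] / _molar_mass(formula))
        return out

    @property
    def component_coeffs(self) -> dict[str, float]:
        """All mass-carrying components (44 precursors + 3 structural units)."""
        out = self.precursor_coeffs
        for name, (formula, macro) in _STRUCTURAL_UNITS.items():
            out[name] = (self.scale * self.macromolecule_fractions[macro]
                         / _molar_mass(formula))
        return out

    def component_formula(self, name: str) -> str:
        if name in _PRECURSORS:
            return _PRECURSORS[name][0]
        return _STRUCTURAL_UNITS[name][0]

    def molecular_weight(self) -> float:
        return biomass_molecular_weight(self)

    def carbon_content(self) -> float:
        """mmol carbon fixed per gDW of biomass."""
        return sum(c * _carbons(self.component_formula(n))
                   for n, c in self.component_coeffs.items())

    def electron_content(self) -> float:
        """Electron (degree-of-reduction) content per gDW of biomass."""
        return sum(c * _electrons(self.component_formula(n))
                   for n, c in self.component_coeffs.items())

    def scaled(self, k: float) -> "BiomassComposition":
        """Homogeneously scale every coefficient by ``k``."""
        return BiomassComposition(dict(self.macromolecule_fractions),
                                  dict(self.mass_shares), self.scale * k)


def default_composition() -> BiomassComposition:
    return BiomassComposition()


def biomass_molecular_weight(composition: BiomassComposition) -> float:
    """Mass of one mmol of biomass, g/mmol: sum of coefficient x molar mass.

    Exactly 1.000 for the unperturbed default by the FBA normalisation
    convention.
    """
    mw = sum(c * _molar_mass(composition.component_formula(n))
             for n, c in composition.component_coeffs.items())
    if mw == 0.0:
        warnings.warn("all-zero biomass composition: molecular weight is 0")
    return mw


def _positive_normal(rng: np.random.Generator, mean: float, rsd: float) -> float:
    """One normal draw with relative SD ``rsd``, resampled until positive."""
    if rsd == 0.0 or mean == 0.0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, rsd * mean)
        if x > 0.0:
            return x
    raise RuntimeError("could not draw a positive coefficient")


def perturb_composition(
    composition: BiomassComposition,
    rng: np.random.Generator,
    rsd_precursors: float = 0.0,
    rsd_macromolecules: float = 0.0,
) -> BiomassComposition:
    """Random composition with normally perturbed coefficients.

    Precursor shares are perturbed independently (not renormalised), which
    disperses the biomass molecular weight; macromolecule fractions are
    perturbed and renormalised to sum to one, so they shift the composition
    without changing the total biomass mass bookkeeping.
    """
    shares = {n: _positive_normal(rng, s, rsd_precursors)
              for n, s in composition.mass_shares.items()}
    fractions = {n: _positive_normal(rng, f, rsd_macromolecules)
                 for n, f in composition.macromolecule_fractions.items()}
    total = sum(fractions.values())
    fractions = {n: f / total for n, f in fractions.items()}
    return BiomassComposition(fractions, shares, composition.scale)
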
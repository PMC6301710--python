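"""Stoichiometric model of anaerobic glycerol metabolism.

The bundled reduced network lumps the central anaerobic glycerol metabolism
of *Clostridium butyricum* into 15 reactions over 8 balanced intracellular
metabolites:

* the reductive branch glycerol -> 3-HPA -> 1,3-propanediol (PDO), consuming
  one NADH per PDO;
* the oxidative branch glycerol -> DHAP -> pyruvate -> acetyl-CoA with the
  ATP/NADH stoichiometry of glycolysis and pyruvate:ferredoxin
  oxidoreductase;
* fermentative sinks: acetate (+1 ATP), butyrate (+1 ATP per two acetyl-CoA,
  2 NADH consumed), lactate, ethanol, butanol, H2 (from reduced ferredoxin
  or NADH), CO2, and a ferredoxin-NAD+ reductase bridging the two electron
  carriers;
* a lumped biomass reaction whose glycerol, ATP and NADH stoichiometry is
  derived from the biomass composition by carbon and electron bookkeeping.

Every metabolite carries a carbon count and electron (degree-of-reduction)
content, so carbon and redox conservation can be asserted network-wide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .composition import BiomassComposition, biomass_molecular_weight, default_composition
from .optimize import FluxProblem, solve_fractional, solve_product
from .units import MOLAR_MASS_G_MOL

__all__ = [
    "Metabolite", "Reaction", "ObjectiveSpec", "FluxState", "MetabolicNetwork",
    "build_reduced_network", "set_biomass_composition", "load_network",
    "save_network", "solve_flux_state", "NetworkValidationError",
]

#: sentinel for unbounded fluxes, mmol/gDW/h
FLUX_BOUND = 1000.0

#: default growth-associated ATP demand, mmol ATP per gDW of biomass
DEFAULT_GAM = 40.0

#: electrons carried per glycerol (degree of reduction of C3H8O3)
_GLYCEROL_ELECTRONS = 14.0


class NetworkValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str              # "c" (intracellular) or "e" (extracellular)
    carbon: float = 0.0
    electrons: float = 0.0        # degree-of-reduction electrons per mmol
    molar_mass: float | None = None  # g/mmol, for extracellular species


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = FLUX_BOUND

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id}: lower bound exceeds upper bound")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Weighted growth-per-flux objective.

    Z = mu / (w * sum v_j^2 + (1-w) * v_ATPprod^2) where v_ATPprod is the
    total ATP production rate of the substrate-level phosphorylation steps
    (fluxes weighted by their positive ATP stoichiometry).  ``form="product"``
    selects the literal product reading instead of the ratio.
    """

    w: float
    atp_production_flux_ids: frozenset[str]
    form: str = "ratio"

    def __post_init__(self) -> None:
        if not (0.0 < self.w <= 1.0):
            raise ValueError("objective weight w must lie in (0, 1]")
        if self.form not in ("ratio", "product"):
            raise ValueError("objective form must be 'ratio' or 'product'")


@dataclass
class FluxState:
    fluxes: dict[str, float]
    mu: float
    objective_value: float
    iterations: int = 0


@dataclass
class MetabolicNetwork:
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    composition: BiomassComposition
    gam: float = DEFAULT_GAM
    ngam: float = 0.0
    atp_production_flux_ids: frozenset[str] = field(default_factory=frozenset)

    # -- structural helpers -------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def is_exchange(self, reaction: Reaction) -> bool:
        return any(self.metabolites[m].compartment == "e"
                   for m in reaction.stoichiometry)

    @property
    def extracellular_ids(self) -> list[str]:
        return [m for m, met in self.metabolites.items() if met.compartment == "e"]

    def stoichiometric_matrix(self, compartment: str = "c") -> tuple[np.ndarray, list[str]]:
        """S over the metabolites of one compartment; returns (S, row ids)."""
        rows = [m for m, met in self.metabolites.items()
                if met.compartment == compartment]
        S = np.zeros((len(rows), len(self.reactions)))
        index = {m: i for i, m in enumerate(rows)}
        for j, r in enumerate(self.reactions):
            for m, coeff in r.stoichiometry.items():
                if m in index:
                    S[index[m], j] = coeff
        return S, rows

    def exchange_stoichiometry(self) -> tuple[np.ndarray, list[str]]:
        """Net production stoichiometry of every extracellular species."""
        return self.stoichiometric_matrix("e")

    @property
    def growth_weights(self) -> np.ndarray:
        """c_j such that mu = c . v; the indicator of the biomass reaction
        scaled by the biomass molecular weight (1.000 for the default)."""
        c = np.zeros(len(self.reactions))
        c[self.reaction_ids.index(self.biomass_reaction_id)] = (
            biomass_molecular_weight(self.composition))
        return c

    def atp_weight_vector(self) -> np.ndarray:
        a = np.zeros(len(self.reactions))
        for j, r in enumerate(self.reactions):
            if r.id in self.atp_production_flux_ids:
                a[j] = max(r.stoichiometry.get("atp", 0.0), 0.0)
        return a

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.biomass_reaction_id not in self.reaction_ids:
            raise NetworkValidationError("missing biomass reaction")
        S, rows = self.stoichiometric_matrix("c")
        orphan = [rows[i] for i in range(len(rows)) if not np.any(S[i] != 0.0)]
        if orphan:
            raise NetworkValidationError(f"orphan metabolite(s): {orphan}")
        for r in self.reactions:
            ext = [m for m in r.stoichiometry
                   if self.metabolites[m].compartment == "e"]
            if len(ext) > 1:
                raise NetworkValidationError(
                    f"reaction {r.id} touches several extracellular species: {ext}")
        _, ext_rows = self.exchange_stoichiometry()
        for m in ext_rows:
            n_ex = sum(1 for r in self.reactions if m in r.stoichiometry)
            if n_ex != 1:
                raise NetworkValidationError(
                    f"extracellular metabolite {m} appears in {n_ex} reactions "
                    "(expected exactly one exchange)")

    def carbon_imbalances(self) -> dict[str, float]:
        out = {}
        for r in self.reactions:
            out[r.id] = sum(coeff * self.metabolites[m].carbon
                            for m, coeff in r.stoichiometry.items())
        return out

    def electron_imbalances(self) -> dict[str, float]:
        out = {}
        for r in self.reactions:
            out[r.id] = sum(coeff * self.metabolites[m].electrons
                            for m, coeff in r.stoichiometry.items())
        return out


# ---------------------------------------------------------------------------
# Bundled reduced network
# ---------------------------------------------------------------------------

def _biomass_reaction(composition: BiomassComposition, gam: float) -> tuple[dict[str, float], float, float]:
    """Stoichiometry of the lumped biomass reaction per mmol (= MW gram).

    Carbon demand is met from intracellular glycerol; surplus electrons
    (glycerol is more reduced than biomass) are released as NADH.
    Returns (stoichiometry, carbon content, electron content).
    """
    c_x = composition.carbon_content()
    e_x = composition.electron_content()
    gly = c_x / 3.0
    nadh_released = (gly * _GLYCEROL_ELECTRONS - e_x) / 2.0
    stoich = {"glycerol_c": -gly, "atp": -gam, "nadh": nadh_released,
              "biomass_e": 1.0}
    return stoich, c_x, e_x


def build_reduced_network(
    composition: BiomassComposition | None = None,
    gam: float = DEFAULT_GAM,
    ngam: float = 0.0,
) -> MetabolicNetwork:
    """The bundled lumped network of anaerobic glycerol fermentation."""
    comp = composition if composition is not None else default_composition()
    mw = biomass_molecular_weight(comp)
    bio_stoich, c_x, e_x = _biomass_reaction(comp, gam)

    mets = {
        # extracellular
        "glycerol_e": Metabolite("glycerol_e", "e", 3, 14, MOLAR_MASS_G_MOL["glycerol"] / 1000),
        "pdo_e": Metabolite("pdo_e", "e", 3, 16, MOLAR_MASS_G_MOL["pdo"] / 1000),
        "acetate_e": Metabolite("acetate_e", "e", 2, 8, MOLAR_MASS_G_MOL["acetate"] / 1000),
        "butyrate_e": Metabolite("butyrate_e", "e", 4, 20, MOLAR_MASS_G_MOL["butyrate"] / 1000),
        "lactate_e": Metabolite("lactate_e", "e", 3, 12, MOLAR_MASS_G_MOL["lactate"] / 1000),
        "ethanol_e": Metabolite("ethanol_e", "e", 2, 12, MOLAR_MASS_G_MOL["ethanol"] / 1000),
        "butanol_e": Metabolite("butanol_e", "e", 4, 24, MOLAR_MASS_G_MOL["butanol"] / 1000),
        "h2_e": Metabolite("h2_e", "e", 0, 2, MOLAR_MASS_G_MOL["h2"] / 1000),
        "co2_e": Metabolite("co2_e", "e", 1, 0, MOLAR_MASS_G_MOL["co2"] / 1000),
        "biomass_e": Metabolite("biomass_e", "e", c_x, e_x, mw),
        # intracellular
        "glycerol_c": Metabolite("glycerol_c", "c", 3, 14),
        "dhap": Metabolite("dhap", "c", 3, 12),
        "pyruvate": Metabolite("pyruvate", "c", 3, 10),
        "accoa": Metabolite("accoa", "c", 2, 8),   # acetyl moiety only
        "coa": Metabolite("coa", "c", 0, 0),       # carrier bookkeeping
        "h2_c": Metabolite("h2_c", "c", 0, 2),
        "nadh": Metabolite("nadh", "c", 0, 2),
        "fdred": Metabolite("fdred", "c", 0, 2),   # reduced ferredoxin (2 e-)
        "atp": Metabolite("atp", "c", 0, 0),
    }

    rxns = [
        Reaction("glycerol_uptake", {"glycerol_e": -1, "glycerol_c": 1}, 0, FLUX_BOUND),
        # reductive branch: glycerol -> 3-HPA -> PDO (1 NADH per PDO)
        Reaction("pdo_synthesis", {"glycerol_c": -1, "nadh": -1, "pdo_e": 1}),
        # oxidative branch: glycerol dehydrogenase + DHA kinase
        Reaction("glycerol_oxidation", {"glycerol_c": -1, "atp": -1,
                                        "dhap": 1, "nadh": 1}),
        # lower glycolysis lump (GAPDH/PGK/ENO/PYK): 2 ATP, 1 NADH per triose
        Reaction("glycolysis_lower", {"dhap": -1, "pyruvate": 1,
                                      "nadh": 1, "atp": 2}),
        Reaction("pfor", {"pyruvate": -1, "coa": -1, "accoa": 1,
                          "co2_e": 1, "fdred": 1}),
        Reaction("hydrogenase", {"fdred": -1, "h2_c": 1}),
        Reaction("nadh_hydrogenase", {"nadh": -1, "h2_c": 1}),
        Reaction("h2_secretion", {"h2_c": -1, "h2_e": 1}),
        Reaction("fnor", {"fdred": -1, "nadh": 1}),
        Reaction("acetate_kinase", {"accoa": -1, "acetate_e": 1,
                                    "atp": 1, "coa": 1}),
        Reaction("butyrate_kinase", {"accoa": -2, "nadh": -2, "butyrate_e": 1,
                                     "atp": 1, "coa": 2}),
        Reaction("ldh", {"pyruvate": -1, "nadh": -1, "lactate_e": 1}),
        Reaction("adh", {"accoa": -1, "nadh": -2, "ethanol_e": 1, "coa": 1}),
        Reaction("bdh", {"accoa": -2, "nadh": -4, "butanol_e": 1, "coa": 2}),
        Reaction("atp_maintenance", {"atp": -1}, ngam, FLUX_BOUND),
        Reaction("biomass", bio_stoich),
    ]
    net = MetabolicNetwork(
        metabolites=mets, reactions=rxns, biomass_reaction_id="biomass",
        composition=comp, gam=gam, ngam=ngam,
        atp_production_flux_ids=frozenset(
            {"glycolysis_lower", "acetate_kinase", "butyrate_kinase"}),
    )
    net.validate()
    return net


def set_biomass_composition(
    network: MetabolicNetwork, composition: BiomassComposition
) -> MetabolicNetwork:
    """Return a copy of the network with a rescaled biomass reaction."""
    if any(v < 0 for v in composition.component_coeffs.values()):
        raise ValueError("negative biomass coefficient")
    return build_reduced_network(composition, gam=network.gam, ngam=network.ngam)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_JSON_VERSION = 1


def bundled_network_path() -> str:
    """Path of the versioned JSON copy of the reduced network."""
    import importlib.resources as res
    return str(res.files("dfba_pdo") / "data" / "reduced_network.json")


def save_network(network: MetabolicNetwork, path: str) -> None:
    doc = {
        "format_version": _JSON_VERSION,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "carbon": m.carbon,
             "electrons": m.electrons, "molar_mass": m.molar_mass}
            for m in network.metabolites.values()
        ],
        "reactions": [
            {"id": r.id, "stoichiometry": r.stoichiometry,
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound}
            for r in network.reactions
        ],
        "biomass_reaction_id": network.biomass_reaction_id,
        "gam": network.gam,
        "ngam": network.ngam,
        "atp_production_flux_ids": sorted(network.atp_production_flux_ids),
        "composition": {
            "macromolecule_fractions": network.composition.macromolecule_fractions,
            "mass_shares": network.composition.mass_shares,
            "scale": network.composition.scale,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_network(path: str, format: str = "json") -> MetabolicNetwork:
    """Load a network from the bundled JSON schema or an SBML L3/FBC file."""
    if format == "json":
        return _load_json(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown network format {format!r}")


def _load_json(path: str) -> MetabolicNetwork:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise NetworkValidationError(f"cannot parse network file: {exc}") from exc
    comp_doc = doc.get("composition", {})
    comp = BiomassComposition(
        comp_doc.get("macromolecule_fractions"),
        comp_doc.get("mass_shares"),
        comp_doc.get("scale", 1.0),
    ) if comp_doc else default_composition()
    mets = {
        m["id"]: Metabolite(m["id"], m["compartment"], m.get("carbon", 0.0),
                            m.get("electrons", 0.0), m.get("molar_mass"))
        for m in doc["metabolites"]
    }
    rxns = [
        Reaction(r["id"], dict(r["stoichiometry"]),
                 _clip_bound(r.get("lower_bound", 0.0)),
                 _clip_bound(r.get("upper_bound", FLUX_BOUND)))
        for r in doc["reactions"]
    ]
    net = MetabolicNetwork(
        metabolites=mets, reactions=rxns,
        biomass_reaction_id=doc["biomass_reaction_id"], composition=comp,
        gam=doc.get("gam", DEFAULT_GAM), ngam=doc.get("ngam", 0.0),
        atp_production_flux_ids=frozenset(doc.get("atp_production_flux_ids", [])),
    )
    net.validate()
    return net


def _clip_bound(b: float | None) -> float:
    if b is None or not np.isfinite(b):
        return FLUX_BOUND if (b is None or b > 0) else -FLUX_BOUND
    return float(np.clip(b, -FLUX_BOUND, FLUX_BOUND))


def _load_sbml(path: str) -> MetabolicNetwork:
    """Import hook for SBML Level 3 + FBC models (e.g. a genome-scale model).

    Carbon/electron annotations are taken from metabolite formulae when
    present; the biomass reaction is identified from the FBC objective.
    """
    import cobra

    from .composition import _carbons, _electrons  # formula bookkeeping

    model = cobra.io.read_sbml_model(path)
    objective_rxns = [r for r in model.reactions
                      if r.objective_coefficient not in (0, None)]
    if not objective_rxns:
        raise NetworkValidationError("SBML model declares no objective "
                                     "(biomass) reaction")
    biomass_id = objective_rxns[0].id
    mets = {}
    for m in model.metabolites:
        formula = m.formula or ""
        mets[m.id] = Metabolite(
            m.id, "e" if m.compartment in ("e", "e0", "extracellular") else "c",
            _carbons(formula), _electrons(formula) if formula else 0.0,
            (m.formula_weight / 1000.0) if m.formula_weight else None,
        )
    rxns = [
        Reaction(r.id, {m.id: coeff for m, coeff in r.metabolites.items()},
                 _clip_bound(r.lower_bound), _clip_bound(r.upper_bound))
        for r in model.reactions
    ]
    return MetabolicNetwork(
        metabolites=mets, reactions=rxns, biomass_reaction_id=biomass_id,
        composition=default_composition(),
    )


# ---------------------------------------------------------------------------
# Instantaneous flux optimisation
# ---------------------------------------------------------------------------

def solve_flux_state(
    network: MetabolicNetwork,
    objective: ObjectiveSpec,
    dynamic_bounds: dict[str, tuple[float, float]] | None = None,
    warm_start: np.ndarray | None = None,
) -> FluxState:
    """Maximise the growth-per-flux objective under the current bounds.

    ``dynamic_bounds`` maps reaction ids to (lower, upper) overrides — the
    DFBA engine uses it to pin the glycerol uptake at its kinetic rate and to
    cap the acetate secretion flux.
    """
    prob = build_flux_problem(network, objective, dynamic_bounds)
    ids = network.reaction_ids
    if objective.form == "product":
        v, z = solve_product(prob)
        its = 0
    else:
        v, z, its = solve_fractional(prob, warm_start=warm_start)
    resid = float(np.max(np.abs(prob.S @ v), initial=0.0))
    if resid > 1e-6:
        raise FluxStateError(f"steady-state residual {resid:.2e} exceeds 1e-6")
    mu = prob.mu(v)
    return FluxState(fluxes=dict(zip(ids, v)), mu=mu, objective_value=z,
                     iterations=its)


class FluxStateError(RuntimeError):
    pass


def build_flux_problem(
    network: MetabolicNetwork,
    objective: ObjectiveSpec,
    dynamic_bounds: dict[str, tuple[float, float]] | None = None,
) -> FluxProblem:
    S, _ = network.stoichiometric_matrix("c")
    ids = network.reaction_ids
    lb = np.array([r.lower_bound for r in network.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in network.reactions], dtype=float)
    if dynamic_bounds:
        for rid, (lo, hi) in dynamic_bounds.items():
            j = ids.index(rid)
            lb[j], ub[j] = lo, hi
    a = np.zeros(len(ids))
    for j, r in enumerate(network.reactions):
        if r.id in objective.atp_production_flux_ids:
            a[j] = max(r.stoichiometry.get("atp", 0.0), 0.0)
    return FluxProblem(S=S, lb=lb, ub=ub, c_mu=network.growth_weights,
                       atp_weights=a, w=objective.w)
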
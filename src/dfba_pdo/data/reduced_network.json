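{
 "format_version": 1,
 "metabolites": [
  {
   "id": "glycerol_e",
   "compartment": "e",
   "carbon": 3,
   "electrons": 14,
   "molar_mass": 0.09209
  },
  {
   "id": "pdo_e",
   "compartment": "e",
   "carbon": 3,
   "electrons": 16,
   "molar_mass": 0.07609
  },
  {
   "id": "acetate_e",
   "compartment": "e",
   "carbon": 2,
   "electrons": 8,
   "molar_mass": 0.06005
  },
  {
   "id": "butyrate_e",
   "compartment": "e",
   "carbon": 4,
   "electrons": 20,
   "molar_mass": 0.08811
  },
  {
   "id": "lactate_e",
   "compartment": "e",
   "carbon": 3,
   "electrons": 12,
   "molar_mass": 0.09008
  },
  {
   "id": "ethanol_e",
   "compartment": "e",
   "carbon": 2,
   "electrons": 12,
   "molar_mass": 0.04607
  },
  {
   "id": "butanol_e",
   "compartment": "e",
   "carbon": 4,
   "electrons": 24,
   "molar_mass": 0.07412
  },
  {
   "id": "h2_e",
   "compartment": "e",
   "carbon": 0,
   "electrons": 2,
   "molar_mass": 0.002016
  },
  {
   "id": "co2_e",
   "compartment": "e",
   "carbon": 1,
   "electrons": 0,
   "molar_mass": 0.04401
  },
  {
   "id": "biomass_e",
   "compartment": "e",
   "carbon": 37.40738572362196,
   "electrons": 156.60280738220382,
   "molar_mass": 1.0000000000000002
  },
  {
   "id": "glycerol_c",
   "compartment": "c",
   "carbon": 3,
   "electrons": 14,
   "molar_mass": null
  },
  {
   "id": "dhap",
   "compartment": "c",
   "carbon": 3,
   "electrons": 12,
   "molar_mass": null
  },
  {
   "id": "pyruvate",
   "compartment": "c",
   "carbon": 3,
   "electrons": 10,
   "molar_mass": null
  },
  {
   "id": "accoa",
   "compartment": "c",
   "carbon": 2,
   "electrons": 8,
   "molar_mass": null
  },
  {
   "id": "coa",
   "compartment": "c",
   "carbon": 0,
   "electrons": 0,
   "molar_mass": null
  },
  {
   "id": "h2_c",
   "compartment": "c",
   "carbon": 0,
   "electrons": 2,
   "molar_mass": null
  },
  {
   "id": "nadh",
   "compartment": "c",
   "carbon": 0,
   "electrons": 2,
   "molar_mass": null
  },
  {
   "id": "fdred",
   "compartment": "c",
   "carbon": 0,
   "electrons": 2,
   "molar_mass": null
  },
  {
   "id": "atp",
   "compartment": "c",
   "carbon": 0,
   "electrons": 0,
   "molar_mass": null
  }
 ],
 "reactions": [
  {
   "id": "glycerol_uptake",
   "stoichiometry": {
    "glycerol_e": -1,
    "glycerol_c": 1
   },
   "lower_bound": 0,
   "upper_bound": 1000.0
  },
  {
   "id": "pdo_synthesis",
   "stoichiometry": {
    "glycerol_c": -1,
    "nadh": -1,
    "pdo_e": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "glycerol_oxidation",
   "stoichiometry": {
    "glycerol_c": -1,
    "atp": -1,
    "dhap": 1,
    "nadh": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "glycolysis_lower",
   "stoichiometry": {
    "dhap": -1,
    "pyruvate": 1,
    "nadh": 1,
    "atp": 2
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "pfor",
   "stoichiometry": {
    "pyruvate": -1,
    "coa": -1,
    "accoa": 1,
    "co2_e": 1,
    "fdred": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "hydrogenase",
   "stoichiometry": {
    "fdred": -1,
    "h2_c": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "nadh_hydrogenase",
   "stoichiometry": {
    "nadh": -1,
    "h2_c": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "h2_secretion",
   "stoichiometry": {
    "h2_c": -1,
    "h2_e": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "fnor",
   "stoichiometry": {
    "fdred": -1,
    "nadh": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "acetate_kinase",
   "stoichiometry": {
    "accoa": -1,
    "acetate_e": 1,
    "atp": 1,
    "coa": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "butyrate_kinase",
   "stoichiometry": {
    "accoa": -2,
    "nadh": -2,
    "butyrate_e": 1,
    "atp": 1,
    "coa": 2
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "ldh",
   "stoichiometry": {
    "pyruvate": -1,
    "nadh": -1,
    "lactate_e": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "adh",
   "stoichiometry": {
    "accoa": -1,
    "nadh": -2,
    "ethanol_e": 1,
    "coa": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "bdh",
   "stoichiometry": {
    "accoa": -2,
    "nadh": -4,
    "butanol_e": 1,
    "coa": 2
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "atp_maintenance",
   "stoichiometry": {
    "atp": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  },
  {
   "id": "biomass",
   "stoichiometry": {
    "glycerol_c": -12.469128574540653,
    "atp": -40.0,
    "nadh": 8.982496330682665,
    "biomass_e": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0
  }
 ],
 "biomass_reaction_id": "biomass",
 "gam": 40.0,
 "ngam": 0.0,
 "atp_production_flux_ids": [
  "acetate_kinase",
  "butyrate_kinase",
  "glycolysis_lower"
 ],
 "composition": {
  "macromolecule_fractions": {
   "protein": 0.52,
   "rna": 0.155,
   "dna": 0.03,
   "lipid": 0.075,
   "teichoic_acid": 0.03,
   "peptidoglycan": 0.06,
   "carbohydrate": 0.1,
   "trace": 0.03
  },
  "mass_shares": {
   "ala": 0.0677591129968015,
   "arg": 0.07590472897389443,
   "asn": 0.04710053207509985,
   "asp": 0.04745132888374886,
   "cys": 0.01631678910198853,
   "gln": 0.056732384133786735,
   "glu": 0.05711436288098232,
   "gly": 0.06839036504083858,
   "his": 0.022125439203070772,
   "ile": 0.05611679435918731,
   "leu": 0.08729279122540248,
   "lys": 0.07412174953047651,
   "met": 0.0342797880876724,
   "phe": 0.045804176253435885,
   "pro": 0.03739623904942367,
   "ser": 0.03330288076906068,
   "thr": 0.04435377246555287,
   "trp": 0.017797463770762426,
   "tyr": 0.03732140556580806,
   "val": 0.07331789563300595,
   "amp": 0.2636097770415819,
   "gmp": 0.3393921159167463,
   "cmp": 0.1887457104176714,
   "ump": 0.20825239662400044,
   "damp": 0.33438088680971007,
   "dgmp": 0.1805772578566205,
   "dcmp": 0.15976186276379498,
   "dtmp": 0.32527999256987444,
   "fa12_0": 0.030739146895422884,
   "fa14_0": 0.07008799244605282,
   "fa16_0": 0.27544191885440955,
   "fa16_1": 0.11711847902255544,
   "fa18_0": 0.08730738975646692,
   "fa18_1": 0.13003302700536598,
   "fa17_cyc": 0.08238383534264049,
   "pe": 0.11680041059430078,
   "pg": 0.05547031754062617,
   "clpn": 0.03461748254215878,
   "nad": 0.25252252107036693,
   "nadp": 0.1476339483669392,
   "fad": 0.13000344984758017,
   "coa": 0.19053117954899376,
   "sam": 0.1318766545276031,
   "thf": 0.1474322466385169
  },
  "scale": 1.0
 }
}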
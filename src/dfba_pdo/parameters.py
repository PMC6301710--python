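"""The 60-parameter input space shared by sensitivity analysis and the PBM.

The perturbable inputs of the dynamic model are grouped as

* 44 biomass precursor coefficients (``prec:<name>``),
* 8 macromolecule mass fractions (``macro:<name>``),
* 3 acetate-secretion kinetic constants (v0_aa, vinf_aa, r_aa),
* 2 death constants (kd_lim, kd_exc),
* 3 glycerol-uptake kinetic constants (vmax_gly, ks_gly, ki_gly).

Sampling draws each parameter from an independent normal distribution with a
group-specific relative standard deviation (30% by default, 20% for the
glycerol-uptake kinetics), truncated to positive values by resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import (MACROMOLECULES, PRECURSORS, BiomassComposition,
                          default_composition)
from .kinetics import KineticParams
from .network import MetabolicNetwork, build_reduced_network

__all__ = ["ParameterEnsemble", "sample_parameter_ensemble", "PARAMETER_GROUPS",
           "default_base_values", "build_model"]

_ACETATE = ("v0_aa", "vinf_aa", "r_aa")
_DEATH = ("kd_lim", "kd_exc")
_GLYCEROL = ("vmax_gly", "ks_gly", "ki_gly")

PARAMETER_GROUPS: dict[str, tuple[str, ...]] = {
    "precursors44": tuple(f"prec:{p}" for p in PRECURSORS),
    "macromolecules8": tuple(f"macro:{m}" for m in MACROMOLECULES),
    "acetate3": _ACETATE,
    "death2": _DEATH,
    "glycerol3": _GLYCEROL,
}
PARAMETER_GROUPS["all57"] = (PARAMETER_GROUPS["precursors44"]
                             + PARAMETER_GROUPS["macromolecules8"]
                             + PARAMETER_GROUPS["acetate3"]
                             + PARAMETER_GROUPS["death2"])
PARAMETER_GROUPS["all60"] = PARAMETER_GROUPS["all57"] + PARAMETER_GROUPS["glycerol3"]

#: default relative standard deviations per group
DEFAULT_RSD: dict[str, float] = {
    "precursors44": 0.30, "macromolecules8": 0.30, "acetate3": 0.30,
    "death2": 0.30, "glycerol3": 0.20,
}


def default_base_values(kinetics: KineticParams | None = None,
                        composition: BiomassComposition | None = None
                        ) -> dict[str, float]:
    kin = kinetics or KineticParams()
    comp = composition or default_composition()
    base: dict[str, float] = {}
    for p in PRECURSORS:
        base[f"prec:{p}"] = comp.mass_shares[p]
    for m in MACROMOLECULES:
        base[f"macro:{m}"] = comp.macromolecule_fractions[m]
    for name in _ACETATE + _DEATH + _GLYCEROL:
        base[name] = getattr(kin, name)
    return base


@dataclass
class ParameterEnsemble:
    """K sampled copies of the model input parameters."""

    base: dict[str, float]
    samples: pd.DataFrame          # K x n_parameters
    rsd_map: dict[str, float]      # parameter name -> RSD used
    seed: int

    @property
    def k(self) -> int:
        return len(self.samples)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.samples.columns)


def _group_of(name: str) -> str:
    for group in ("precursors44", "macromolecules8", "acetate3", "death2",
                  "glycerol3"):
        if name in PARAMETER_GROUPS[group]:
            return group
    raise KeyError(name)


def sample_parameter_ensemble(
    base: dict[str, float] | None = None,
    rsd_map: dict[str, float] | None = None,
    k: int = 2280,
    seed: int = 0,
    parameters: tuple[str, ...] | None = None,
) -> ParameterEnsemble:
    """K independent truncated-normal draws of the chosen parameters.

    ``rsd_map`` may be keyed by group name or by individual parameter name;
    parameters not perturbed (RSD 0) stay at their base value.  Non-positive
    draws are rejected and resampled so every sampled value is positive.
    """
    if k < 2:
        raise ValueError("need at least two ensemble members")
    base = dict(base) if base is not None else default_base_values()
    names = list(parameters) if parameters is not None else list(base)
    rsd_in = dict(DEFAULT_RSD) if rsd_map is None else dict(rsd_map)
    rng = np.random.default_rng(seed)
    cols = {}
    rsd_used = {}
    for name in names:
        rsd = rsd_in.get(name, rsd_in.get(_group_of(name), 0.0))
        if rsd < 0:
            raise ValueError("RSD must be non-negative")
        rsd_used[name] = rsd
        mean = base[name]
        if rsd == 0.0 or mean == 0.0:
            cols[name] = np.full(k, mean)
            continue
        draws = rng.normal(mean, rsd * mean, size=k)
        bad = draws <= 0.0
        while bad.any():
            draws[bad] = rng.normal(mean, rsd * mean, size=int(bad.sum()))
            bad = draws <= 0.0
        cols[name] = draws
    return ParameterEnsemble(base=base, samples=pd.DataFrame(cols),
                             rsd_map=rsd_used, seed=seed)


def build_model(
    row: dict[str, float] | pd.Series,
    base_kinetics: KineticParams | None = None,
    gam: float | None = None,
    ngam: float | None = None,
) -> tuple[MetabolicNetwork, KineticParams]:
    """Materialise (network, kinetics) from one parameter draw.

    Macromolecule fractions are renormalised to sum to one; precursor mass
    shares are used as drawn (their dispersion carries into the biomass
    molecular weight).  Parameters absent from ``row`` keep base values.
    """
    kin = base_kinetics or KineticParams()
    kin_over = {name: float(row[name]) for name in _ACETATE + _DEATH + _GLYCEROL
                if name in row}
    if kin_over:
        kin = kin.with_overrides(**kin_over)
    comp0 = default_composition()
    shares = {p: float(row.get(f"prec:{p}", comp0.mass_shares[p]))
              for p in PRECURSORS}
    fractions = {m: float(row.get(f"macro:{m}", comp0.macromolecule_fractions[m]))
                 for m in MACROMOLECULES}
    total = sum(fractions.values())
    fractions = {m: f / total for m, f in fractions.items()}
    comp = BiomassComposition(fractions, shares)
    net = build_reduced_network(comp, gam=gam if gam is not None else 40.0,
                                ngam=ngam if ngam is not None else 0.0)
    return net, kin
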
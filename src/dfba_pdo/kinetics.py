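"""Time-varying flux constraints and regime logic.

The dynamic model constrains the instantaneous flux problem with two kinetic
rate laws and switches its objective weight and death constant with the
extracellular glycerol level:

* glycerol uptake follows a Ghose–Tyagi substrate-inhibition law,
  ``v = vmax * G/(ks + G) * (1 - G/ki)`` with G in mM — Monod saturation
  multiplied by a linear inhibition term that reaches zero at ``ki``;
* the acetate secretion flux is capped by a logistic function of the glycerol
  uptake flux, rising from a basal value ``v0`` to a plateau ``vinf`` with
  accumulation rate ``R``;
* below the switching glycerol concentration (default 15 g/L) the culture is
  glycerol-limited: the objective weight is w = 1 and cells die at ``kd_lim``;
  at or above it the culture is in glycerol excess: w = 0.04 and ``kd_exc``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "KineticParams",
    "glycerol_uptake_bound",
    "acetate_secretion_bound",
    "objective_weight",
    "death_rate",
]


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants of the dynamic constraints.

    Defaults are the published values for *Clostridium* sp IBUN 158B grown on
    glycerol (acetate and death constants from other *C. butyricum* cultures).

    Attributes
    ----------
    v0_aa : float
        Basal acetate secretion flux as glycerol uptake tends to 0, mmol/gDW/h.
    vinf_aa : float
        Maximum acetate secretion flux (uptake -> infinity), mmol/gDW/h.
    r_aa : float
        Accumulation rate of the acetate flux with glycerol uptake, g*h/mmol.
    kd_lim, kd_exc : float
        First-order death constants at glycerol limitation / excess, 1/h.
    vmax_gly : float
        Maximum glycerol uptake flux, mmol/gDW/h.
    ks_gly : float
        Affinity (half-saturation) constant of glycerol uptake, mM.
    ki_gly : float
        Inhibition constant of glycerol uptake (uptake is 0 at this
        concentration), mM.
    switch_gly : float
        Glycerol concentration separating the limitation and excess regimes,
        g/L.  The boundary itself belongs to the excess regime.
    """

    v0_aa: float = 0.1578
    vinf_aa: float = 11.50
    r_aa: float = 0.0859
    kd_lim: float = 0.0350
    kd_exc: float = 0.0105
    vmax_gly: float = 174.86
    ks_gly: float = 482.1
    ki_gly: float = 755.4
    switch_gly: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "v0_aa", "vinf_aa", "r_aa", "kd_lim", "kd_exc",
            "vmax_gly", "ks_gly", "ki_gly", "switch_gly",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"kinetic parameter {name} must be positive")
        if self.ks_gly >= self.ki_gly:
            raise ValueError("ks_gly must be smaller than ki_gly")
        if self.v0_aa >= self.vinf_aa:
            raise ValueError("v0_aa must be smaller than vinf_aa")

    def with_overrides(self, **kwargs: float) -> "KineticParams":
        return replace(self, **kwargs)


def glycerol_uptake_bound(glycerol_mm: float, p: KineticParams) -> float:
    """Ghose–Tyagi glycerol uptake flux (mmol/gDW/h) at a concentration in mM.

    Zero at zero substrate and at the inhibition constant ``ki_gly``; clamped
    at zero above ``ki_gly``.
    """
    if glycerol_mm < 0:
        raise ValueError("glycerol concentration must be non-negative")
    if glycerol_mm >= p.ki_gly:
        return 0.0
    monod = p.vmax_gly * glycerol_mm / (p.ks_gly + glycerol_mm)
    return monod * (1.0 - glycerol_mm / p.ki_gly)


def acetate_secretion_bound(v_gly: float, p: KineticParams) -> float:
    """Logistic upper bound of the acetate secretion flux (mmol/gDW/h).

    A function of the glycerol uptake flux ``v_gly``: equal to ``v0_aa`` at
    zero uptake, strictly increasing and approaching ``vinf_aa`` from below.
    """
    if v_gly < 0:
        raise ValueError("glycerol uptake flux must be non-negative")
    # Numerically stable form for large exponents: divide through by e^(R*v).
    rv = p.r_aa * v_gly
    if rv > 500.0:
        return p.vinf_aa
    e = math.exp(rv)
    return p.vinf_aa * p.v0_aa * e / (p.vinf_aa + p.v0_aa * (e - 1.0))


def objective_weight(glycerol_gl: float, p: KineticParams) -> float:
    """Objective weight w: 1 under glycerol limitation, 0.04 at excess."""
    if glycerol_gl < 0:
        raise ValueError("glycerol concentration must be non-negative")
    return 0.04 if glycerol_gl >= p.switch_gly else 1.0


def death_rate(glycerol_gl: float, p: KineticParams) -> float:
    """First-order death constant (1/h) for the current glycerol regime."""
    if glycerol_gl < 0:
        raise ValueError("glycerol concentration must be non-negative")
    return p.kd_exc if glycerol_gl >= p.switch_gly else p.kd_lim
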
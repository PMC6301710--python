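"""Design-space scans of culture conditions.

Batch cultures are scanned over a full factorial of initial biomass and
initial glycerol; fed-batch cultures over feed glycerol content (mass %)
crossed with the feeding proportionality constant (alpha for constant flow,
beta for flow coupled to proton secretion / pH control).  Each grid point is
simulated and summarised by production, productivity and yield; fed-batch
points are classified as infeasible / suboptimal / unconsumed-glycerol /
optimal following the selection rules of the study design: the optimal set
is the Pareto frontier of (final PDO, productivity), with the pH-coupled
mode additionally requiring a minimum fed-basis mass conversion of 45% and
at most 5 g/L residual glycerol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import KineticParams
from .simulate import (CultureState, FeedPolicy, SimulationSpec,
                       simulate_fedbatch, simulate_soa, trajectory_metrics)
from .units import mm_to_g_per_l

__all__ = ["ScanSpec", "ScanResult", "batch_factorial_scan", "fedbatch_scan",
           "classify_fedbatch_outcome", "DEFAULT_BATCH_BIOMASS",
           "DEFAULT_BATCH_GLYCEROL"]

#: 15 inoculum levels (g/L); the exponential-phase inoculum cap is 0.12 g/L
DEFAULT_BATCH_BIOMASS = tuple(np.round(np.linspace(0.01, 0.15, 15), 4))
#: 13 initial glycerol levels (g/L)
DEFAULT_BATCH_GLYCEROL = tuple(np.round(np.linspace(5.0, 65.0, 13), 2))

#: fed-batch selection constraints
MIN_MASS_CONVERSION = 0.45
MAX_RESIDUAL_GLYCEROL = 5.0  # g/L


@dataclass
class ScanSpec:
    mode: str = "batch"                 # batch | fedbatch_constant | fedbatch_ph
    axis1: tuple = DEFAULT_BATCH_GLYCEROL   # glycerol0 g/L, or feed mass %
    axis2: tuple = DEFAULT_BATCH_BIOMASS    # X0 g/L, or alpha / beta
    base: SimulationSpec | None = None
    kinetics: KineticParams = field(default_factory=KineticParams)

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "fedbatch_constant", "fedbatch_ph"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if len(self.axis1) == 0 or len(self.axis2) == 0:
            raise ValueError("scan grids must be non-empty")
        if min(self.axis1) < 0 or min(self.axis2) < 0:
            raise ValueError("scan grids must be non-negative")


@dataclass
class ScanResult:
    table: pd.DataFrame                 # one row per grid point
    mode: str

    @property
    def optimum(self) -> pd.Series:
        opt = self.table[self.table["class"] == "optimal"]
        if len(opt) == 0:
            raise ValueError("no grid point classified optimal")
        return opt.loc[opt["q_pdo"].idxmax()]

    def best_by(self, metric: str) -> pd.Series:
        ok = self.table[self.table["class"] != "infeasible"]
        return ok.loc[ok[metric].idxmax()]


def _metric_row(metrics: dict, **axes) -> dict:
    row = dict(axes)
    for key in ("final_pdo", "q_pdo", "y_pdo_mol", "y_pdo_mass",
                "residual_glycerol", "culture_time", "mass_conversion_fed",
                "glycerol_consumed_g", "glycerol_fed_g"):
        row[key] = metrics.get(key, np.nan)
    return row


def batch_factorial_scan(spec: ScanSpec) -> ScanResult:
    """Full factorial over (initial glycerol, initial biomass) batches.

    Points are classified ``optimal`` (argmax of productivity), ``infeasible``
    (simulation failure) or ``suboptimal``.
    """
    if spec.mode != "batch":
        raise ValueError("batch_factorial_scan requires mode='batch'")
    base = spec.base or SimulationSpec(
        network=_default_network(), kinetics=spec.kinetics, tf=48.0,
        n_intervals=96, approach="SOA")
    rows = []
    for gly0 in spec.axis1:
        for x0 in spec.axis2:
            axes = {"glycerol0": gly0, "biomass0": x0}
            try:
                traj = simulate_soa(replace(
                    base,
                    initial=CultureState(t=base.t0, X=x0,
                                         z={"glycerol": gly0}, V=base.initial.V)))
                m = trajectory_metrics(traj)
                row = _metric_row(m, **axes)
                row["class"] = "suboptimal"
            except Exception as exc:  # noqa: BLE001
                row = _metric_row({}, **axes)
                row["class"] = "infeasible"
                row["error"] = str(exc)
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["class"] != "infeasible"
    if ok.any():
        table.loc[table.loc[ok, "q_pdo"].idxmax(), "class"] = "optimal"
    return ScanResult(table=table, mode="batch")


def fedbatch_scan(spec: ScanSpec) -> ScanResult:
    """Grid over (feed glycerol mass %, feeding constant) fed-batch runs."""
    if spec.mode not in ("fedbatch_constant", "fedbatch_ph"):
        raise ValueError("fedbatch_scan requires a fed-batch mode")
    feed_mode = "constant" if spec.mode == "fedbatch_constant" else "ph_coupled"
    base = spec.base or SimulationSpec(
        network=_default_network(), kinetics=spec.kinetics, tf=60.0,
        n_intervals=240, approach="SOA",
        initial=CultureState(X=0.12, z={"glycerol": 46.0}, V=1.0))
    ki_gl = mm_to_g_per_l(spec.kinetics.ki_gly, "glycerol")
    rows = []
    for pct in spec.axis1:
        for rate in spec.axis2:
            axes = {"feed_mass_pct": pct, "rate": rate}
            feed = FeedPolicy.glycerol_feed(feed_mode, rate, pct)
            try:
                traj = simulate_fedbatch(replace(base, feed=feed))
                m = trajectory_metrics(traj)
                row = _metric_row(m, **axes)
                row["class"] = classify_fedbatch_outcome(
                    m, mode=feed_mode, inhibition_gl=ki_gl)
            except Exception as exc:  # noqa: BLE001
                row = _metric_row({}, **axes)
                row["class"] = "infeasible"
                row["error"] = str(exc)
            rows.append(row)
    table = pd.DataFrame(rows)
    _mark_pareto_optimal(table, feed_mode)
    return ScanResult(table=table, mode=spec.mode)


def classify_fedbatch_outcome(metrics: dict, mode: str = "constant",
                              inhibition_gl: float = 69.56) -> str:
    """Outcome class of one fed-batch run (before Pareto marking).

    * ``infeasible``: no PDO formed, or the culture poisoned itself (residual
      glycerol at or beyond the uptake-inhibition concentration);
    * ``unconsumed_glycerol`` (pH-coupled mode): residual above 5 g/L;
    * ``candidate`` otherwise — the Pareto step may upgrade it to optimal.
    """
    if not np.isfinite(metrics.get("final_pdo", np.nan)):
        return "infeasible"
    if metrics["final_pdo"] <= 1e-6 or metrics["residual_glycerol"] >= inhibition_gl:
        return "infeasible"
    if mode == "ph_coupled" and metrics["residual_glycerol"] > MAX_RESIDUAL_GLYCEROL:
        return "unconsumed_glycerol"
    return "candidate"


def _mark_pareto_optimal(table: pd.DataFrame, feed_mode: str) -> None:
    cand = table["class"] == "candidate"
    if feed_mode == "ph_coupled":
        cand &= table["mass_conversion_fed"] >= MIN_MASS_CONVERSION
        cand &= table["residual_glycerol"] <= MAX_RESIDUAL_GLYCEROL
    idx = table.index[cand]
    pdo = table.loc[idx, "final_pdo"].to_numpy()
    q = table.loc[idx, "q_pdo"].to_numpy()
    optimal = []
    for i in range(len(idx)):
        dominated = np.any((pdo >= pdo[i]) & (q >= q[i])
                           & ((pdo > pdo[i]) | (q > q[i])))
        if not dominated:
            optimal.append(idx[i])
    table.loc[table["class"] == "candidate", "class"] = "suboptimal"
    table.loc[optimal, "class"] = "optimal"


def _default_network():
    from .network import build_reduced_network
    return build_reduced_network()
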
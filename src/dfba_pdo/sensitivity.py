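"""Global sensitivity analysis: MPSA and PRCC.

MPSA (multi-parametric sensitivity analysis) classifies each Monte-Carlo
parameter draw as *acceptable* or *unacceptable* by comparing the mean
squared error of its predicted outputs against error-propagation thresholds,
then scores each input parameter by the Kolmogorov–Smirnov distance between
the parameter's acceptable and unacceptable empirical distributions.  A
parameter whose K–S statistic stays below the critical value 1.36/sqrt(K)
has statistically indistinguishable class distributions, i.e. no detectable
influence.

PRCC (partial rank correlation coefficient) rank-transforms parameters and
outputs and correlates each parameter with each output while controlling
for all other parameters, yielding a signed monotone-influence measure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import ParameterEnsemble, build_model
from .simulate import SimulationSpec, Trajectory, simulate_soa, trajectory_metrics

__all__ = [
    "mse_profile", "classify_profiles", "ks_statistic", "ks_critical_value",
    "run_mpsa", "run_prcc", "MpsaResult", "PrccResult", "DEFAULT_THRESHOLDS",
    "evaluate_ensemble",
]

#: error-propagation classification thresholds per output (squared units)
DEFAULT_THRESHOLDS: dict[str, float] = {
    "pdo_profile": 6.0 ** 2,       # (6 g/L)^2
    "q_pdo": 0.057 ** 2,           # (0.057 g/L/h)^2
    "y_pdo_mol": 0.052 ** 2,       # (0.052 mol/mol)^2
}


def mse_profile(predicted: np.ndarray, observed: np.ndarray,
                reduce_mean: bool = True) -> float:
    """Squared-error statistic between predicted and observed series.

    The mean of squared residuals by default, so per-observation thresholds
    from error propagation apply directly; ``reduce_mean=False`` returns the
    raw sum instead.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed series differ in length")
    if predicted.size == 0:
        raise ValueError("need at least one observation")
    sq = float(np.sum((observed - predicted) ** 2))
    return sq / predicted.size if reduce_mean else sq


def classify_profiles(mse: pd.DataFrame,
                      thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Boolean acceptability flags per profile and output.

    A profile is *unacceptable* for an output when its MSE is strictly
    greater than the threshold; a profile exactly at the threshold is
    acceptable.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    flags = {}
    for out, thr in thresholds.items():
        if thr <= 0:
            raise ValueError("thresholds must be positive")
        if out in mse.columns:
            flags[out] = ~(mse[out] > thr)
    return pd.DataFrame(flags, index=mse.index)


def ks_statistic(values_acceptable: np.ndarray,
                 values_unacceptable: np.ndarray) -> float:
    """Supremum distance between the two empirical CDFs, in [0, 1]."""
    a = np.asarray(values_acceptable, dtype=float)
    b = np.asarray(values_unacceptable, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def ks_critical_value(k: int) -> float:
    """Critical K–S value 1.36/sqrt(K) at the 5% significance level."""
    if k < 1:
        raise ValueError("K must be at least 1")
    return 1.36 / math.sqrt(k)


@dataclass
class MpsaResult:
    ks: pd.DataFrame               # parameter x output K-S statistics
    acceptable: pd.DataFrame       # K x outputs boolean flags
    mse: pd.DataFrame              # K x outputs error statistics
    thresholds: dict[str, float]
    d_crit: float
    n_failed: int

    def significant(self) -> pd.DataFrame:
        """True where the parameter influences the output (K-S >= d_crit)."""
        return self.ks >= self.d_crit

    def to_long(self) -> pd.DataFrame:
        long = self.ks.stack().rename("value").reset_index()
        long.columns = ["parameter", "output", "value"]
        long["statistic"] = "ks"
        long["significant"] = long["value"] >= self.d_crit
        return long


@dataclass
class PrccResult:
    prcc: pd.DataFrame             # parameter x output, in [-1, 1]

    def to_long(self) -> pd.DataFrame:
        long = self.prcc.stack().rename("value").reset_index()
        long.columns = ["parameter", "output", "value"]
        long["statistic"] = "prcc"
        return long


# ---------------------------------------------------------------------------

def _default_simulator(spec: SimulationSpec):
    def run(row: pd.Series) -> Trajectory:
        net, kin = build_model(row)
        return simulate_soa(
            SimulationSpec(network=net, kinetics=kin, initial=spec.initial,
                           t0=spec.t0, tf=spec.tf,
                           n_intervals=spec.n_intervals, approach="SOA"))
    return run


def evaluate_ensemble(
    ensemble: ParameterEnsemble,
    scenario: SimulationSpec,
    observed: pd.DataFrame,
    simulator=None,
    reduce_mean: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Simulate every draw and compute the per-draw output error statistics.

    ``observed`` needs columns ``t``, ``pdo`` and (for the scalar outputs)
    ``glycerol``; predicted PDO is interpolated at the observation times.
    Returns (K x outputs error table, number of failed simulations); failed
    draws are excluded (NaN rows).
    """
    simulator = simulator or _default_simulator(scenario)
    t_obs = observed["t"].to_numpy(dtype=float)
    pdo_obs = observed["pdo"].to_numpy(dtype=float)
    q_obs, y_obs = _observed_scalars(observed)
    rows = []
    n_failed = 0
    for _, draw in ensemble.samples.iterrows():
        try:
            traj = simulator(draw)
            st = traj.states
            pdo_pred = np.interp(t_obs, st["t"], st["pdo"])
            # predicted scalars over the same observation window as the data
            gly_pred = np.interp(t_obs, st["t"], st["glycerol"])
            q_pred = (pdo_pred[-1] - pdo_pred[0]) / max(t_obs[-1] - t_obs[0], 1e-12)
            consumed = max(gly_pred[0] - gly_pred[-1], 1e-12)
            y_pred = (pdo_pred[-1] - pdo_pred[0]) / consumed * (92.09 / 76.09)
            m = trajectory_metrics(traj)
            rows.append({
                "pdo_profile": mse_profile(pdo_pred, pdo_obs, reduce_mean),
                "q_pdo": (q_pred - q_obs) ** 2,
                "y_pdo_mol": (y_pred - y_obs) ** 2,
                # whole-culture metrics of the draw (PRCC output variables)
                "q_pdo_value": m["q_pdo"],
                "y_pdo_mol_value": m["y_pdo_mol"],
                "final_pdo_value": m["final_pdo"],
            })
        except Exception:  # noqa: BLE001 - failures are counted, not fatal
            n_failed += 1
            rows.append({c: np.nan for c in
                         ("pdo_profile", "q_pdo", "y_pdo_mol",
                          "q_pdo_value", "y_pdo_mol_value", "final_pdo_value")})
    return pd.DataFrame(rows, index=ensemble.samples.index), n_failed


def _observed_scalars(observed: pd.DataFrame) -> tuple[float, float]:
    t = observed["t"].to_numpy(dtype=float)
    pdo = observed["pdo"].to_numpy(dtype=float)
    span = max(t[-1] - t[0], 1e-12)
    q = (pdo[-1] - pdo[0]) / span
    if "glycerol" in observed:
        gly = observed["glycerol"].to_numpy(dtype=float)
        consumed = max(gly[0] - gly[-1], 1e-12)
        y = (pdo[-1] - pdo[0]) / consumed * (92.09 / 76.09)
    else:
        y = 0.0
    return q, y


def run_mpsa(
    ensemble: ParameterEnsemble,
    scenario: SimulationSpec,
    observed: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    simulator=None,
    errors: pd.DataFrame | None = None,
) -> MpsaResult:
    """Full MPSA: simulate, classify, and score K-S per (parameter, output).

    Parameters whose acceptable or unacceptable class is empty for an output
    are reported as NaN (not classifiable) for that output.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    if errors is None:
        errors, n_failed = evaluate_ensemble(ensemble, scenario, observed,
                                             simulator)
    else:
        n_failed = int(errors.isna().any(axis=1).sum())
    ok = ~errors.isna().any(axis=1)
    flags = classify_profiles(errors.loc[ok], thresholds)
    ks = pd.DataFrame(index=ensemble.parameter_names, columns=list(flags.columns),
                      dtype=float)
    for out in flags.columns:
        acc = flags[out]
        for name in ensemble.parameter_names:
            vals = ensemble.samples.loc[ok, name].to_numpy()
            if vals.std() == 0.0:
                ks.loc[name, out] = 0.0
                continue
            a, u = vals[acc.to_numpy()], vals[~acc.to_numpy()]
            if a.size == 0 or u.size == 0:
                ks.loc[name, out] = np.nan   # not classifiable
                continue
            ks.loc[name, out] = ks_statistic(a, u)
    return MpsaResult(ks=ks, acceptable=flags, mse=errors,
                      thresholds=dict(thresholds),
                      d_crit=ks_critical_value(int(ok.sum())),
                      n_failed=n_failed)


def _partial_rank_correlation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """PRCC of each column of x with y, controlling for the other columns."""
    k, p = x.shape
    rx = np.apply_along_axis(stats.rankdata, 0, x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean(axis=0)) / np.where(rx.std(axis=0) == 0, 1, rx.std(axis=0))
    sy = ry.std()
    if sy == 0:
        warnings.warn("constant output: PRCC reported as 0")
        return np.zeros(p)
    ry = (ry - ry.mean()) / sy
    out = np.empty(p)
    for j in range(p):
        others = np.delete(rx, j, axis=1)
        A = np.column_stack([others, np.ones(k)])
        res_x = rx[:, j] - A @ np.linalg.lstsq(A, rx[:, j], rcond=None)[0]
        res_y = ry - A @ np.linalg.lstsq(A, ry, rcond=None)[0]
        denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
        out[j] = float(res_x @ res_y / denom) if denom > 1e-12 else 0.0
    return out


def run_prcc(
    ensemble: ParameterEnsemble,
    outputs: pd.DataFrame,
    output_names: tuple[str, ...] = ("q_pdo", "y_pdo_mol"),
    mode: str = "partial_rank",
) -> PrccResult:
    """Partial rank correlation of every parameter with the scalar outputs.

    ``outputs`` holds one column per output variable (K rows aligned with the
    ensemble).  ``mode="pearson"`` computes plain Pearson correlations on the
    raw values instead of partial rank correlations.
    """
    if ensemble.k < 10:
        raise ValueError("PRCC needs at least 10 ensemble members")
    ok = ~outputs[list(output_names)].isna().any(axis=1)
    varying = [n for n in ensemble.parameter_names
               if ensemble.samples[n].std() > 0]
    if int(ok.sum()) <= len(varying) + 2:
        warnings.warn("PRCC with K <= number of varying parameters is "
                      "degenerate; increase the ensemble size")
    x = ensemble.samples.loc[ok, varying].to_numpy(dtype=float)
    prcc = pd.DataFrame(index=ensemble.parameter_names,
                        columns=list(output_names), dtype=float)
    for out in output_names:
        y = outputs.loc[ok, out].to_numpy(dtype=float)
        if mode == "pearson":
            with np.errstate(invalid="ignore"):
                vals = [float(np.corrcoef(x[:, j], y)[0, 1])
                        for j in range(x.shape[1])]
            vals = np.nan_to_num(np.array(vals))
        else:
            vals = _partial_rank_correlation(x, y)
        prcc.loc[varying, out] = vals
        prcc.loc[[n for n in ensemble.parameter_names if n not in varying], out] = 0.0
    return PrccResult(prcc=prcc)
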
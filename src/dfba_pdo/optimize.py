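"""Numerical core: the instantaneous flux optimisation.

The per-instant problem is

    maximise  Z = mu / ( w * sum_j v_j^2 + (1 - w) * v_ATPprod^2 )
    subject   S v = 0,   lb <= v <= ub

with ``mu`` linear in ``v`` and a convex quadratic denominator.  This is a
concave-linear over convex-quadratic fractional programme, which Dinkelbach's
algorithm solves to global optimality: iterate

    v_{k+1} = argmax  mu(v) - lambda_k * D(v)     (a convex QP)
    lambda_{k+1} = mu(v_{k+1}) / D(v_{k+1})

until mu - lambda * D ~ 0.  Each subproblem is an equality-constrained QP
with box bounds, solved by a primal active-set method on the bound
constraints (KKT systems via least squares, so redundant stoichiometric rows
— e.g. a conserved carrier pair — are harmless).  scipy's SLSQP serves as a
fallback and, in the test-suite, as an independent oracle.

The literal product reading of the objective, Z = mu * D, is also available;
being non-concave it is handled by multistart SLSQP only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as sopt

__all__ = ["FluxProblem", "solve_fractional", "InfeasibleProblemError",
           "FluxSolverError"]

_BOUND_EPS = 1e-9


class InfeasibleProblemError(RuntimeError):
    """The constraint set S v = 0, lb <= v <= ub is empty."""


class FluxSolverError(RuntimeError):
    """The NLP failed to converge after multistart."""


@dataclass
class FluxProblem:
    """Arrays of one instantaneous flux problem."""

    S: np.ndarray          # m x n stoichiometric matrix (balanced metabolites)
    lb: np.ndarray
    ub: np.ndarray
    c_mu: np.ndarray       # growth weights: mu = c_mu . v
    atp_weights: np.ndarray  # v_ATPprod = atp_weights . v (>=0 entries)
    w: float               # objective weight in (0, 1]

    def denominator(self, v: np.ndarray) -> float:
        va = float(self.atp_weights @ v)
        return self.w * float(v @ v) + (1.0 - self.w) * va * va

    def mu(self, v: np.ndarray) -> float:
        return float(self.c_mu @ v)

    def _hessian(self, lam: float) -> np.ndarray:
        n = len(self.lb)
        H = 2.0 * lam * self.w * np.eye(n)
        if self.w < 1.0:
            a = self.atp_weights
            H += 2.0 * lam * (1.0 - self.w) * np.outer(a, a)
        return H


def _feasible_point(prob: FluxProblem, maximize_mu: bool = True) -> np.ndarray:
    c = -prob.c_mu if maximize_mu else np.zeros_like(prob.c_mu)
    res = sopt.linprog(
        c, A_eq=prob.S, b_eq=np.zeros(prob.S.shape[0]),
        bounds=list(zip(prob.lb, prob.ub)), method="highs",
    )
    if not res.success:
        raise InfeasibleProblemError(
            f"flux constraint set is infeasible: {res.message}")
    return np.clip(res.x, prob.lb, prob.ub)


def _solve_qp_active_set(
    prob: FluxProblem, lam: float, x0: np.ndarray, max_iter: int = 200
) -> np.ndarray | None:
    """min 0.5 x'Hx - c_mu'x  s.t.  Sx=0, lb<=x<=ub, from feasible x0.

    Active set over the box constraints; returns None if it fails to
    converge (caller falls back to SLSQP).
    """
    H = prob._hessian(lam)
    q = -prob.c_mu
    S, lb, ub = prob.S, prob.lb, prob.ub
    m, n = S.shape
    x = x0.copy()

    fixed = lb >= ub - _BOUND_EPS          # pinned fluxes: never released
    at_lo = x <= lb + _BOUND_EPS
    at_hi = x >= ub - _BOUND_EPS
    active_lo = (at_lo & ~fixed)
    active_hi = (at_hi & ~fixed & ~active_lo)

    for _ in range(max_iter):
        free = ~(fixed | active_lo | active_hi)
        nf = int(free.sum())
        g = H @ x + q
        if nf == 0:
            p = np.zeros(n)
            nu = np.linalg.lstsq(S.T, -g, rcond=None)[0]
        else:
            Hff = H[np.ix_(free, free)]
            Sf = S[:, free]
            kkt = np.block([[Hff, Sf.T], [Sf, np.zeros((m, m))]])
            rhs = np.concatenate([-g[free], np.zeros(m)])
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
            p = np.zeros(n)
            p[free] = sol[:nf]
            nu = sol[nf:]
        if np.max(np.abs(p)) < 1e-11:
            # multipliers of the active bounds
            mult = g + S.T @ nu
            worst, worst_idx, lower = 0.0, -1, True
            for i in np.flatnonzero(active_lo):
                if mult[i] < worst - 1e-10:
                    worst, worst_idx, lower = mult[i], i, True
            for i in np.flatnonzero(active_hi):
                if -mult[i] < worst - 1e-10:
                    worst, worst_idx, lower = -mult[i], i, False
            if worst_idx < 0:
                return np.clip(x, lb, ub)
            if lower:
                active_lo[worst_idx] = False
            else:
                active_hi[worst_idx] = False
            continue
        # longest feasible step along p
        alpha, block, block_hi = 1.0, -1, False
        for i in np.flatnonzero(free):
            if p[i] < -1e-13:
                a = (lb[i] - x[i]) / p[i]
                if a < alpha:
                    alpha, block, block_hi = a, i, False
            elif p[i] > 1e-13:
                a = (ub[i] - x[i]) / p[i]
                if a < alpha:
                    alpha, block, block_hi = a, i, True
        x = x + max(alpha, 0.0) * p
        if block >= 0 and alpha < 1.0:
            if block_hi:
                active_hi[block] = True
                x[block] = ub[block]
            else:
                active_lo[block] = True
                x[block] = lb[block]
    return None


def _solve_qp_slsqp(prob: FluxProblem, lam: float, x0: np.ndarray) -> np.ndarray:
    H = prob._hessian(lam)
    q = -prob.c_mu

    def fun(x):
        return 0.5 * x @ H @ x + q @ x

    def jac(x):
        return H @ x + q

    res = sopt.minimize(
        fun, x0, jac=jac, method="SLSQP",
        bounds=list(zip(prob.lb, prob.ub)),
        constraints=[{"type": "eq", "fun": lambda x: prob.S @ x,
                      "jac": lambda x: prob.S}],
        options={"maxiter": 300, "ftol": 1e-12},
    )
    if not res.success and np.max(np.abs(prob.S @ res.x)) > 1e-6:
        raise FluxSolverError(f"QP subproblem failed: {res.message}")
    return np.clip(res.x, prob.lb, prob.ub)


def _solve_qp(prob: FluxProblem, lam: float, x0: np.ndarray) -> np.ndarray:
    x = _solve_qp_active_set(prob, lam, x0)
    if x is None:
        x = _solve_qp_slsqp(prob, lam, x0)
    return x


def _min_denominator_point(prob: FluxProblem, x0: np.ndarray) -> np.ndarray:
    """argmin D(v) over the feasible set (used when max mu = 0)."""
    zero_mu = FluxProblem(prob.S, prob.lb, prob.ub,
                          np.zeros_like(prob.c_mu), prob.atp_weights, prob.w)
    return _solve_qp(zero_mu, 1.0, x0)


def solve_fractional(
    prob: FluxProblem,
    warm_start: np.ndarray | None = None,
    tol: float = 1e-10,
    max_outer: int = 60,
) -> tuple[np.ndarray, float, int]:
    """Globally maximise mu/D over the feasible flux polytope.

    Returns (v*, Z*, number of Dinkelbach iterations).  If the only feasible
    growth is zero, the minimum-denominator point is returned with Z = 0 (and
    v = 0 whenever the zero flux vector is feasible).
    """
    if not (0.0 < prob.w <= 1.0):
        raise ValueError("objective weight w must be in (0, 1]")
    if (warm_start is not None and _is_feasible(prob, warm_start)
            and prob.mu(warm_start) > 1e-9):
        # hot path for consecutive DFBA steps: skip the feasibility LP
        starts = [np.clip(warm_start, prob.lb, prob.ub)]
    else:
        v_best = _feasible_point(prob, maximize_mu=True)
        mu_max = prob.mu(v_best)
        if mu_max <= 1e-9:
            v = _min_denominator_point(prob, v_best)
            if prob.denominator(v) < 1e-14:
                v = np.where(np.abs(v) < 1e-9, 0.0, v)
            return v, 0.0, 0
        starts = [v_best]
        if warm_start is not None and _is_feasible(prob, warm_start):
            starts.insert(0, warm_start)
    best = None
    for x0 in starts:
        d0 = prob.denominator(x0)
        if d0 < 1e-14:
            # vanishing flux scale (e.g. uptake pinned at ~0): the culture is
            # effectively inactive and the objective value is immaterial
            return x0, 0.0, 0
        lam = prob.mu(x0) / d0
        v = x0
        for it in range(1, max_outer + 1):
            v = _solve_qp(prob, lam, v)
            mu, d = prob.mu(v), prob.denominator(v)
            gap = mu - lam * d
            if d < 1e-14:
                break
            if abs(gap) <= tol * max(1.0, abs(lam) * d):
                z = mu / d
                if best is None or z > best[1]:
                    best = (v, z, it)
                break
            lam = mu / d
        else:
            raise FluxSolverError("Dinkelbach iteration did not converge")
    if best is None:
        raise FluxSolverError("no valid fractional optimum found")
    return best


def _is_feasible(prob: FluxProblem, v: np.ndarray, tol: float = 1e-7) -> bool:
    return (np.all(v >= prob.lb - tol) and np.all(v <= prob.ub + tol)
            and float(np.max(np.abs(prob.S @ v), initial=0.0)) < tol)


def solve_product(prob: FluxProblem, seeds: int = 5) -> tuple[np.ndarray, float]:
    """Maximise the literal product mu * D by multistart SLSQP."""
    x0 = _feasible_point(prob, maximize_mu=True)
    rng = np.random.default_rng(0)
    best = None
    starts = [x0] + [np.clip(x0 * rng.uniform(0.2, 1.0, len(x0)),
                             prob.lb, prob.ub) for _ in range(seeds - 1)]

    def neg(x):
        return -prob.mu(x) * prob.denominator(x)

    for s in starts:
        res = sopt.minimize(
            neg, s, method="SLSQP", bounds=list(zip(prob.lb, prob.ub)),
            constraints=[{"type": "eq", "fun": lambda x: prob.S @ x,
                          "jac": lambda x: prob.S}],
            options={"maxiter": 300, "ftol": 1e-12},
        )
        if res.success or np.max(np.abs(prob.S @ res.x)) < 1e-7:
            z = -neg(res.x)
            if best is None or z > best[1]:
                best = (np.clip(res.x, prob.lb, prob.ub), z)
    if best is None:
        raise FluxSolverError("product-form NLP failed from all starts")
    return best
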
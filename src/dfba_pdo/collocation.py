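"""Orthogonal collocation primitives.

States of the dynamic-optimisation (DOA) solution strategy are represented by
Lagrange interpolating polynomials through the roots of classical orthogonal
polynomials; the ODE right-hand side is enforced at those roots through the
derivative of the interpolant.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import hermite_e, laguerre, legendre

__all__ = ["collocation_nodes", "lagrange_derivative_matrix", "lagrange_interpolate"]

_FAMILIES = ("chebyshev1", "chebyshev2", "laguerre", "legendre", "hermite")


def collocation_nodes(
    family: str, n: int, interval: tuple[float, float] | None = None
) -> np.ndarray:
    """Roots of the degree-``n`` orthogonal polynomial of ``family``, sorted.

    Families with compact natural support (Legendre, both Chebyshev kinds)
    have their roots on (-1, 1); Laguerre roots lie in (0, inf) and Hermite
    roots are symmetric about 0.  If ``interval`` is given, the roots are
    affinely mapped from the hull of the natural support onto it so that they
    fall strictly inside the integration interval.
    """
    if n < 2:
        raise ValueError("need at least 2 collocation points")
    if family == "legendre":
        c = np.zeros(n + 1)
        c[-1] = 1.0
        nodes = legendre.legroots(c)
        natural = (-1.0, 1.0)
    elif family == "chebyshev1":
        nodes = np.cos((2 * np.arange(1, n + 1) - 1) * np.pi / (2 * n))[::-1]
        natural = (-1.0, 1.0)
    elif family == "chebyshev2":
        nodes = np.cos(np.arange(1, n + 1) * np.pi / (n + 1))[::-1]
        natural = (-1.0, 1.0)
    elif family == "laguerre":
        c = np.zeros(n + 1)
        c[-1] = 1.0
        nodes = laguerre.lagroots(c)
        # map from the hull of the roots (0, max) rather than an infinite support
        natural = (0.0, float(nodes.max()) * (1.0 + 1.0 / n))
    elif family == "hermite":
        c = np.zeros(n + 1)
        c[-1] = 1.0
        nodes = hermite_e.hermeroots(c)
        m = float(np.abs(nodes).max()) * (1.0 + 1.0 / n)
        natural = (-m, m)
    else:
        raise ValueError(f"unknown collocation family {family!r}; "
                         f"choose one of {_FAMILIES}")
    nodes = np.sort(np.asarray(nodes, dtype=float))
    if interval is not None:
        a, b = interval
        lo, hi = natural
        nodes = a + (nodes - lo) * (b - a) / (hi - lo)
    return nodes


def _barycentric_weights(nodes: np.ndarray) -> np.ndarray:
    diff = nodes[:, None] - nodes[None, :]
    np.fill_diagonal(diff, 1.0)
    return 1.0 / diff.prod(axis=1)


def lagrange_derivative_matrix(nodes: np.ndarray) -> np.ndarray:
    """Differentiation matrix D of the Lagrange basis on ``nodes``.

    ``D[a, b]`` is the derivative of the b-th cardinal polynomial evaluated at
    node a, so ``D @ f(nodes)`` is exact for any polynomial ``f`` of degree
    below ``len(nodes)``.
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim != 1 or len(nodes) < 2:
        raise ValueError("need a 1-D array of at least two nodes")
    if len(np.unique(nodes)) != len(nodes):
        raise ValueError("collocation nodes must be distinct")
    w = _barycentric_weights(nodes)
    n = len(nodes)
    diff = nodes[:, None] - nodes[None, :]
    np.fill_diagonal(diff, np.inf)
    d = (w[None, :] / w[:, None]) / diff
    # diagonal: rows of D sum to zero (derivative of the constant 1 is 0)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(d, -d.sum(axis=1))
    return d


def lagrange_interpolate(nodes: np.ndarray, values: np.ndarray, x: float) -> np.ndarray:
    """Evaluate the Lagrange interpolant through (nodes, values) at ``x``.

    ``values`` may be 1-D (one state) or 2-D with one row per node.
    """
    nodes = np.asarray(nodes, dtype=float)
    values = np.asarray(values, dtype=float)
    hit = np.flatnonzero(np.isclose(x, nodes, rtol=0.0, atol=1e-14))
    if hit.size:
        return values[hit[0]]
    w = _barycentric_weights(nodes)
    r = w / (x - nodes)
    return (r @ values) / r.sum()
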
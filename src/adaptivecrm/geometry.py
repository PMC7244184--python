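"""Simplex representation of strategies and supply, and convex-hull tests.

Coexistence of all species at a stationary state of the adaptive model can be
read geometrically: value-weighted, sum-normalized metabolic strategies
alpha_hat_{sigma i} = v_i alpha_{sigma i} / sum_j v_j alpha_{sigma j} and the
likewise-rescaled supply vector all live on the (p-1)-simplex, and the system
self-organizes so that the supply point lies inside the convex hull of the
strategy points.  With resource degradation the relevant supply point is the
effective supply s_tilde_i = v_i (s_i - mu_i c_i*) / sum_j v_j (s_j - mu_j c_j*),
evaluated at the stationary concentrations c*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .core import CommunityParams

__all__ = [
    "SimplexPoint",
    "rescale_strategy",
    "rescale_supply",
    "effective_supply",
    "in_convex_hull",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class SimplexPoint:
    """A point on the probability simplex: non-negative coordinates summing to 1."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.coordinates, dtype=float))
        if np.any(x < -_SUM_TOL):
            raise ValueError("simplex coordinates must be non-negative")
        total = float(x.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"simplex coordinates must sum to 1, got {total}")
        x = np.maximum(x, 0.0)
        x = x / x.sum()
        object.__setattr__(self, "coordinates", x)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.coordinates, dtype=dtype)

    def __len__(self) -> int:
        return self.coordinates.size


def _value_weighted(vec, resource_values, what: str) -> SimplexPoint:
    x = np.asarray(vec, dtype=float)
    v = np.asarray(resource_values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("resource values must be positive")
    if np.any(x < 0):
        raise ValueError(f"{what} entries must be non-negative")
    w = v * x
    total = w.sum()
    if total <= 0:
        raise ValueError(f"{what} must have at least one positive entry")
    return SimplexPoint(w / total)


def rescale_strategy(strategy_row, resource_values) -> SimplexPoint:
    """Value-weighted normalization alpha_hat_i = v_i alpha_i / sum_j v_j alpha_j."""
    return _value_weighted(strategy_row, resource_values, "strategy row")


def rescale_supply(supply_vector, resource_values) -> SimplexPoint:
    """Value-weighted normalization s_hat_i = v_i s_i / sum_j v_j s_j."""
    return _value_weighted(supply_vector, resource_values, "supply vector")


def effective_supply(stationary_c, params: CommunityParams) -> SimplexPoint:
    """Effective supply point under degradation,
    s_tilde_i = v_i (s_i - mu_i c_i*) / sum_j v_j (s_j - mu_j c_j*).

    Reduces to :func:`rescale_supply` when all degradation rates vanish.
    Raises if the denominator is non-positive (the formula's domain is a
    regime where net supply reaches the consumers).
    """
    c = np.asarray(stationary_c, dtype=float)
    net = params.s - params.mu * c
    # stationarity guarantees net consumption >= 0; clip rounding-level dips
    scale = float(np.max(np.abs(params.s), initial=0.0))
    net = np.where((net < 0) & (net > -1e-9 * max(scale, 1.0)), 0.0, net)
    if np.any(net < 0):
        raise ValueError(
            "negative net supply s_i - mu_i c_i*: state is outside the "
            "effective-supply formula's domain"
        )
    w = params.v * net
    total = w.sum()
    if total <= 0:
        raise ValueError("non-positive total effective supply")
    return SimplexPoint(w / total)


def in_convex_hull(
    point, vertices: Sequence, tol: float = 1e-9
) -> bool:
    """Whether ``point`` is a convex combination of ``vertices``.

    Decided by a small linear program: minimize the L1 residual of
    V^T w = x subject to w >= 0, sum w = 1; membership iff the residual is
    below ``tol``.  Robust for degenerate (collinear, duplicated) vertex sets.
    """
    x = np.asarray(point, dtype=float)
    V = np.asarray([np.asarray(v, dtype=float) for v in vertices])
    if V.ndim != 2 or V.shape[0] < 1:
        raise ValueError("need at least one vertex")
    if V.shape[1] != x.size:
        raise ValueError("point and vertices must have the same dimension")
    k, p = V.shape
    # variables: w (k), e+ (p), e- (p)
    c = np.concatenate([np.zeros(k), np.ones(2 * p)])
    A_eq = np.zeros((p + 1, k + 2 * p))
    A_eq[:p, :k] = V.T
    A_eq[:p, k : k + p] = np.eye(p)
    A_eq[:p, k + p :] = -np.eye(p)
    A_eq[p, :k] = 1.0
    b_eq = np.concatenate([x, [1.0]])
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        return False
    return float(res.fun) <= tol * max(1.0, float(np.abs(x).sum()))
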
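"""Core types and right-hand sides of the adaptive consumer-resource model.

The community model couples population densities ``n_sigma`` (cell/mL),
resource concentrations ``c_i`` (g/mL) and the metabolic-strategy matrix
``alpha_{sigma i}`` (g/(cell*h)), the per-resource maximum uptake rates:

    dn_sigma/dt = n_sigma * ( sum_i v_i alpha_{sigma i} r_i(c_i) - delta_sigma )
    dc_i/dt     = s_i - sum_sigma n_sigma alpha_{sigma i} r_i(c_i) - mu_i c_i

with Monod responses r_i(c) = c / (K_i + c).  When adaptation is enabled the
strategies themselves evolve by constrained gradient ascent of each species'
growth rate, with the total uptake budget sum_i alpha_{sigma i} capped at
E*_sigma = Q_sigma * delta_sigma:

    dalpha_{sigma i}/dt = alpha_{sigma i} * lambda_sigma *
        [ v_i r_i - Theta(phi_sigma) * (sum_j v_j r_j alpha_{sigma j})
                                      / (sum_k alpha_{sigma k}) ]

where phi_sigma = sum_i alpha_{sigma i} / E*_sigma - 1 <= 0 is the budget
constraint and Theta is Heaviside's step function with Theta(0) = 1, so the
constraint surface is invariant: on it, the row sum of the strategy derivative
vanishes identically.

Units follow a single fixed system (hours, mL, grams of resource, cells); no
conversion layer is provided.

A single-species two-resource variant describes batch diauxic growth on
galactose with ethanol excreted as a fermentation by-product (yield ``Y``) and
later respired; see :class:`DiauxicParams` and :func:`diauxic_rhs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ResourceParams",
    "SpeciesParams",
    "CommunityParams",
    "CommunityState",
    "DiauxicParams",
    "monod",
    "growth_rate",
    "constraint_phi",
    "strategy_rhs",
    "community_rhs",
    "diauxic_rhs",
    "UPTAKE_TOL",
    "THETA_WIDTH",
]

#: relative tolerance allowed on the total-uptake constraint sum_i alpha <= E*
UPTAKE_TOL = 1e-9

#: width (in units of phi, i.e. relative to the budget E*) of the continuous
#: ramp replacing the Heaviside factor just below the constraint surface.
#: The exact step function makes the surface a sliding mode on which any ODE
#: solver chatters with collapsing step sizes; ramping Theta from 0 at
#: phi = -THETA_WIDTH to 1 at phi = 0 keeps Theta(0) = 1 (so row sums are
#: conserved exactly on the surface) and leaves the phi <= -THETA_WIDTH
#: branch exact, while making the right-hand side continuous.
THETA_WIDTH = 1e-6


def _theta(phi):
    """Heaviside factor of the constraint projection, regularized by a C1
    smoothstep ramp of relative width THETA_WIDTH below the surface
    (exactly 1 for phi >= 0, exactly 0 for phi <= -THETA_WIDTH)."""
    x = np.clip(1.0 + phi / THETA_WIDTH, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


def _nonnegative(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be non-negative and finite, got {value!r}")


@dataclass(frozen=True)
class ResourceParams:
    """Static parameters of one resource.

    value : resource value v_i, cell per g of resource (1/v_i measures how
        unfavorable the resource is);
    half_saturation : Monod constant K_i, g of resource per mL;
    supply : constant supply rate s_i, g of resource/(mL*h) (may be overridden
        by a time-dependent supply protocol);
    degradation : abiotic degradation rate mu_i, 1/h.
    """

    value: float
    half_saturation: float
    supply: float = 0.0
    degradation: float = 0.0

    def __post_init__(self) -> None:
        _positive("value", self.value)
        _positive("half_saturation", self.half_saturation)
        _nonnegative("supply", self.supply)
        _nonnegative("degradation", self.degradation)


@dataclass(frozen=True)
class SpeciesParams:
    """Static parameters of one species.

    death_rate : delta_sigma, 1/h;
    ctr : characteristic timescale ratio Q_sigma = E*_sigma / delta_sigma,
        g of resource per cell;
    learning_rate : lambda_sigma, g of resource/(cell*h); 0 freezes the
        species' strategies even when the community is adaptive.
    """

    death_rate: float
    ctr: float
    learning_rate: float = 0.0

    def __post_init__(self) -> None:
        _positive("death_rate", self.death_rate)
        _positive("ctr", self.ctr)
        _nonnegative("learning_rate", self.learning_rate)

    @property
    def max_uptake(self) -> float:
        """Maximum total uptake rate E*_sigma = Q_sigma * delta_sigma."""
        return self.ctr * self.death_rate

    @classmethod
    def with_adaptation_velocity(
        cls, death_rate: float, ctr: float, d: float
    ) -> "SpeciesParams":
        """Build a species with learning rate lambda = d * delta, the single
        adaptation-velocity convention used when one timescale per species."""
        return cls(death_rate=death_rate, ctr=ctr, learning_rate=d * death_rate)


class CommunityParams:
    """All static parameters of an m-species, p-resource community."""

    def __init__(
        self,
        species: Sequence[SpeciesParams],
        resources: Sequence[ResourceParams],
        adaptive: bool = True,
    ) -> None:
        if len(species) < 1:
            raise ValueError("need at least one species")
        if len(resources) < 1:
            raise ValueError("need at least one resource")
        self.species = list(species)
        self.resources = list(resources)
        self.adaptive = bool(adaptive)
        # cached parameter arrays used by the RHS hot loop
        self.delta = np.array([sp.death_rate for sp in self.species])
        self.ctr = np.array([sp.ctr for sp in self.species])
        self.lam = np.array([sp.learning_rate for sp in self.species])
        self.e_star = self.ctr * self.delta
        self.v = np.array([rs.value for rs in self.resources])
        self.K = np.array([rs.half_saturation for rs in self.resources])
        self.s = np.array([rs.supply for rs in self.resources])
        self.mu = np.array([rs.degradation for rs in self.resources])

    @property
    def m(self) -> int:
        return len(self.species)

    @property
    def p(self) -> int:
        return len(self.resources)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CommunityParams(m={self.m}, p={self.p}, "
            f"adaptive={self.adaptive})"
        )


@dataclass
class CommunityState:
    """Instantaneous state: densities n (m,), concentrations c (p,),
    strategy matrix A (m, p)."""

    n: np.ndarray
    c: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.atleast_1d(np.asarray(self.n, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.A.shape != (self.n.size, self.c.size):
            raise ValueError(
                f"strategy matrix shape {self.A.shape} does not match "
                f"(m={self.n.size}, p={self.c.size})"
            )

    def validate(self, params: CommunityParams, tol: float = UPTAKE_TOL) -> None:
        """Check non-negativity and the per-species total-uptake constraint."""
        for name, arr in (("n", self.n), ("c", self.c), ("A", self.A)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {name}")
            if np.any(arr < -tol * max(1.0, float(np.max(np.abs(arr), initial=0.0)))):
                raise ValueError(f"negative entries in {name}")
        rowsum = self.A.sum(axis=1)
        if np.any(rowsum > params.e_star * (1.0 + tol)):
            raise ValueError(
                "total uptake exceeds E* beyond tolerance for species "
                f"{np.nonzero(rowsum > params.e_star * (1.0 + tol))[0].tolist()}"
            )

    def copy(self) -> "CommunityState":
        return CommunityState(self.n.copy(), self.c.copy(), self.A.copy())

    def pack(self) -> np.ndarray:
        return np.concatenate([self.n, self.c, self.A.ravel()])

    @classmethod
    def unpack(cls, y: np.ndarray, m: int, p: int) -> "CommunityState":
        y = np.asarray(y, dtype=float)
        return cls(y[:m].copy(), y[m : m + p].copy(), y[m + p :].reshape(m, p).copy())


def monod(c, K):
    """Monod uptake response r(c) = c / (K + c), in [0, 1).

    Strictly increasing in ``c``; raises on negative concentration or
    non-positive half-saturation constant.
    """
    c = np.asarray(c, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if np.any(K <= 0):
        raise ValueError("half-saturation constant must be positive")
    out = c / (K + c)
    return float(out) if out.ndim == 0 else out


def _monod_unchecked(c: np.ndarray, K: np.ndarray) -> np.ndarray:
    # hot path: callers guarantee clipped c >= 0, K > 0
    return c / (K + c)


def growth_rate(sigma: int, state: CommunityState, params: CommunityParams) -> float:
    """Instantaneous growth rate g_sigma = sum_i v_i alpha_{sigma i} r_i - delta_sigma."""
    if not 0 <= sigma < params.m:
        raise IndexError(f"species index {sigma} out of range for m={params.m}")
    r = _monod_unchecked(np.maximum(state.c, 0.0), params.K)
    return float(params.v @ (state.A[sigma] * r) - params.delta[sigma])


def constraint_phi(strategy_row, e_star: float) -> float:
    """Signed uptake-budget violation phi = sum_i alpha_i / E* - 1 (feasible iff <= 0)."""
    if e_star <= 0:
        raise ValueError("E* must be positive")
    return float(np.sum(strategy_row) / e_star - 1.0)


def _strategy_rhs_arrays(
    A: np.ndarray,
    vr: np.ndarray,
    lam: np.ndarray,
    e_star: np.ndarray,
) -> np.ndarray:
    """Strategy derivative matrix given precomputed v_i * r_i.

    On the constraint surface the projection term makes each row sum of the
    derivative vanish identically; all-zero rows have zero derivative (the
    weighted average is defined as 0 there).
    """
    rowsum = A.sum(axis=1)
    uptake = A @ vr  # sum_j v_j r_j alpha_{sigma j}
    safe = np.where(rowsum > 0.0, rowsum, 1.0)
    avg = np.where(rowsum > 0.0, uptake / safe, 0.0)
    phi = rowsum / e_star - 1.0
    theta = _theta(phi)
    return A * lam[:, None] * (vr[None, :] - (theta * avg)[:, None])


def strategy_rhs(state: CommunityState, params: CommunityParams) -> np.ndarray:
    """Time derivative of the strategy matrix under constrained gradient ascent."""
    c = np.maximum(state.c, 0.0)
    vr = params.v * _monod_unchecked(c, params.K)
    return _strategy_rhs_arrays(np.maximum(state.A, 0.0), vr, params.lam, params.e_star)


def community_rhs(t, state: CommunityState, params: CommunityParams, supply=None):
    """Full state derivative (dn, dc, dA) at time ``t``.

    ``supply`` may be None (use the per-resource constant supply), a vector, or
    a callable s(t) -> vector (a supply protocol).
    """
    if supply is None:
        s = params.s
    elif callable(supply):
        s = np.asarray(supply(t), dtype=float)
    else:
        s = np.asarray(supply, dtype=float)
    n = np.maximum(state.n, 0.0)
    c = np.maximum(state.c, 0.0)
    A = np.maximum(state.A, 0.0)
    r = _monod_unchecked(c, params.K)
    vr = params.v * r
    dn = n * (A @ vr - params.delta)
    dc = s - r * (n @ A) - params.mu * c
    if params.adaptive:
        dA = _strategy_rhs_arrays(A, vr, params.lam, params.e_star)
    else:
        dA = np.zeros_like(A)
    return dn, dc, dA


def make_packed_rhs(params: CommunityParams, supply):
    """Return f(t, y) operating on the packed state vector, for the solver."""
    m, p = params.m, params.p
    v, K, mu, delta = params.v, params.K, params.mu, params.delta
    lam, e_star = params.lam, params.e_star
    adaptive = params.adaptive
    constant = not callable(supply)
    s_const = params.s if supply is None else (
        None if callable(supply) else np.asarray(supply, dtype=float)
    )

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n = np.maximum(y[:m], 0.0)
        c = np.maximum(y[m : m + p], 0.0)
        A = np.maximum(y[m + p :].reshape(m, p), 0.0)
        s = s_const if constant else np.asarray(supply(t), dtype=float)
        r = c / (K + c)
        vr = v * r
        dn = n * (A @ vr - delta)
        dc = s - r * (n @ A) - mu * c
        if adaptive:
            dA = _strategy_rhs_arrays(A, vr, lam, e_star)
            return np.concatenate([dn, dc, dA.ravel()])
        out = np.zeros_like(y)
        out[:m] = dn
        out[m : m + p] = dc
        return out

    return rhs


# --------------------------------------------------------------------------
# Batch diauxic growth: one species, galactose + excreted ethanol
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DiauxicParams:
    """Parameters and initial conditions of the batch diauxic-growth model.

    Galactose is only consumed; ethanol is consumed and simultaneously
    produced at rate Y times the galactose consumption rate (Y is the
    galactose-to-ethanol yield, g/g).  The strategy pair (alpha_gal,
    alpha_eth) adapts with learning rate d*delta under the budget
    alpha_gal + alpha_eth <= Q*delta.  Batch culture: no supply, no dilution.

    Units: v_* cell/g; K_* g/mL; delta 1/h; Q, d g/cell; Y dimensionless g/g;
    n0 cell/mL; c_* g/mL; alpha_* g/(cell*h).
    """

    v_gal: float
    v_eth: float
    K_gal: float
    K_eth: float
    delta: float
    Q: float
    d: float
    Y: float
    n0: float
    c_gal0: float
    c_eth0: float
    alpha_gal0: float
    alpha_eth0: float

    def __post_init__(self) -> None:
        for name in (
            "v_gal", "v_eth", "K_gal", "K_eth", "delta", "Q", "d", "Y",
            "n0", "c_gal0", "alpha_gal0", "alpha_eth0",
        ):
            _positive(name, getattr(self, name))
        _nonnegative("c_eth0", self.c_eth0)
        if self.alpha_gal0 + self.alpha_eth0 > self.Q * self.delta * (1 + UPTAKE_TOL):
            raise ValueError(
                "initial strategies violate the uptake budget: "
                f"alpha_gal0 + alpha_eth0 = {self.alpha_gal0 + self.alpha_eth0} "
                f"> Q*delta = {self.Q * self.delta}"
            )

    @property
    def e_star(self) -> float:
        """Total uptake budget E* = Q * delta, g/(cell*h)."""
        return self.Q * self.delta

    def y0(self) -> np.ndarray:
        """Initial state vector (n, c_gal, c_eth, alpha_gal, alpha_eth)."""
        return np.array(
            [self.n0, self.c_gal0, self.c_eth0, self.alpha_gal0, self.alpha_eth0]
        )


def diauxic_rhs(t, y, params: DiauxicParams, adaptive: bool = True):
    """Derivative of (n, c_gal, c_eth, alpha_gal, alpha_eth) in batch culture.

    With ``adaptive=False`` the strategies are frozen (classical fixed-strategy
    consumer-resource dynamics); setting d -> 0 in the adaptive variant gives
    the same trajectories.
    """
    n = max(float(y[0]), 0.0)
    c_gal = max(float(y[1]), 0.0)
    c_eth = max(float(y[2]), 0.0)
    a_gal = max(float(y[3]), 0.0)
    a_eth = max(float(y[4]), 0.0)

    r_gal = c_gal / (params.K_gal + c_gal)
    r_eth = c_eth / (params.K_eth + c_eth)

    uptake = params.v_gal * a_gal * r_gal + params.v_eth * a_eth * r_eth
    dn = n * (uptake - params.delta)
    dc_gal = -n * a_gal * r_gal
    dc_eth = -n * a_eth * r_eth + params.Y * n * a_gal * r_gal

    if adaptive:
        lam = params.d * params.delta
        total = a_gal + a_eth
        phi = total / params.e_star - 1.0
        theta = float(_theta(phi))
        avg = uptake / total if total > 0.0 else 0.0
        da_gal = a_gal * lam * (params.v_gal * r_gal - theta * avg)
        da_eth = a_eth * lam * (params.v_eth * r_eth - theta * avg)
    else:
        da_gal = 0.0
        da_eth = 0.0

    return np.array([dn, dc_gal, dc_eth, da_gal, da_eth])
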
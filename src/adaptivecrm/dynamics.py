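"""Time integration of the community model.

Handles constant and piecewise-constant periodic supply protocols (the solver
is restarted at every supply switch so it never steps across a discontinuity),
records extinction events as the first downward crossing of a density
threshold (default 1 cell/mL), and detects stationarity.  Extinct species are
*not* removed from the system: only crossing times are recorded, and densities
keep evolving under the ODEs, which preserves re-invasion under variable
supply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import (
    CommunityParams,
    CommunityState,
    UPTAKE_TOL,
    make_packed_rhs,
)

__all__ = [
    "SupplyProtocol",
    "Trajectory",
    "StationaryResult",
    "IntegrationError",
    "integrate",
    "stationary_state",
    "survivors",
    "DEFAULT_EXTINCTION_THRESHOLD",
]

#: extinction threshold, cell/mL
DEFAULT_EXTINCTION_THRESHOLD = 1.0

# absolute tolerances per state block; densities and concentrations differ by
# many orders of magnitude, so each block gets its own floor
ATOL_N = 1e-6   # cell/mL
ATOL_C = 1e-12  # g/mL
ATOL_A = 1e-12  # g/(cell*h)


class IntegrationError(RuntimeError):
    """Solver failure (step-size collapse or non-finite state)."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message if t is None else f"{message} (at t={t:g} h)")
        self.t = t


@dataclass(frozen=True)
class SupplyProtocol:
    """Nutrient supply vector s(t): constant, or alternating periodically
    between ``s_in`` (for ``tau_in`` hours) and ``s_out`` (for ``tau_out``),
    starting in the ``s_in`` phase at t=0 by default."""

    mode: str  # "constant" | "periodic"
    s_constant: Optional[np.ndarray] = None
    s_in: Optional[np.ndarray] = None
    s_out: Optional[np.ndarray] = None
    tau_in: float = 0.0
    tau_out: float = 0.0
    start_phase: str = "in"

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "periodic"):
            raise ValueError(f"unknown supply mode {self.mode!r}")
        if self.mode == "constant":
            s = np.asarray(self.s_constant, dtype=float)
            if np.any(s < 0):
                raise ValueError("supply entries must be non-negative")
            object.__setattr__(self, "s_constant", s)
        else:
            if self.tau_in <= 0 or self.tau_out <= 0:
                raise ValueError("tau_in and tau_out must be positive")
            if self.start_phase not in ("in", "out"):
                raise ValueError("start_phase must be 'in' or 'out'")
            for name in ("s_in", "s_out"):
                s = np.asarray(getattr(self, name), dtype=float)
                if np.any(s < 0):
                    raise ValueError("supply entries must be non-negative")
                object.__setattr__(self, name, s)
            if self.s_in.shape != self.s_out.shape:
                raise ValueError("s_in and s_out must have the same length")

    @classmethod
    def constant(cls, s) -> "SupplyProtocol":
        return cls(mode="constant", s_constant=np.asarray(s, dtype=float))

    @classmethod
    def periodic(
        cls, s_in, s_out, tau_in: float, tau_out: float, start_phase: str = "in"
    ) -> "SupplyProtocol":
        return cls(
            mode="periodic",
            s_in=np.asarray(s_in, dtype=float),
            s_out=np.asarray(s_out, dtype=float),
            tau_in=float(tau_in),
            tau_out=float(tau_out),
            start_phase=start_phase,
        )

    @property
    def period(self) -> float:
        if self.mode != "periodic":
            raise ValueError("constant protocol has no period")
        return self.tau_in + self.tau_out

    def __call__(self, t: float) -> np.ndarray:
        if self.mode == "constant":
            return self.s_constant
        tau_first = self.tau_in if self.start_phase == "in" else self.tau_out
        phase = float(t) % self.period
        first = phase < tau_first
        if self.start_phase == "in":
            return self.s_in if first else self.s_out
        return self.s_out if first else self.s_in

    def segments(self, t0: float, t1: float) -> Iterator[tuple[float, float, np.ndarray]]:
        """Yield (ta, tb, s) pieces over [t0, t1] on which s(t) is constant."""
        if self.mode == "constant":
            yield (t0, t1, self.s_constant)
            return
        period = self.period
        tau_first = self.tau_in if self.start_phase == "in" else self.tau_out
        # switch instants: k*period and k*period + tau_first
        ta = t0
        while ta < t1 - 1e-12:
            phase = ta % period
            if phase < tau_first - 1e-12:
                tb_local = np.floor(ta / period) * period + tau_first
            else:
                tb_local = (np.floor(ta / period) + 1) * period
            tb = min(float(tb_local), t1)
            if tb <= ta + 1e-12:
                tb = t1
            yield (ta, tb, self(0.5 * (ta + tb)))
            ta = tb


@dataclass
class Trajectory:
    """Time-stamped sequence of community states plus extinction events.

    ``extinctions`` holds (species index, time of first downward crossing of
    the threshold); each species appears at most once.
    """

    times: np.ndarray
    n: np.ndarray  # (T, m)
    c: np.ndarray  # (T, p)
    A: np.ndarray  # (T, m, p)
    extinctions: list[tuple[int, float]] = field(default_factory=list)
    threshold: float = DEFAULT_EXTINCTION_THRESHOLD

    @property
    def m(self) -> int:
        return self.n.shape[1]

    @property
    def p(self) -> int:
        return self.c.shape[1]

    def state_at(self, index: int) -> CommunityState:
        return CommunityState(self.n[index].copy(), self.c[index].copy(), self.A[index].copy())

    @property
    def final_state(self) -> CommunityState:
        return self.state_at(-1)

    def survivors(self, threshold: float | None = None) -> np.ndarray:
        thr = self.threshold if threshold is None else threshold
        return survivors(self.n[-1], thr)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: time_h, variable_kind, species_index,
        resource_index, value."""
        frames = []
        T, m = self.n.shape
        p = self.c.shape[1]
        frames.append(
            pd.DataFrame(
                {
                    "time_h": np.repeat(self.times, m),
                    "variable_kind": "density",
                    "species_index": np.tile(np.arange(m), T),
                    "resource_index": -1,
                    "value": self.n.ravel(),
                }
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "time_h": np.repeat(self.times, p),
                    "variable_kind": "concentration",
                    "species_index": -1,
                    "resource_index": np.tile(np.arange(p), T),
                    "value": self.c.ravel(),
                }
            )
        )
        sp_idx = np.tile(np.repeat(np.arange(m), p), T)
        rs_idx = np.tile(np.arange(p), T * m)
        frames.append(
            pd.DataFrame(
                {
                    "time_h": np.repeat(self.times, m * p),
                    "variable_kind": "strategy",
                    "species_index": sp_idx,
                    "resource_index": rs_idx,
                    "value": self.A.ravel(),
                }
            )
        )
        return pd.concat(frames, ignore_index=True)

    def extinctions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.extinctions, columns=["species_index", "time_h"])


@dataclass
class StationaryResult:
    """Outcome of a stationarity search: the terminal state, whether the
    derivative criterion was met, the time reached and the residual."""

    state: CommunityState
    converged: bool
    t_reached: float
    residual: float


def _project_rows(A: np.ndarray, e_star: np.ndarray, tol: float = UPTAKE_TOL) -> np.ndarray:
    """Rescale strategy rows that numerically overshot the uptake budget."""
    rowsum = A.sum(axis=1)
    over = rowsum > e_star * (1.0 + tol)
    if np.any(over):
        A = A.copy()
        A[over] *= (e_star[over] / rowsum[over])[:, None]
    return A

def _sanitize(y: np.ndarray, m: int, p: int, e_star: np.ndarray) -> np.ndarray:
    """Clip rounding-level negatives to zero and project strategy rows."""
    y = y.copy()
    floors = np.concatenate(
        [np.full(m, 1e3 * ATOL_N), np.full(p, 1e6 * ATOL_C), np.full(m * p, 1e6 * ATOL_A)]
    )
    scale = np.maximum(np.abs(y), 1.0)
    bad = y < -np.maximum(floors, 1e-7 * scale)
    if np.any(bad):
        raise IntegrationError(
            f"state became significantly negative in components {np.nonzero(bad)[0].tolist()}"
        )
    y[y < 0.0] = 0.0
    A = _project_rows(y[m + p :].reshape(m, p), e_star)
    y[m + p :] = A.ravel()
    return y


def _atol_vector(m: int, p: int) -> np.ndarray:
    return np.concatenate(
        [np.full(m, ATOL_N), np.full(p, ATOL_C), np.full(m * p, ATOL_A)]
    )


def integrate(
    params: CommunityParams,
    protocol: SupplyProtocol,
    initial: CommunityState,
    t_end: float,
    *,
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
    stop_after_extinctions: int | None = None,
    t_eval: Optional[np.ndarray] = None,
    method: str = "LSODA",
    rtol: float = 1e-8,
    store_steps: bool = True,
) -> Trajectory:
    """Integrate the community ODEs over [0, t_end].

    Parameters
    ----------
    extinction_threshold : density whose first downward crossing defines a
        species' extinction time (the species keeps evolving afterwards).
    stop_after_extinctions : stop as soon as this many distinct species have
        crossed (used by the extinction-time experiments); None integrates to
        ``t_end``.
    t_eval : explicit output grid; supply-switch boundaries are always stored.
        With ``store_steps=True`` and no grid, every accepted solver step is
        stored.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if extinction_threshold <= 0:
        raise ValueError("extinction threshold must be positive")
    m, p = params.m, params.p
    initial.validate(params)
    y = _sanitize(initial.pack(), m, p, params.e_star)
    atol = _atol_vector(m, p)

    times: list[np.ndarray] = [np.array([0.0])]
    states: list[np.ndarray] = [y[None, :].copy()]
    recorded: dict[int, float] = {}
    want_stop = stop_after_extinctions is not None
    if want_stop and stop_after_extinctions < 1:
        raise ValueError("stop_after_extinctions must be >= 1")

    if t_eval is not None:
        t_eval = np.asarray(t_eval, dtype=float)

    def make_event(idx: int):
        def ev(t, yy, idx=idx):
            return yy[idx] - extinction_threshold

        ev.direction = -1
        ev.terminal = want_stop
        return ev

    for ta, tb, svec in protocol.segments(0.0, t_end):
        rhs = make_packed_rhs(params, svec)
        t_cur = ta
        while t_cur < tb - 1e-12:
            active = [i for i in range(m) if i not in recorded]
            events = [make_event(i) for i in active]
            if t_eval is not None:
                mask = (t_eval > t_cur + 1e-12) & (t_eval < tb - 1e-12)
                seg_eval = np.concatenate([t_eval[mask], [tb]])
            elif store_steps:
                seg_eval = None
            else:
                seg_eval = np.array([tb])
            sol = solve_ivp(
                rhs,
                (t_cur, tb),
                y,
                method=method,
                rtol=rtol,
                atol=atol,
                t_eval=seg_eval,
                events=events if events else None,
            )
            if sol.status == -1:
                raise IntegrationError(f"solver failed: {sol.message}", t=sol.t[-1] if sol.t.size else t_cur)
            if not np.all(np.isfinite(sol.y)):
                raise IntegrationError("non-finite state encountered", t=sol.t[-1])

            # record first crossings seen in this chunk
            new_events: list[tuple[float, int]] = []
            if events:
                for k_ev, i in enumerate(active):
                    te = sol.t_events[k_ev]
                    if te.size:
                        new_events.append((float(te[0]), i))
            new_events.sort()

            # sol.t/sol.y may be bare empty lists when a terminal event fires
            # before the first requested output point
            st = np.asarray(sol.t, dtype=float)
            if st.size:
                keep = st > t_cur + 1e-12
                times.append(st[keep])
                states.append(np.asarray(sol.y).T[keep])

            if want_stop and sol.status == 1:
                # terminal event: record the earliest crossing, restart there
                te, idx = new_events[0]
                recorded[idx] = te
                k_ev = active.index(idx)
                y = _sanitize(sol.y_events[k_ev][0].copy(), m, p, params.e_star)
                times.append(np.array([te]))
                states.append(y[None, :].copy())
                if len(recorded) >= stop_after_extinctions:
                    return _build_trajectory(
                        times, states, m, p, recorded, extinction_threshold, params
                    )
                t_cur = te
            else:
                for te, i in new_events:
                    recorded.setdefault(i, te)
                y = _sanitize(sol.y[:, -1].copy(), m, p, params.e_star)
                t_cur = tb
    return _build_trajectory(times, states, m, p, recorded, extinction_threshold, params)


def _build_trajectory(times, states, m, p, recorded, threshold, params) -> Trajectory:
    t = np.concatenate(times)
    ys = np.vstack(states)
    order = np.argsort(t, kind="stable")
    t = t[order]
    ys = ys[order]
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    t = t[keep]
    ys = ys[keep]
    ys = np.maximum(ys, 0.0)
    A = ys[:, m + p :].reshape(-1, m, p)
    # project stored strategy rows onto the budget surface where overshooting
    rowsum = A.sum(axis=2)
    over = rowsum > params.e_star[None, :] * (1.0 + UPTAKE_TOL)
    if np.any(over):
        factor = np.where(over, params.e_star[None, :] / np.where(rowsum > 0, rowsum, 1.0), 1.0)
        A = A * factor[:, :, None]
    events = sorted(((i, te) for i, te in recorded.items()), key=lambda x: x[1])
    return Trajectory(
        times=t,
        n=ys[:, :m],
        c=ys[:, m : m + p],
        A=A,
        extinctions=[(int(i), float(te)) for i, te in events],
        threshold=threshold,
    )


def stationary_state(
    params: CommunityParams,
    protocol: SupplyProtocol,
    initial: CommunityState,
    *,
    tol: float = 1e-9,
    t_max: float = 1e7,
    chunk0: float = 50.0,
    method: str = "LSODA",
    rtol: float = 1e-8,
    blocks: str = "all",
) -> StationaryResult:
    """Integrate under constant supply until the state derivative is negligible.

    The criterion is max_i |f_i| / (|y_i| + floor_i) < tol, with per-block
    floors matching the solver's absolute tolerances; units of the left side
    are 1/h.  ``blocks='biotic'`` restricts the criterion to densities and
    strategies — appropriate when an unconsumed, non-degrading resource
    accumulates without bound while the community itself is stationary.
    Returns the terminal state and a convergence flag (never raises on
    non-convergence).
    """
    if protocol.mode != "constant":
        raise ValueError("stationarity is undefined under periodic forcing")
    if blocks not in ("all", "biotic"):
        raise ValueError("blocks must be 'all' or 'biotic'")
    m, p = params.m, params.p
    initial.validate(params)
    rhs = make_packed_rhs(params, protocol.s_constant)
    atol = _atol_vector(m, p)
    floors = np.concatenate(
        [np.full(m, ATOL_N), np.full(p, ATOL_C), np.full(m * p, ATOL_A)]
    )
    mask = np.ones(m + p + m * p, dtype=bool)
    if blocks == "biotic":
        mask[m : m + p] = False
    y = _sanitize(initial.pack(), m, p, params.e_star)

    def residual(yy: np.ndarray) -> float:
        f = rhs(0.0, yy)
        return float(np.max((np.abs(f) / (np.abs(yy) + floors))[mask]))

    res = residual(y)
    t_cur = 0.0
    if res < tol:
        return StationaryResult(CommunityState.unpack(y, m, p), True, 0.0, res)
    chunk = chunk0
    while t_cur < t_max:
        tb = min(t_cur + chunk, t_max)
        sol = solve_ivp(
            rhs, (t_cur, tb), y, method=method, rtol=rtol, atol=atol,
            t_eval=np.array([tb]),
        )
        if sol.status != 0:
            raise IntegrationError(f"solver failed: {sol.message}", t=t_cur)
        y = _sanitize(sol.y[:, -1], m, p, params.e_star)
        t_cur = tb
        res = residual(y)
        if res < tol:
            return StationaryResult(CommunityState.unpack(y, m, p), True, t_cur, res)
        chunk *= 2.0
    return StationaryResult(CommunityState.unpack(y, m, p), False, t_cur, res)


def survivors(densities, threshold: float = DEFAULT_EXTINCTION_THRESHOLD) -> np.ndarray:
    """Indices of species with density strictly above the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(densities, CommunityState):
        densities = densities.n
    densities = np.asarray(densities, dtype=float)
    return np.nonzero(densities > threshold)[0]
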
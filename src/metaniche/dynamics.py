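"""Forward integration of the full tumor-resource system.

The system is mildly stiff: carrying capacities span 1e5-1e7 cells while
the intravasation constant is ~1e-6 and the resource relaxes on a
1000-day timescale, so a stiff-capable implicit solver (LSODA) is the
default.  Populations are continuous; a clone that falls below a
pseudo-extinction threshold while declining is set to zero, which makes
competitive exclusion ("cheaters become extinct") realizable in finite
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import capacities, competition_matrix, rhs_cells
from .params import ModelParams
from .types import CANONICAL_ORDER, CellType, TumorState

__all__ = ["Trajectory", "IntegrationError", "integrate",
           "detect_fast_equilibration"]


class IntegrationError(RuntimeError):
    """Solver failure; carries the last good state for diagnostics."""

    def __init__(self, message: str, last_state: TumorState | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class Trajectory:
    """Sampled solution of the full system.

    ``times`` is strictly increasing (days); ``n`` has shape (T, 4) in
    canonical clone order; ``events`` is a list of (time, label) markers
    such as pseudo-extinctions or mutant arrivals.
    """

    times: np.ndarray
    n: np.ndarray
    R: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)

    @property
    def N(self) -> np.ndarray:
        return self.n.sum(axis=1)

    def state_at(self, i: int) -> TumorState:
        return TumorState(n=self.n[i].copy(), R=float(self.R[i]),
                          t=float(self.times[i]))

    @property
    def final_state(self) -> TumorState:
        return self.state_at(-1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.n, columns=[ct.label for ct in CANONICAL_ORDER])
        df.insert(0, "t", self.times)
        df["R"] = self.R
        df["N"] = self.N
        return df


def _solve_chunk(params: ModelParams, y0: np.ndarray, t0: float, t1: float,
                 t_eval: np.ndarray, C: np.ndarray,
                 rtol: float, atol: float, method: str):
    def f(t, y):
        n = np.clip(y[:4], 0.0, None)
        dn = rhs_cells(n, max(y[4], 0.0), params, C=C)
        dR = params.g * (n[2] + n[3]) - params.l * max(y[4], 0.0)
        return np.append(dn, dR)

    sol = solve_ivp(f, (t0, t1), y0, method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        last = TumorState(np.clip(y0[:4], 0, None), max(y0[4], 0.0), t0)
        raise IntegrationError(
            f"solver failed on [{t0}, {t1}]: {sol.message}", last_state=last)
    return sol


def integrate(params: ModelParams, initial: TumorState, horizon: float,
              sample_interval: float = 1.0, rtol: float = 1e-8,
              atol: float = 1e-6, method: str = "LSODA",
              extinction_threshold: float = 1.0) -> Trajectory:
    """Integrate the full system for ``horizon`` days from ``initial``.

    Samples at ``sample_interval`` (default daily).  At each sample a clone
    below ``extinction_threshold`` cells with negative per-capita growth is
    zeroed and an extinction event recorded; integration restarts from the
    modified state.  Negative solver undershoots are clipped to zero.
    Set ``extinction_threshold=0`` to disable zeroing.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    C = competition_matrix(params)
    t0 = initial.t
    t_end = t0 + horizon
    grid = np.arange(t0, t_end + 0.5 * sample_interval, sample_interval)
    if grid[-1] < t_end:
        grid = np.append(grid, t_end)

    times = [t0]
    ns = [initial.n.copy()]
    Rs = [initial.R]
    events: list[tuple[float, str]] = []
    y = np.append(initial.n, initial.R)
    t = t0
    while t < t_end - 1e-9:
        t_eval = grid[grid > t + 1e-9]
        sol = _solve_chunk(params, y, t, t_end, t_eval, C, rtol, atol, method)
        restart = False
        for j in range(sol.y.shape[1]):
            n_j = np.clip(sol.y[:4, j], 0.0, None)
            R_j = max(float(sol.y[4, j]), 0.0)
            t_j = float(sol.t[j])
            zeroed = []
            if extinction_threshold > 0:
                dn = rhs_cells(n_j, R_j, params, C=C)
                for ct in CANONICAL_ORDER:
                    i = ct.index
                    if 0 < n_j[i] < extinction_threshold and dn[i] < 0:
                        n_j[i] = 0.0
                        zeroed.append(ct)
            times.append(t_j)
            ns.append(n_j)
            Rs.append(R_j)
            if zeroed:
                for ct in zeroed:
                    events.append((t_j, f"extinct:{ct.label}"))
                y = np.append(n_j, R_j)
                t = t_j
                restart = True
                break
        if not restart:
            t = float(sol.t[-1])
            y = sol.y[:, -1].copy()
            y[:4] = np.clip(y[:4], 0.0, None)
    return Trajectory(np.array(times), np.vstack(ns), np.array(Rs), events)


def detect_fast_equilibration(traj: Trajectory, window: float = 50.0,
                              tol: float = 1e-4,
                              params: ModelParams | None = None,
                              capacity_normalized: bool = False,
                              floor: float = 1.0) -> float | None:
    """Earliest time after which the cell populations have settled.

    The per-day relative change of each clone (ignoring clones below
    ``floor`` cells) must stay below ``tol`` from the detected time to the
    end of the trajectory, with at least ``window`` days of evidence.  With
    ``capacity_normalized=True`` (requires ``params``) the settling of the
    capacity-scaled coordinates n_i / K_i(R) is measured instead: the fast
    subsystem then counts as equilibrated once it rides the slowly moving
    quasi-equilibrium manifold even though the raw populations keep growing
    with R.  Returns None if the trajectory never settles.
    """
    if len(traj.times) < 3:
        return None
    if capacity_normalized:
        if params is None:
            raise ValueError("capacity_normalized requires params")
        K = np.vstack([capacities(R, params) for R in traj.R])
        values = traj.n / K
    else:
        values = traj.n
    dt = np.diff(traj.times)
    rate = np.abs(np.diff(values, axis=0)) / dt[:, None]
    # relative change per day; clones below the floor are treated as settled
    active = traj.n[:-1] >= floor
    rel = np.where(active, rate / np.maximum(np.abs(values[:-1]), 1e-300), 0.0)
    ok = np.all(rel < tol, axis=1)
    # earliest index from which ok holds through the end
    settled_from = None
    for i in range(len(ok) - 1, -1, -1):
        if ok[i]:
            settled_from = i
        else:
            break
    if settled_from is None:
        return None
    t_settle = float(traj.times[settled_from])
    if traj.times[-1] - t_settle < window:
        return None
    return t_settle
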
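"""Quasi-equilibria of the fast cell subsystem at frozen resource level.

On timescales where R barely moves, the cell populations settle onto fixed
points of the frozen-R Lotka-Volterra subsystem.  A primary tumor without
pre-metastatic producers admits three non-trivial quasi-equilibria: cheaters
only, local producers only, and cheater/local-producer coexistence.  All
three have closed forms; larger resident sets are handled by multi-start
root finding.  The induced slow flow of R on the quasi-equilibrium manifold
is dR/dt = g (n10* + n11*) - l R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import optimize

from .model import capacities, competition_matrix, rhs_cells
from .params import ModelParams
from .types import CANONICAL_ORDER, CellType

__all__ = [
    "QuasiEquilibrium",
    "DegenerateGeometryError",
    "NoFeasibleEquilibriumError",
    "RootFindingError",
    "single_type_equilibrium",
    "coexistence_equilibrium",
    "find_quasi_equilibria",
    "slow_resource_flow",
    "resource_closed_form",
]

#: Relative residual tolerance for verifying fixed points.
RESIDUAL_RTOL = 1e-8
#: Coexistence feasibility: components must exceed this fraction of K.
FEASIBILITY_RTOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Coexistence isoclines are parallel (c01 * c10 = 1 at alpha = 0)."""


class NoFeasibleEquilibriumError(ValueError):
    """No nonnegative quasi-equilibrium exists for the requested resident set."""


class RootFindingError(RuntimeError):
    """Multi-start root finding failed to converge; carries diagnostics."""


@dataclass
class QuasiEquilibrium:
    """A fixed point of the frozen-R cell subsystem.

    ``n_star`` is the full length-4 abundance vector (entries outside
    ``resident_set`` are exactly zero); ``residual`` is the max-norm of the
    cell derivatives at the fixed point, relative to r_max * K_max.
    """

    resident_set: frozenset[CellType]
    n_star: np.ndarray
    R: float
    method: str = "closed_form"
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.resident_set = frozenset(self.resident_set)
        self.n_star = np.asarray(self.n_star, dtype=float)

    @property
    def N(self) -> float:
        return float(self.n_star.sum())

    def abundance(self, ct: CellType) -> float:
        return float(self.n_star[ct.index])

    def to_record(self) -> dict:
        rec = {"resident_set": "+".join(sorted(ct.label for ct in self.resident_set)),
               "R": self.R, "method": self.method, "residual": self.residual}
        for ct in CANONICAL_ORDER:
            rec[ct.label] = self.abundance(ct)
        return rec


def _residual(n: np.ndarray, R: float, params: ModelParams) -> float:
    scale = float(np.max(params.growth_rates) * np.max(capacities(R, params)))
    return float(np.max(np.abs(rhs_cells(n, R, params))) / scale)


def single_type_equilibrium(ct: CellType, R: float,
                            params: ModelParams) -> QuasiEquilibrium:
    """Closed-form fixed point with a single resident clone.

    With only clone ``ct`` present, N = n and the logistic-with-dispersal
    balance r (1 - n/K) = alpha n / K gives n* = K(R) r / (r + alpha).
    """
    if R < 0:
        raise ValueError("R must be nonnegative")
    r = params.growth_rate(ct)
    K = params.k + params.beta(ct) * R
    alpha = params.alpha
    if params.shared_dispersal_beta is not None:
        # balance r (1 - n/K) = alpha n / K_shared
        K_shared = params.k + params.shared_dispersal_beta * R
        n_star = r / (r / K + alpha / K_shared)
    else:
        n_star = K * r / (r + alpha)
    n = np.zeros(4)
    n[ct.index] = n_star
    return QuasiEquilibrium(frozenset({ct}), n, R, method="closed_form",
                            residual=_residual(n, R, params))


def _pair_equilibrium(a: CellType, b: CellType, R: float,
                      params: ModelParams) -> QuasiEquilibrium | None:
    """Closed-form two-clone fixed point (general resident pair).

    Solves the linear system obtained from r_i (1 - (C n)_i / K_i) = alpha N / K_i
    for the two resident abundances; returns None when either component is
    not strictly positive (no feasible two-clone equilibrium).
    """
    C = competition_matrix(params)
    K = capacities(R, params)
    if params.shared_dispersal_beta is not None:
        Kd = np.full(4, params.k + params.shared_dispersal_beta * R)
    else:
        Kd = K
    r = params.growth_rates
    ia, ib = a.index, b.index
    # r_i K_i - r_i (C n)_i = alpha N K_i / Kd_i, N = n_a + n_b
    ga, gb = params.alpha * K[ia] / Kd[ia], params.alpha * K[ib] / Kd[ib]
    A = np.array([
        [r[ia] * C[ia, ia] + ga, r[ia] * C[ia, ib] + ga],
        [r[ib] * C[ib, ia] + gb, r[ib] * C[ib, ib] + gb],
    ])
    rhs_vec = np.array([r[ia] * K[ia], r[ib] * K[ib]])
    det = float(np.linalg.det(A))
    scale = float(np.abs(A).max() ** 2)
    if abs(det) <= 1e-9 * scale:
        raise DegenerateGeometryError(
            f"coexistence system for {{{a.label}, {b.label}}} is singular "
            f"(c01*c10 = 1); isoclines are parallel"
        )
    sol = np.linalg.solve(A, rhs_vec)
    if np.any(sol <= FEASIBILITY_RTOL * np.max(K)):
        return None
    n = np.zeros(4)
    n[ia], n[ib] = sol
    return QuasiEquilibrium(frozenset({a, b}), n, R, method="closed_form",
                            residual=_residual(n, R, params))


def coexistence_equilibrium(R: float, params: ModelParams) -> QuasiEquilibrium | None:
    """Cheater/local-producer coexistence fixed point, or None if infeasible.

    With alpha = 0 this is the textbook two-species Lotka-Volterra interior
    point n00 + c01 n10 = K0, c10 n00 + n10 = K1 with c01 = C[(0,0),(1,0)]
    and c10 = C[(1,0),(0,0)]; the alpha > 0 correction is kept exactly.
    """
    return _pair_equilibrium(CellType.CHEATER, CellType.LOCAL, R, params)


def find_quasi_equilibria(R: float, params: ModelParams,
                          resident_set) -> list[QuasiEquilibrium]:
    """All nonnegative fixed points restricted to ``resident_set``.

    One- and two-clone sets use the closed forms; larger sets use
    multi-start Powell-hybrid root finding with starts at the vertices and
    centroid of [0, K_max]^m, duplicates merged at 1e-6 relative tolerance.
    """
    residents = sorted(set(resident_set), key=lambda ct: ct.index)
    if not residents:
        raise ValueError("resident_set must be nonempty")
    if len(residents) == 1:
        return [single_type_equilibrium(residents[0], R, params)]
    if len(residents) == 2:
        eq = _pair_equilibrium(residents[0], residents[1], R, params)
        return [eq] if eq is not None else []

    C = competition_matrix(params)
    K = capacities(R, params)
    idx = [ct.index for ct in residents]
    Kmax = float(np.max(K))
    m = len(idx)

    def restricted(x: np.ndarray) -> np.ndarray:
        n = np.zeros(4)
        n[idx] = x
        return rhs_cells(n, R, params, C=C)[idx]

    starts = [np.array(v, dtype=float) * Kmax for v in product((0.0, 1.0), repeat=m)]
    starts.append(np.full(m, 0.5 * Kmax))
    found: list[np.ndarray] = []
    failures: list[str] = []
    for x0 in starts:
        sol = optimize.root(restricted, x0, method="hybr",
                            options={"xtol": 1e-12})
        if not sol.success:
            failures.append(f"start {x0}: {sol.message}")
            continue
        x = sol.x
        if np.any(x < -1e-9 * Kmax):
            continue
        x = np.clip(x, 0.0, None)
        n = np.zeros(4)
        n[idx] = x
        if _residual(n, R, params) > RESIDUAL_RTOL:
            continue
        if any(np.allclose(x, y, rtol=1e-6, atol=1e-6 * Kmax) for y in found):
            continue
        found.append(x)
    if not found and failures:
        raise RootFindingError(
            f"root finding failed for resident set "
            f"{{{', '.join(ct.label for ct in residents)}}} at R={R}: "
            + "; ".join(failures[:3])
        )
    out = []
    for x in sorted(found, key=lambda v: -float(np.sum(v))):
        n = np.zeros(4)
        n[idx] = x
        support = frozenset(ct for ct in residents
                            if n[ct.index] > FEASIBILITY_RTOL * Kmax)
        out.append(QuasiEquilibrium(support, n, R, method="root_find",
                                    residual=_residual(n, R, params)))
    return out


def slow_resource_flow(R: float, params: ModelParams, resident_set) -> float:
    """dR/dt on the quasi-equilibrium manifold for the given resident set.

    Substitutes the quasi-equilibrium abundances n*(R) into the resource
    equation: g (n10* + n11*) - l R.
    """
    residents = set(resident_set)
    eqs = find_quasi_equilibria(R, params, residents)
    eqs = [eq for eq in eqs if eq.resident_set == frozenset(residents)]
    if not eqs:
        raise NoFeasibleEquilibriumError(
            f"no feasible quasi-equilibrium for resident set "
            f"{{{', '.join(sorted(ct.label for ct in residents))}}} at R={R}"
        )
    eq = eqs[0]
    producers = eq.abundance(CellType.LOCAL) + eq.abundance(CellType.GLOBAL)
    return float(params.g * producers - params.l * R)


def resource_closed_form(t, R0: float, P: float, params: ModelParams):
    """Exact solution of dR/dt = g P - l R with constant producer total P.

    R(t) = gP/l + (R0 - gP/l) exp(-l t); for l = 0 the limit R0 + gP t.
    Used as an integration-accuracy oracle.
    """
    t = np.asarray(t, dtype=float)
    if params.l == 0:
        out = R0 + params.g * P * t
    else:
        Rinf = params.g * P / params.l
        out = Rinf + (R0 - Rinf) * np.exp(-params.l * t)
    return out if out.ndim else float(out)
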
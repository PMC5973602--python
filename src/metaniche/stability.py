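"""Stability of quasi-equilibria and invasion analysis for rare mutants.

Whether a rare mutant clone can establish in a resident tumor is decided by
the sign of its per-capita growth rate at the resident quasi-equilibrium
(the invasion eigenvalue of the boundary fixed point).  This module
computes that rate numerically, evaluates the equivalent exact analytic
inequalities, evaluates the large-R / small-alpha limit conditions of the
summary grid, and cross-checks the three routes against each other over
random parameter draws.

Notation for the limit conditions (resident community x question):

====================  =========================  ==============  ==============
cell                  structure I                structure II    structure III
====================  =========================  ==============  ==============
producer stability    theta > beta0/beta1        same            same
producer invade 01    omega < beta0/beta1        beta0 > beta1   theta < beta0/beta1
producer invade 11    mu < 1                     never           never
cheater stability     never                      never           never
cheater invade 01     phi < 1                    phi < 1         r01 > r10
cheater invade 11     psi < 1                    psi < 1         phi < 1
coexistence inv 01    b1(pt-w)+b0(wt-p-t^2+1)>0  see code        never
coexistence inv 11    b0(mt-s)+b1(st-m-t^2+1)>0  (s-t)(t*b1-b0)  (p-t)(b1*t-b0)
====================  =========================  ==============  ==============

Several "never" cells are knife-edge: the invader's growth rate tends to
exactly zero as alpha -> 0, so numeric sign tests there are meaningless and
the consistency machinery excludes them via the boundary margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import (QuasiEquilibrium, coexistence_equilibrium,
                         single_type_equilibrium)
from .model import capacities, competition_matrix, dispersal_rates, rhs_cells
from .params import ModelParams
from .types import CANONICAL_ORDER, CellType

__all__ = [
    "InvasionVerdict",
    "NotApplicable",
    "invasion_growth_rate",
    "jacobian_fast",
    "is_stable",
    "StabilityReport",
    "analytic_invasion_exact",
    "analytic_invasion_margin",
    "invasion_verdict",
    "analytic_condition_limit",
    "limit_condition_margin",
    "consistency_report",
    "sample_params",
    "GRID_CELLS",
]

#: Default nondimensional margin below which a draw counts as a boundary case.
BOUNDARY_MARGIN = 1e-3

#: Resident-community labels used by the summary grid.
RESIDENTS = ("cheater_only", "producer_only", "coexistence")
QUESTIONS = ("stability", "invade_01", "invade_11")

#: The (resident, question) cells of the summary grid, excluding coexistence
#: stability (analytically intractable; decided numerically only).
GRID_CELLS = tuple((res, q) for res in RESIDENTS for q in QUESTIONS
                    if not (res == "coexistence" and q == "stability"))

_RESIDENT_SETS = {
    "cheater_only": frozenset({CellType.CHEATER}),
    "producer_only": frozenset({CellType.LOCAL}),
    "coexistence": frozenset({CellType.CHEATER, CellType.LOCAL}),
}
_INVADERS = {"invade_01": CellType.SECONDARY, "invade_11": CellType.GLOBAL}


class NotApplicable(Exception):
    """The requested analytic condition is not defined for this case."""


@dataclass
class InvasionVerdict:
    """Cross-checked invasion assessment for one (invader, resident) pair."""

    invader: CellType
    resident_eq: QuasiEquilibrium
    lambda_num: float
    analytic_exact: bool | None
    analytic_limit: bool | None
    agree: bool
    boundary: bool


# ---------------------------------------------------------------------------
# Numeric route
# ---------------------------------------------------------------------------

def invasion_growth_rate(invader: CellType, resident_eq: QuasiEquilibrium,
                         params: ModelParams) -> float:
    """Per-capita growth rate of a rare invader at the resident equilibrium.

    lambda = r_inv (1 - (C n*)_inv / K_inv(R)) - m_inv(N*, R), evaluated
    with the invader at zero abundance.  This equals the invader's diagonal
    Jacobian entry at the boundary equilibrium, since the invader's row and
    column decouple at n_inv = 0.
    """
    if invader in resident_eq.resident_set:
        raise ValueError(f"invader {invader.label} is part of the resident set")
    C = competition_matrix(params)
    K = capacities(resident_eq.R, params)
    m = dispersal_rates(resident_eq.N, resident_eq.R, params)
    i = invader.index
    r = params.growth_rates[i]
    return float(r * (1.0 - (C[i] @ resident_eq.n_star) / K[i]) - m[i])


def jacobian_fast(n: np.ndarray, R: float, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of the frozen-R cell subsystem at (n, R).

    f_i = r_i n_i (1 - (C n)_i / K_i) - alpha N n_i / Kd_i gives
    J_ij = -r_i n_i C_ij / K_i - alpha n_i / Kd_i
           + delta_ij [ r_i (1 - (C n)_i / K_i) - alpha N / Kd_i ].
    """
    n = np.asarray(n, dtype=float)
    C = competition_matrix(params)
    K = capacities(R, params)
    if params.shared_dispersal_beta is not None:
        Kd = np.full(4, params.k + params.shared_dispersal_beta * R)
    else:
        Kd = K
    r = params.growth_rates
    N = float(n.sum())
    J = -(r * n / K)[:, None] * C - (params.alpha * n / Kd)[:, None] * np.ones((1, 4))
    J[np.diag_indices(4)] += r * (1.0 - (C @ n) / K) - params.alpha * N / Kd
    return J


@dataclass
class StabilityReport:
    stable: bool
    internal_eigenvalues: np.ndarray
    external_growth_rates: dict[CellType, float]


def is_stable(resident_eq: QuasiEquilibrium, params: ModelParams,
              tol: float = 0.0) -> StabilityReport:
    """Linear stability of a quasi-equilibrium, internal and external.

    Internal: all eigenvalues of the Jacobian restricted to resident
    coordinates have negative real part.  External: the invasion growth
    rates of absent clones among {cheater, local producer} are negative,
    i.e. the equilibrium also resists the tumor's initial composition.
    Pre-metastatic clones (0,1)/(1,1) are assessed separately as invaders.
    """
    J = jacobian_fast(resident_eq.n_star, resident_eq.R, params)
    idx = sorted(ct.index for ct in resident_eq.resident_set)
    eigs = np.linalg.eigvals(J[np.ix_(idx, idx)])
    internal_ok = bool(np.all(eigs.real < tol))
    external = {}
    for ct in (CellType.CHEATER, CellType.LOCAL):
        if ct not in resident_eq.resident_set:
            external[ct] = invasion_growth_rate(ct, resident_eq, params)
    external_ok = all(lam < tol for lam in external.values())
    return StabilityReport(internal_ok and external_ok, eigs, external)


# ---------------------------------------------------------------------------
# Exact analytic route
# ---------------------------------------------------------------------------

def analytic_invasion_margin(invader: CellType, resident_eq: QuasiEquilibrium,
                             params: ModelParams) -> float:
    """Signed, nondimensional slack of the exact invasion inequality.

    The inequality sum_res n_res (C[inv,res] + alpha/r_inv) < K_inv(R),
    rearranged as (K_inv - lhs)/K_inv; positive means the invader can
    invade.  Algebraically identical to lambda / r_inv when the dispersal
    denominator uses the focal clone's carrying capacity.
    """
    if resident_eq.resident_set - {CellType.CHEATER, CellType.LOCAL}:
        raise NotApplicable(
            "exact invasion conditions cover residents among {(0,0), (1,0)} only")
    if invader not in (CellType.SECONDARY, CellType.GLOBAL):
        raise NotApplicable("exact invasion conditions cover (0,1)/(1,1) invaders")
    C = competition_matrix(params)
    K = capacities(resident_eq.R, params)
    i = invader.index
    r = params.growth_rates[i]
    lhs = sum(resident_eq.abundance(ct) * (C[i, ct.index] + params.alpha / r)
              for ct in resident_eq.resident_set)
    return float((K[i] - lhs) / K[i])


def analytic_invasion_exact(invader: CellType, resident_eq: QuasiEquilibrium,
                            params: ModelParams) -> bool:
    """Exact invasion inequality at the resident abundances (True = invadable)."""
    return analytic_invasion_margin(invader, resident_eq, params) > 0


def invasion_verdict(invader: CellType, resident_eq: QuasiEquilibrium,
                     params: ModelParams,
                     margin: float = BOUNDARY_MARGIN) -> InvasionVerdict:
    """Cross-checked verdict: numeric rate vs exact (and, where tabulated,
    limit) analytic conditions, with margin-aware agreement."""
    lam = invasion_growth_rate(invader, resident_eq, params)
    num_margin = abs(lam) / params.growth_rates[invader.index]
    try:
        exact = analytic_invasion_exact(invader, resident_eq, params)
        amargin = abs(analytic_invasion_margin(invader, resident_eq, params))
    except NotApplicable:
        exact, amargin = None, math.inf
    resident = {frozenset({CellType.CHEATER}): "cheater_only",
                frozenset({CellType.LOCAL}): "producer_only",
                frozenset({CellType.CHEATER, CellType.LOCAL}): "coexistence",
                }.get(resident_eq.resident_set)
    question = "invade_01" if invader is CellType.SECONDARY else "invade_11"
    limit = None
    if resident is not None and invader in _INVADERS.values():
        try:
            limit = analytic_condition_limit(resident, question, params)
        except NotApplicable:
            pass
    boundary = num_margin < margin or amargin < margin
    agree = boundary or exact is None or (lam > 0) == exact
    return InvasionVerdict(invader, resident_eq, lam, exact, limit,
                           agree, boundary)


# ---------------------------------------------------------------------------
# Limit-form route (large R for producer-containing residents, R ~ 0 for the
# cheater-only resident, alpha ~ 0 throughout)
# ---------------------------------------------------------------------------

def limit_condition_margin(resident: str, question: str,
                           params: ModelParams) -> float:
    """Signed margin of the summary-grid limit condition (positive = True).

    Constant-verdict cells return +/- inf so they never register as
    boundary cases on the analytic side; the numeric-lambda margin still
    applies to them.
    """
    s = params.structure
    b0, b1 = params.beta0, params.beta1
    th, ph, ps = params.theta, params.phi, params.psi
    om, mu = params.omega, params.mu
    ratio = b0 / b1
    bscale = b0 + b1
    if (resident, question) not in GRID_CELLS:
        raise NotApplicable(f"no limit condition for ({resident}, {question})")

    if resident == "producer_only":
        if question == "stability":
            return th - ratio
        if question == "invade_01":
            return {"I": ratio - om, "II": b0 / b1 - 1.0, "III": ratio - th}[s]
        # invade_11
        return {"I": 1.0 - mu, "II": -math.inf, "III": -math.inf}[s]

    if resident == "cheater_only":
        if question == "stability":
            return -math.inf
        if question == "invade_01":
            if s == "III":
                return (params.r01 - params.r10) / params.r00
            return 1.0 - ph
        # invade_11
        if s == "III":
            return 1.0 - ph
        return 1.0 - ps

    # coexistence
    if question == "invade_01":
        if s == "I":
            return (b1 * (ph * th - om) + b0 * (om * th - ph - th ** 2 + 1)) / bscale
        if s == "II":
            return (ph + th * (th - 1) - 1) / (ph * th - 1) - b1 / b0
        return -math.inf
    # invade_11
    if s == "I":
        return (b0 * (mu * th - ps) + b1 * (ps * th - mu - th ** 2 + 1)) / bscale
    if s == "II":
        return (ps - th) * (th * b1 - b0) / bscale
    return (ph - th) * (b1 * th - b0) / bscale


def analytic_condition_limit(resident: str, question: str,
                             params: ModelParams) -> bool:
    """Summary-grid verdict in the applicable limit regime (True/False)."""
    return limit_condition_margin(resident, question, params) > 0


# ---------------------------------------------------------------------------
# Consistency harness
# ---------------------------------------------------------------------------

def sample_params(rng: np.random.Generator, structure: str,
                  alpha_max: float = 1e-5) -> ModelParams:
    """Random parameter set respecting the invariants, for cross-checks.

    Growth rates keep the producer-cost ordering; competition coefficients
    stay away from their bounds by 0.05; specificity beta1/beta0 spans both
    sides of 1.
    """
    r00 = rng.uniform(0.04, 0.1)
    r01 = r00 * rng.uniform(0.4, 0.95)
    r10 = r00 * rng.uniform(0.4, 0.95)
    r11 = min(r01, r10) * rng.uniform(0.2, 0.9)
    return ModelParams(
        r00=r00, r01=r01, r10=r10, r11=r11,
        k=1e5,
        beta0=rng.uniform(0.5, 2.0), beta1=rng.uniform(0.5, 2.0),
        alpha=rng.uniform(0.0, alpha_max),
        g=0.004, l=0.001,
        structure=structure,
        theta=rng.uniform(0.05, 0.95), phi=rng.uniform(0.05, 0.95),
        psi=rng.uniform(0.05, 0.95), omega=rng.uniform(0.05, 1.0),
        mu=rng.uniform(0.05, 1.0), nu=rng.uniform(0.05, 1.0),
    )


def _resident_equilibrium(resident: str, R: float,
                          params: ModelParams) -> QuasiEquilibrium | None:
    if resident == "cheater_only":
        return single_type_equilibrium(CellType.CHEATER, R, params)
    if resident == "producer_only":
        return single_type_equilibrium(CellType.LOCAL, R, params)
    return coexistence_equilibrium(R, params)


def _numeric_stability_margin(eq: QuasiEquilibrium, params: ModelParams):
    """(stable?, nondimensional distance to the stability boundary)."""
    rep = is_stable(eq, params)
    rmax = float(np.max(params.growth_rates))
    margins = [abs(float(np.max(rep.internal_eigenvalues.real))) / rmax]
    margins += [abs(lam) / params.growth_rates[ct.index]
                for ct, lam in rep.external_growth_rates.items()]
    return rep.stable, min(margins)


def consistency_report(n_draws: int, rng_seed: int, regime: str = "limit",
                       structures=("I", "II", "III"),
                       R_values=(0.0,), margin: float = BOUNDARY_MARGIN,
                       questions: tuple[str, ...] = QUESTIONS) -> pd.DataFrame:
    """Analytic-vs-numeric verdicts over random parameter draws.

    regime="exact": samples alpha in [0, 1e-5] and evaluates, at each R in
    ``R_values``, the sign of the numeric invasion rate against the exact
    inequality for each feasible resident community and invader.

    regime="limit": alpha = 0, R = 1e6 k for producer-containing residents
    and R = 0 for the cheater-only resident; compares the summary-grid
    limit verdicts against the numeric verdicts (including stability).

    Draws whose numeric or analytic margin is within ``margin`` of zero are
    flagged ``boundary`` and should be excluded from agreement statistics;
    cells where every draw is boundary are knife-edge by construction.
    """
    if regime not in ("exact", "limit"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for structure in structures:
        for draw in range(n_draws):
            params = sample_params(
                rng, structure, alpha_max=0.0 if regime == "limit" else 1e-5)
            if regime == "limit":
                R_for = {"cheater_only": (0.0,),
                         "producer_only": (1e6 * params.k,),
                         "coexistence": (1e6 * params.k,)}
            else:
                R_for = {res: tuple(R_values) for res in RESIDENTS}
            for resident in RESIDENTS:
                for R in R_for[resident]:
                    eq = _resident_equilibrium(resident, R, params)
                    if eq is None:
                        continue
                    for question in questions:
                        if (resident, question) not in GRID_CELLS:
                            continue
                        if question == "stability":
                            if regime == "exact":
                                continue  # no exact closed form asserted
                            verdict, num_margin = _numeric_stability_margin(
                                eq, params)
                            lam = math.nan
                            exact = None
                        else:
                            invader = _INVADERS[question]
                            lam = invasion_growth_rate(invader, eq, params)
                            num_margin = abs(lam) / params.growth_rates[
                                invader.index]
                            verdict = lam > 0
                            exact = analytic_invasion_exact(invader, eq, params)
                        if regime == "limit":
                            limit = analytic_condition_limit(
                                resident, question, params)
                            lm = limit_condition_margin(
                                resident, question, params)
                            analytic = limit
                            amargin = abs(lm) if math.isfinite(lm) else math.inf
                        else:
                            limit = None
                            analytic = exact
                            amargin = abs(analytic_invasion_margin(
                                _INVADERS[question], eq, params))
                        boundary = (num_margin < margin) or (amargin < margin)
                        rows.append({
                            "structure": structure, "resident": resident,
                            "question": question, "draw": draw, "R": R,
                            "lambda": lam, "numeric": verdict,
                            "exact": exact, "limit": limit,
                            "boundary": boundary,
                            "agree": (verdict == analytic) or boundary,
                        })
    return pd.DataFrame(rows)


def agreement_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Per-cell agreement fractions over non-boundary draws.

    ``n_effective`` counts non-boundary draws; a cell with zero effective
    draws is knife-edge (the verdict margin vanishes identically there) and
    gets agreement NaN.
    """
    rows = []
    for (structure, resident, question), grp in report.groupby(
            ["structure", "resident", "question"], sort=False):
        eff = grp[~grp["boundary"]]
        rows.append({
            "structure": structure, "resident": resident, "question": question,
            "n_total": len(grp), "n_effective": len(eff),
            "agreement": float(eff["agree"].mean()) if len(eff) else math.nan,
        })
    return pd.DataFrame(rows)


__all__.append("agreement_summary")
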
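"""Competition structures, carrying capacities, dispersal, and the governing ODEs.

The tumor is a four-clone competitive Lotka-Volterra system coupled to one
slow resource variable R:

    dn_i/dt = r_i n_i (1 - (C n)_i / K_i(R)) - m_i(N, R) n_i
    dR/dt   = g (n10 + n11) - l R

with clone-specific carrying capacity K_i(R) = k + beta_x R (beta0 for
clones that do not construct the local niche, beta1 for those that do),
density-dependent intravasation m_i = alpha N / K_i, and a 4x4 competition
matrix C whose entry C[i, j] is the competitive effect of clone j on clone
i (diagonal fixed at 1).
"""

from __future__ import annotations

import numpy as np

from .params import ConfigurationError, ModelParams
from .types import CANONICAL_ORDER, CellType, TumorState

__all__ = [
    "competition_matrix",
    "carrying_capacity",
    "capacities",
    "dispersal_rate",
    "dispersal_rates",
    "rhs",
    "rhs_cells",
]


def competition_matrix(params: ModelParams) -> np.ndarray:
    """The 4x4 interclonal competition matrix for the chosen structure.

    Orientation: ``C[i, j]`` is the effect OF clone j ON clone i, rows and
    columns in canonical order [(0,0), (0,1), (1,0), (1,1)].

    Structure I is the general symmetric case; structure II is structure I
    with all producer-producer couplings at the intraclonal magnitude 1
    (omega = nu = mu = 1); structure III groups clones into two niches by
    the local-production flag (non-producers {(0,0),(0,1)} vs producers
    {(1,0),(1,1)}), with intra-niche competition 1, effect of producers on
    non-producers theta, and effect of non-producers on producers phi.
    """
    th, ph, ps = params.theta, params.phi, params.psi
    om, mu, nu = params.omega, params.mu, params.nu
    if params.structure == "I":
        return np.array([
            [1.0, ph, th, ps],
            [ph, 1.0, om, nu],
            [th, om, 1.0, mu],
            [ps, nu, mu, 1.0],
        ])
    if params.structure == "II":
        return np.array([
            [1.0, ph, th, ps],
            [ph, 1.0, 1.0, 1.0],
            [th, 1.0, 1.0, 1.0],
            [ps, 1.0, 1.0, 1.0],
        ])
    if params.structure == "III":
        C = np.empty((4, 4))
        for i, ci in enumerate(CANONICAL_ORDER):
            for j, cj in enumerate(CANONICAL_ORDER):
                if ci.x == cj.x:
                    C[i, j] = 1.0
                elif ci.x == 0:  # non-producer experiencing a producer
                    C[i, j] = th
                else:            # producer experiencing a non-producer
                    C[i, j] = ph
        return C
    raise ConfigurationError(f"unknown competition structure {params.structure!r}")


def carrying_capacity(ct: CellType, R: float, params: ModelParams) -> float:
    """k + beta0*R for non-producers of the local niche, k + beta1*R for producers."""
    if R < 0:
        raise ValueError(f"resource level must be nonnegative, got {R}")
    return params.k + params.beta(ct) * R


def capacities(R: float, params: ModelParams) -> np.ndarray:
    """Length-4 vector of clone carrying capacities at resource level R."""
    return params.k + params.betas * R


def _dispersal_denominators(R: float, params: ModelParams) -> np.ndarray:
    if params.shared_dispersal_beta is not None:
        return np.full(4, params.k + params.shared_dispersal_beta * R)
    return capacities(R, params)


def dispersal_rate(ct: CellType, N: float, R: float, params: ModelParams) -> float:
    """Per-capita intravasation rate m(N, R) = alpha N / (k + beta_x R).

    The denominator is the focal clone's carrying capacity unless
    ``params.shared_dispersal_beta`` selects the shared-beta variant.
    """
    if N < 0 or R < 0:
        raise ValueError("N and R must be nonnegative")
    return params.alpha * N / float(_dispersal_denominators(R, params)[ct.index])


def dispersal_rates(N: float, R: float, params: ModelParams) -> np.ndarray:
    """Vector of per-capita intravasation rates in canonical order."""
    return params.alpha * N / _dispersal_denominators(R, params)


def rhs_cells(n: np.ndarray, R: float, params: ModelParams,
              C: np.ndarray | None = None) -> np.ndarray:
    """Time derivatives of the four clone populations at frozen resource R.

    This is the "fast" subsystem used for quasi-equilibrium and stability
    analysis.  ``C`` may be passed to avoid rebuilding the competition
    matrix in inner loops.
    """
    n = np.asarray(n, dtype=float)
    if C is None:
        C = competition_matrix(params)
    K = capacities(R, params)
    m = dispersal_rates(float(n.sum()), R, params)
    return params.growth_rates * n * (1.0 - (C @ n) / K) - m * n


def rhs(state: TumorState | tuple, params: ModelParams,
        C: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Full system right-hand side: (dn/dt, dR/dt).

    Accepts a :class:`TumorState` or a ``(n, R)`` pair.  Populations must be
    nonnegative; a clone at exactly zero has derivative exactly zero.
    """
    if isinstance(state, TumorState):
        n, R = state.n, state.R
    else:
        n, R = state
        n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError(f"populations must be nonnegative, got {n}")
    if R < 0:
        raise ValueError(f"resource level must be nonnegative, got {R}")
    dn = rhs_cells(n, R, params, C=C)
    dR = params.g * (n[CellType.LOCAL.index] + n[CellType.GLOBAL.index]) - params.l * R
    return dn, float(dR)
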
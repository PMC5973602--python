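"""Core domain types: cell clones and tumor state.

Four clonal phenotypes are indexed by a pair of binary flags (x, y):
``x`` marks participation in local niche construction (production of the
shared resource R that raises the primary tumor's carrying capacity) and
``y`` marks participation in pre-metastatic niche construction (secretion
of factors that prepare a distant site, at a growth cost but with no local
benefit).  The canonical ordering used for every vector, matrix and file
column is ``[(0,0), (0,1), (1,0), (1,1)]``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class CellType(enum.Enum):
    """One of the four clones, indexed (x, y).

    - ``CHEATER``   (0,0): no niche construction, highest growth rate.
    - ``SECONDARY`` (0,1): pre-metastatic niche producer only; acts as a
      cheater from the primary tumor's point of view.
    - ``LOCAL``     (1,0): local (primary) niche producer.
    - ``GLOBAL``    (1,1): produces in both niches, pays a double cost.
    """

    CHEATER = (0, 0)
    SECONDARY = (0, 1)
    LOCAL = (1, 0)
    GLOBAL = (1, 1)

    @property
    def x(self) -> int:
        """Local niche-construction flag."""
        return self.value[0]

    @property
    def y(self) -> int:
        """Pre-metastatic niche-construction flag."""
        return self.value[1]

    @property
    def index(self) -> int:
        """Position in the canonical ordering [(0,0),(0,1),(1,0),(1,1)]."""
        return 2 * self.x + self.y

    @property
    def label(self) -> str:
        return f"n{self.x}{self.y}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CellType({self.x},{self.y})"


#: Canonical clone ordering for all vectors and matrices.
CANONICAL_ORDER: tuple[CellType, ...] = (
    CellType.CHEATER,
    CellType.SECONDARY,
    CellType.LOCAL,
    CellType.GLOBAL,
)

#: Clones that construct the pre-metastatic niche (y = 1); the existence of
#: an established lineage of either is the model's necessary condition for
#: metastasis.
METASTATIC_TYPES: tuple[CellType, ...] = (CellType.SECONDARY, CellType.GLOBAL)


@dataclass
class TumorState:
    """Populations of the four clones plus the resource level at one time.

    Parameters
    ----------
    n : array-like of length 4
        Population sizes (cells, continuous) in canonical order.
    R : float
        Local resource level (resource units), nonnegative.
    t : float
        Time in days.
    """

    n: np.ndarray
    R: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.shape != (4,):
            raise ValueError(f"n must have length 4, got shape {self.n.shape}")
        if np.any(self.n < 0):
            raise ValueError(f"populations must be nonnegative, got {self.n}")
        if self.R < 0:
            raise ValueError(f"resource level must be nonnegative, got {self.R}")

    @property
    def N(self) -> float:
        """Total number of tumor cells."""
        return float(self.n.sum())

    def copy(self) -> "TumorState":
        return TumorState(n=self.n.copy(), R=self.R, t=self.t)
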
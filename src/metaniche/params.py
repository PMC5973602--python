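"""Model and mutation-process parameters, validation and the named registry."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .types import CANONICAL_ORDER, CellType

__all__ = [
    "ModelParams",
    "MutationParams",
    "ConfigurationError",
    "CostOrderingWarning",
    "REGISTRY",
    "published_defaults",
]

#: Valid competition-structure labels.
STRUCTURES = ("I", "II", "III")


class ConfigurationError(ValueError):
    """Raised for invalid parameter values or unknown configuration keys."""


class CostOrderingWarning(UserWarning):
    """Producers are expected to pay a growth-rate cost (r00 > r10, r01; r11
    smallest); a violated ordering is legal (e.g. therapy scenarios) but
    flagged."""


@dataclass
class ModelParams:
    """All rates and coefficients defining one model instance.

    Units: growth rates and decay rates are per day, ``k`` is cells,
    ``beta0``/``beta1`` are cells gained per resource unit, ``g`` is resource
    units per producer cell per day, ``alpha`` scales the density-dependent
    intravasation rate.  Interclonal competition coefficients are
    dimensionless, at most 1 (intraclonal competition is the unit).
    """

    r00: float = 0.07
    r01: float = 0.045
    r10: float = 0.05
    r11: float = 0.02
    k: float = 1e5
    beta0: float = 1.0
    beta1: float = 1.2
    alpha: float = 1e-6
    g: float = 0.004
    l: float = 0.001
    structure: str = "I"
    theta: float = 0.9
    phi: float = 0.9
    psi: float = 0.9
    omega: float = 0.9
    mu: float = 0.9
    nu: float = 0.9
    #: If set, every clone's dispersal denominator uses k + shared_dispersal_beta * R
    #: instead of the focal clone's own carrying capacity (sensitivity variant).
    shared_dispersal_beta: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.structure not in STRUCTURES:
            raise ConfigurationError(
                f"unknown competition structure {self.structure!r}; "
                f"expected one of {STRUCTURES}"
            )
        for name in ("r00", "r01", "r10", "r11", "k", "g", "l"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {v}")
        for name in ("beta0", "beta1", "alpha"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be nonnegative, got {v}")
        for name in ("theta", "phi", "psi"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(
                    f"{name} must lie strictly in (0, 1), got {v}"
                )
        for name in ("omega", "mu", "nu"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        # Producers pay a growth-rate cost; warn (not error) when violated.
        if not (self.r00 > self.r10 and self.r00 > self.r01
                and self.r11 < min(self.r10, self.r01)):
            warnings.warn(
                "growth-rate cost ordering violated (expected r00 > r10, "
                "r00 > r01 and r11 < min(r10, r01)); proceeding anyway",
                CostOrderingWarning,
                stacklevel=2,
            )

    # -- canonical-order vectors -------------------------------------------

    @property
    def growth_rates(self) -> np.ndarray:
        """Per-capita growth rates in canonical order."""
        return np.array([self.r00, self.r01, self.r10, self.r11])

    @property
    def betas(self) -> np.ndarray:
        """Resource-benefit coefficient per clone: beta0 for x=0, beta1 for x=1."""
        return np.array([self.beta0, self.beta0, self.beta1, self.beta1])

    def growth_rate(self, ct: CellType) -> float:
        return float(self.growth_rates[ct.index])

    def beta(self, ct: CellType) -> float:
        return self.beta1 if ct.x == 1 else self.beta0

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


#: Allowed phenotype transitions with their per-transition conditional
#: probabilities given a mutation.  Single-flag flips away from the common
#: ancestral states are "major" class (default 1/500 each); the two-flag
#: jumps are "double" class (default 1/1000 each).  Order is fixed; the
#: mutation kernel draws in this order.
DEFAULT_TRANSITIONS: tuple[tuple[CellType, CellType, str], ...] = (
    (CellType.CHEATER, CellType.SECONDARY, "major"),
    (CellType.CHEATER, CellType.LOCAL, "major"),
    (CellType.CHEATER, CellType.GLOBAL, "double"),
    (CellType.SECONDARY, CellType.LOCAL, "double"),
    (CellType.LOCAL, CellType.CHEATER, "major"),
    (CellType.LOCAL, CellType.GLOBAL, "major"),
)


@dataclass
class MutationParams:
    """Stochastic mutation-process parameters.

    ``rate_per_cell_per_day`` is the probability that a cell mutates (in any
    gene) on a given day; conditional on a mutation, each allowed one-step
    phenotype transition occurs with probability ``p_major`` and each
    two-step transition with ``p_double``.  The residual probability mass is
    phenotypically silent and not tracked.
    """

    rate_per_cell_per_day: float = 2e-7
    p_major: float = 1.0 / 500
    p_double: float = 1.0 / 1000
    transitions: tuple[tuple[CellType, CellType, str], ...] = DEFAULT_TRANSITIONS

    def __post_init__(self) -> None:
        if not (0 <= self.rate_per_cell_per_day <= 1):
            raise ConfigurationError(
                f"mutation rate must lie in [0, 1], got {self.rate_per_cell_per_day}"
            )
        for p in (self.p_major, self.p_double):
            if not (0 <= p <= 1):
                raise ConfigurationError(f"class probability out of [0, 1]: {p}")
        for src in CANONICAL_ORDER:
            total = sum(self.transition_prob(s, t)
                        for s, t, _ in self.transitions if s is src)
            if total > 1 + 1e-12:
                raise ConfigurationError(
                    f"conditional transition probabilities from {src.label} "
                    f"sum to {total} > 1"
                )

    def transition_prob(self, source: CellType, target: CellType) -> float:
        for s, t, cls in self.transitions:
            if s is source and t is target:
                return self.p_major if cls == "major" else self.p_double
        return 0.0

    def to_dict(self) -> dict:
        return {
            "rate_per_cell_per_day": self.rate_per_cell_per_day,
            "p_major": self.p_major,
            "p_double": self.p_double,
        }


# ---------------------------------------------------------------------------
# Named parameter registry
# ---------------------------------------------------------------------------

#: The published default parameter set used for the single-tumor and
#: 200-tumor ensemble experiments.  Only theta and phi are stated there; the
#: remaining interclonal coefficients (psi, omega, nu, mu) are set to the
#: same 0.9 as a documented assumption.
REGISTRY: dict[str, dict] = {
    "published_defaults": dict(
        r00=0.07, r10=0.05, r01=0.045, r11=0.02,
        k=1e5, beta0=1.0, beta1=1.2,
        theta=0.9, phi=0.9, psi=0.9, omega=0.9, mu=0.9, nu=0.9,
        g=0.004, l=0.001, alpha=1e-6,
        structure="I",
    ),
}

#: Default initial condition for a nascent tumor: cheaters only, a small
#: founding population and a trace of resource (the published runs start
#: "with cheaters only and a small amount of resource"; exact values are an
#: assumption recorded here).
DEFAULT_INITIAL = dict(n00=1e3, n01=0.0, n10=0.0, n11=0.0, R=1.0)


def published_defaults(**overrides) -> ModelParams:
    """The registry's published default parameter set, optionally overridden."""
    values = dict(REGISTRY["published_defaults"])
    values.update(overrides)
    return ModelParams(**values)
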
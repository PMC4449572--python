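"""Age standardization and the order-2 Legendre polynomial basis.

Every stage of the pipeline (simulation, mixed-model fit, GWAS back-solving,
bootstrap) evaluates animal trajectories on the same basis: age in days is
mapped linearly onto [-1, 1] and the first three Legendre polynomials are
evaluated at the standardized age.  Normalized (Kirkpatrick-style)
polynomials phi_k = sqrt((2k+1)/2) * P_k are the default, the convention of
the random-regression literature; raw polynomials are available and all
variance-ratio outputs are invariant to the choice.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgeStandardizer", "legendre_row", "legendre_matrix", "ORDER"]

#: polynomial order of the basis (quadratic); the basis is a 3-vector
ORDER = 2

# sqrt((2k+1)/2) for k = 0, 1, 2
_NORM = np.sqrt((2.0 * np.arange(ORDER + 1) + 1.0) / 2.0)


@dataclass(frozen=True)
class AgeStandardizer:
    """Linear map from age in days onto the standardized interval [-1, 1].

    ``age_min`` maps to -1 and ``age_max`` to +1.  The fitted model stores
    its standardizer so downstream GWAS stages reuse identical scaling.
    """

    age_min: float
    age_max: float

    def __post_init__(self) -> None:
        if not self.age_max > self.age_min:
            raise ValueError(
                f"age_max ({self.age_max}) must exceed age_min ({self.age_min})"
            )

    def transform(self, age) -> np.ndarray | float:
        """Standardize ``age`` (days) to t in [-1, 1]; out-of-range ages raise."""
        age = np.asarray(age, dtype=float)
        if np.any(age < self.age_min) or np.any(age > self.age_max):
            raise ValueError(
                f"age outside [{self.age_min}, {self.age_max}]"
            )
        t = 2.0 * (age - self.age_min) / (self.age_max - self.age_min) - 1.0
        return t if t.ndim else float(t)

    def inverse(self, t) -> np.ndarray | float:
        """Map standardized t back to age in days."""
        t = np.asarray(t, dtype=float)
        age = (t + 1.0) * (self.age_max - self.age_min) / 2.0 + self.age_min
        return age if age.ndim else float(age)

    @classmethod
    def from_ages(cls, ages) -> "AgeStandardizer":
        """Standardizer spanning the observed age range of ``ages``."""
        ages = np.asarray(ages, dtype=float)
        return cls(float(ages.min()), float(ages.max()))


def legendre_row(t: float, normalized: bool = True) -> np.ndarray:
    """Evaluate the order-2 Legendre basis at a single standardized age.

    Raw polynomials are P0 = 1, P1 = t, P2 = (3 t^2 - 1) / 2; with
    ``normalized`` each is scaled by sqrt((2k+1)/2).
    """
    return legendre_matrix(np.asarray([t]), normalized=normalized)[0]


def legendre_matrix(t, normalized: bool = True) -> np.ndarray:
    """Evaluate the basis at an array of standardized ages; rows are phi(t)."""
    t = np.asarray(t, dtype=float)
    if np.any(np.abs(t) > 1.0 + 1e-12):
        raise ValueError("standardized age outside [-1, 1]")
    phi = np.empty(t.shape + (ORDER + 1,))
    phi[..., 0] = 1.0
    phi[..., 1] = t
    phi[..., 2] = 0.5 * (3.0 * t * t - 1.0)
    if normalized:
        phi = phi * _NORM
    return phi
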
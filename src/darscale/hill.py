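"""Hill-number alpha diversity.

The Hill number of order ``q`` is the effective number of species

.. math::

    {}^qD = \\Bigl(\\sum_{i=1}^{S} p_i^q\\Bigr)^{1/(1-q)},

with the ``q -> 1`` limit ``exp(-sum p_i ln p_i)`` (the exponential of
Shannon entropy).  Special orders recover the classic indices: ``q=0`` is
richness, ``q=1`` exp(Shannon), ``q=2`` the reciprocal of the Simpson
concentration.  ``q`` weights relative abundances: higher orders discount
rare taxa.  All logarithms are natural.

Inputs may be counts or relative abundances; vectors are normalised
internally over their positive entries, so the result is scale invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_Q_GRID: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)

__all__ = [
    "DEFAULT_Q_GRID",
    "DiversityProfile",
    "EmptyCommunityError",
    "diversity_profile",
    "hill_number",
]


class EmptyCommunityError(ValueError):
    """Raised when a community has no positive abundance."""


def _validate(abundances) -> np.ndarray:
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    if not np.any(x > 0):
        raise EmptyCommunityError("community has no positive abundance")
    return x


def hill_number(abundances: Sequence[float], q: float) -> float:
    """Hill number ``^qD`` of a single community.

    Parameters
    ----------
    abundances
        Non-negative counts or relative abundances; at least one entry
        must be positive.  Zeros are excluded from the sum.
    q
        Diversity order, ``q >= 0``.

    Returns
    -------
    float
        Effective number of species, between 1 and the number of
        positive entries.
    """
    x = _validate(abundances)
    if q < 0:
        raise ValueError("diversity order q must be non-negative")
    p = x[x > 0]
    if q == 0:
        return float(p.size)
    p = p / p.sum()
    p = p[p > 0]  # subnormal entries can underflow to 0 on normalization
    if q == 1:
        # closed-form limit: exponential of Shannon entropy
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_rows(matrix: np.ndarray, q: float) -> np.ndarray:
    """Row-wise Hill numbers of a 2-D array (each row one community).

    Vectorised equivalent of calling :func:`hill_number` on every row;
    rows must each contain at least one positive entry.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D array")
    if np.any(m < 0):
        raise ValueError("abundances must be non-negative")
    totals = m.sum(axis=1)
    if np.any(totals <= 0):
        raise EmptyCommunityError("a row has no positive abundance")
    if q == 0:
        return np.count_nonzero(m > 0, axis=1).astype(float)
    p = m / totals[:, None]
    if q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        return np.exp(-plogp.sum(axis=1))
    return np.where(p > 0, p, 0.0).__pow__(q).sum(axis=1) ** (1.0 / (1.0 - q))


@dataclass(frozen=True)
class DiversityProfile:
    """Hill numbers of one community over a grid of diversity orders."""

    q_grid: tuple[float, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.q_grid) != len(self.values):
            raise ValueError("q_grid and values must have equal length")


def diversity_profile(
    abundances: Sequence[float], q_grid: Sequence[float] = DEFAULT_Q_GRID
) -> DiversityProfile:
    """Evaluate :func:`hill_number` at each order of ``q_grid``, in order."""
    qs = tuple(float(q) for q in q_grid)
    values = np.array([hill_number(abundances, q) for q in qs])
    return DiversityProfile(q_grid=qs, values=values)
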
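"""Diversity-accrual curves and diversity-area relationship (DAR) models.

The DAR generalises the species-area relationship by replacing richness
with Hill numbers of arbitrary order q.  Two models are fit to an accrual
curve ``^qD(A)``, where the "area" A counts accumulated sampling units
(individual microbiome samples, or body sites):

* power law (PL):                     ``D = c * A**z``
* power law, exponential cutoff (PLEC): ``D = c * A**z * exp(d*A)``

Both are estimated as log-linear ordinary least squares,

    ln D = ln c + z ln A           (PL)
    ln D = ln c + z ln A + d A     (PLEC)

Derived parameters:

* ``z``      — diversity scaling rate (slope in log-log space);
* ``g``      — pairwise diversity overlap, ``g = 2 - 2**z``;
* ``A_max``  — area at the PLEC maximum, ``-z/d`` (requires d < 0 < z);
* ``D_max``  — maximal accrual diversity ``c * A_max**z * exp(-z)``, a
  proxy for the "potential" (regional) diversity;
* ``RIP``    — ratio of individual to population diversity,
  ``100 * c / D_max`` in percent (``c`` is the diversity of the first
  accumulated unit).

A fit is *successful* when the regression is estimable (enough distinct
areas, non-constant ln D) and its F-test p-value is below 0.05.  A flat
curve — e.g. phylum richness when every unit has the same number of
phyla — is reported as a failed fit, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .hill import hill_rows
from .io_tables import AbundanceTable

#: p-value threshold of the fit-success rule.
SUCCESS_ALPHA = 0.05

_FLAT_TOL = 1e-12

__all__ = [
    "AccrualCurve",
    "InsufficientDataError",
    "PLFit",
    "PLECFit",
    "UndefinedMaximumError",
    "accrual_curve",
    "fit_pl",
    "fit_plec",
    "mad_from_plec",
    "pdo_from_z",
    "pool_samples",
    "rip",
]


class InsufficientDataError(ValueError):
    """Raised when a curve has too few points to fit."""


class UndefinedMaximumError(ValueError):
    """Raised when the PLEC curve has no finite maximum (d >= 0 or z <= 0)."""


@dataclass(frozen=True)
class AccrualCurve:
    """Ordered (A, ^qD) pairs from pooling accumulated sampling units."""

    areas: np.ndarray
    diversities: np.ndarray
    q: float

    def __post_init__(self) -> None:
        a = np.asarray(self.areas, dtype=float)
        d = np.asarray(self.diversities, dtype=float)
        if a.shape != d.shape or a.ndim != 1:
            raise ValueError("areas and diversities must be equal-length vectors")
        if a.size and (a[0] != 1 or np.any(np.diff(a) <= 0)):
            raise ValueError("areas must increase strictly from 1")
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "diversities", d)

    def __len__(self) -> int:
        return self.areas.size


@dataclass(frozen=True)
class PLFit:
    """Result of the log-linear power-law fit ln D = ln c + z ln A."""

    z: float
    ln_c: float
    R: float
    p_value: float
    success: bool
    n_points: int

    @property
    def c(self) -> float:
        return math.exp(self.ln_c)


@dataclass(frozen=True)
class PLECFit:
    """Result of the fit ln D = ln c + z ln A + d A.

    ``A_max``/``D_max`` are NaN when the curve has no finite maximum
    (``d >= 0`` or ``z <= 0``); the fit itself may still be successful.
    """

    z: float
    ln_c: float
    d: float
    R: float
    p_value: float
    success: bool
    n_points: int
    A_max: float
    D_max: float

    @property
    def c(self) -> float:
        return math.exp(self.ln_c)


# ---------------------------------------------------------------- pooling


def pool_samples(
    table: AbundanceTable, sample_subset: Sequence[str]
) -> np.ndarray:
    """Element-wise sum of the selected sample rows (a pooled community)."""
    ids = list(sample_subset)
    if not ids:
        raise ValueError("sample subset must be non-empty")
    unknown = set(ids) - set(table.data.index)
    if unknown:
        raise LookupError(f"unknown sample ids: {sorted(unknown)[:5]}")
    return table.data.loc[ids].to_numpy(dtype=float).sum(axis=0)


def accrual_curve(
    table: AbundanceTable, order: Sequence[str], q: float
) -> AccrualCurve:
    """Diversity of the pooled community after 1..n accumulated samples.

    ``order`` fixes the accumulation order; element A of the curve is the
    Hill number of order ``q`` of the pool of the first A samples.
    """
    ids = list(order)
    if not ids:
        raise ValueError("accumulation order must be non-empty")
    rows = table.data.loc[ids].to_numpy(dtype=float)
    return accrual_curve_from_matrix(rows, q)


def accrual_curve_from_matrix(rows: np.ndarray, q: float) -> AccrualCurve:
    """Accrual curve from pre-extracted sample rows (accumulation order = row order)."""
    pooled = np.cumsum(np.asarray(rows, dtype=float), axis=0)
    div = hill_rows(pooled, q)
    return AccrualCurve(
        areas=np.arange(1, rows.shape[0] + 1, dtype=float),
        diversities=div,
        q=float(q),
    )


# ---------------------------------------------------------------- fitting


def _check_curve(curve: AccrualCurve, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    if len(curve) < min_points:
        raise InsufficientDataError(
            f"need at least {min_points} points, got {len(curve)}"
        )
    if np.any(curve.diversities <= 0):
        raise ValueError("all diversities must be positive to fit in log space")
    return np.log(curve.areas), np.log(curve.diversities)


def _is_flat(ln_d: np.ndarray) -> bool:
    scale = max(1.0, float(np.abs(ln_d).max()))
    return float(np.ptp(ln_d)) <= _FLAT_TOL * scale


def fit_pl(curve: AccrualCurve) -> PLFit:
    """Fit the PL model by OLS of ln D on ln A.

    ``R`` is the Pearson correlation between observed and fitted ln D and
    ``p_value`` the regression F-test (for one regressor, the slope test).
    A constant curve (zero variance in ln D) is returned with
    ``success=False`` and ``z=0`` — the degenerate no-accrual case.
    """
    ln_a, ln_d = _check_curve(curve, 3)
    if _is_flat(ln_d):
        return PLFit(
            z=0.0,
            ln_c=float(ln_d.mean()),
            R=float("nan"),
            p_value=float("nan"),
            success=False,
            n_points=len(curve),
        )
    res = stats.linregress(ln_a, ln_d)
    fitted = res.intercept + res.slope * ln_a
    r_of = float(np.corrcoef(ln_d, fitted)[0, 1])
    p = float(res.pvalue)
    return PLFit(
        z=float(res.slope),
        ln_c=float(res.intercept),
        R=r_of,
        p_value=p,
        success=bool(np.isfinite(p) and p < SUCCESS_ALPHA),
        n_points=len(curve),
    )


def fit_plec(curve: AccrualCurve) -> PLECFit:
    """Fit the PLEC model by OLS of ln D on (ln A, A).

    ``A_max = -z/d`` and ``D_max = c * A_max**z * exp(-z)`` are computed
    only when ``d < 0`` and ``z > 0``; otherwise both are NaN while the
    fit itself is still reported.
    """
    ln_a, ln_d = _check_curve(curve, 4)
    X = np.column_stack([np.ones_like(ln_a), ln_a, curve.areas])
    failed = PLECFit(
        z=0.0,
        ln_c=float(ln_d.mean()),
        d=0.0,
        R=float("nan"),
        p_value=float("nan"),
        success=False,
        n_points=len(curve),
        A_max=float("nan"),
        D_max=float("nan"),
    )
    if _is_flat(ln_d) or np.linalg.matrix_rank(X) < 3:
        return failed
    res = sm.OLS(ln_d, X).fit()
    ln_c, z, d = (float(v) for v in res.params)
    p = float(res.f_pvalue)
    fitted = np.asarray(res.fittedvalues)
    with np.errstate(invalid="ignore"):
        r_of = float(np.corrcoef(ln_d, fitted)[0, 1])
    if d < 0 and z > 0:
        a_max = -z / d
        d_max = math.exp(ln_c) * a_max**z * math.exp(-z)
    else:
        a_max = d_max = float("nan")
    return PLECFit(
        z=z,
        ln_c=ln_c,
        d=d,
        R=r_of,
        p_value=p,
        success=bool(np.isfinite(p) and p < SUCCESS_ALPHA),
        n_points=len(curve),
        A_max=a_max,
        D_max=d_max,
    )


# ------------------------------------------------- derived parameters


def pdo_from_z(z: float) -> float:
    """Pairwise diversity overlap ``g = 2 - 2**z``.

    ``z=0`` gives total overlap (g=1); ``z=1`` gives no overlap (g=0).
    """
    return 2.0 - 2.0 ** float(z)


def mad_from_plec(fit: PLECFit) -> tuple[float, float]:
    """Maximal accrual diversity of a successful PLEC fit.

    Returns ``(A_max, D_max)`` with ``A_max = -z/d`` the number of units
    needed to reach the maximum and ``D_max = c * A_max**z * exp(-z)``
    the PLEC curve evaluated there.
    """
    if fit.d >= 0 or fit.z <= 0:
        raise UndefinedMaximumError(
            "PLEC curve has no finite maximum (requires d < 0 and z > 0)"
        )
    a_max = -fit.z / fit.d
    d_max = fit.c * a_max**fit.z * math.exp(-fit.z)
    return a_max, d_max


def rip(c: float, d_max: float) -> float:
    """Ratio of individual to population diversity, ``100 * c / D_max`` (%)."""
    if not (c > 0 and d_max > 0):
        raise ValueError("c and D_max must both be positive")
    return 100.0 * c / d_max


def plec_value(c: float, z: float, d: float, a):
    """Evaluate the PLEC model ``c * A**z * exp(d*A)`` at area(s) ``a``."""
    a = np.asarray(a, dtype=float)
    out = c * a**z * np.exp(d * a)
    return float(out) if out.ndim == 0 else out
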
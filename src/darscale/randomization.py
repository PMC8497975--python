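"""Permutation tests for pairwise differences in DAR parameters.

The observed statistic of a group of samples is its resampling-averaged
DAR parameter: over ``inner_reps`` random accumulation orders, fit the
model and average z (power-law slope) or D_max (PLEC maximum).  The null
distribution pools the two groups' samples and randomly re-splits them
into pseudo-groups of the original sizes, recomputing the statistic pair
each time.  The p-value uses the add-one correction

    p = (1 + #{null >= observed}) / (n_valid + 1),

so Monte-Carlo p-values are never zero.  Differences are absolute, i.e.
two-sided.  Permutations whose statistic is undefined (all inner fits
degenerate) are excluded; if more than half are, the test is flagged
inconclusive rather than coerced to a 0/1 call.

The inner loop uses closed-form least squares (identical coefficients to
:func:`darscale.dar.fit_pl` / :func:`fit_plec`) and needs no per-fit
p-value, so a pairwise site matrix at 1000 permutations stays tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .hill import DEFAULT_Q_GRID, hill_rows
from .io_tables import AbundanceTable

_FLAT_TOL = 1e-12

__all__ = [
    "PermutationTestResult",
    "SignificanceMatrix",
    "pairwise_matrix",
    "randomization_test",
]


@dataclass(frozen=True)
class PermutationTestResult:
    """Two-group permutation test on a resampling-averaged DAR parameter."""

    statistic_name: str
    q: float
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    significant: int
    alpha: float
    inconclusive: bool
    n_invalid: int


@dataclass
class SignificanceMatrix:
    """Pairwise 0/1 significance codes between sites, one digit per q.

    ``codes`` is a symmetric site x site frame of strings such as
    ``"0,000"`` (digit for q=0, comma, digits for q=1..); the diagonal is
    NA.  ``percentages`` gives, per q and site, the percentage of that
    site's conclusive comparisons that were significant.
    """

    sites: tuple[str, ...]
    q_grid: tuple[float, ...]
    statistic_name: str
    codes: pd.DataFrame
    significant: dict[float, pd.DataFrame]
    percentages: pd.DataFrame
    alpha: float

    def to_tsv(self, path) -> None:
        out = self.codes.copy()
        for q in self.q_grid:
            out.loc[f"% significant (q={q:g})"] = [
                f"{v:.1f}" for v in self.percentages.loc[q]
            ]
        out.index.name = "site"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------- fast inner fits


def _slope_z(ln_a: np.ndarray, ln_d: np.ndarray) -> float:
    """Closed-form OLS slope of ln D on ln A; NaN for a flat curve."""
    if np.ptp(ln_d) <= _FLAT_TOL * max(1.0, float(np.abs(ln_d).max())):
        return float("nan")
    xc = ln_a - ln_a.mean()
    return float(xc @ (ln_d - ln_d.mean()) / (xc @ xc))


def _dmax(ln_a: np.ndarray, a: np.ndarray, ln_d: np.ndarray) -> float:
    """D_max from the closed-form PLEC normal equations; NaN if undefined."""
    if ln_d.size < 4 or np.ptp(ln_d) <= _FLAT_TOL * max(
        1.0, float(np.abs(ln_d).max())
    ):
        return float("nan")
    X = np.column_stack([np.ones_like(a), ln_a, a])
    coef, _, rank, _ = np.linalg.lstsq(X, ln_d, rcond=None)
    if rank < 3:
        return float("nan")
    ln_c, z, d = (float(v) for v in coef)
    if d >= 0 or z <= 0:
        return float("nan")
    a_max = -z / d
    return float(np.exp(ln_c) * a_max**z * np.exp(-z))


def _group_statistic(
    matrix: np.ndarray,
    statistic: str,
    q: float,
    inner_reps: int,
    rng: np.random.Generator,
) -> float:
    """Mean fitted parameter over ``inner_reps`` random accumulation orders."""
    n = matrix.shape[0]
    ln_a = np.log(np.arange(1, n + 1, dtype=float))
    a = np.arange(1, n + 1, dtype=float)
    vals = []
    for _ in range(inner_reps):
        pooled = np.cumsum(matrix[rng.permutation(n)], axis=0)
        div = hill_rows(pooled, q)
        if np.any(div <= 0):
            continue
        ln_d = np.log(div)
        v = _slope_z(ln_a, ln_d) if statistic == "z" else _dmax(ln_a, a, ln_d)
        if np.isfinite(v):
            vals.append(v)
    return float(np.mean(vals)) if vals else float("nan")


# ------------------------------------------------------------- tests


def randomization_test(
    table: AbundanceTable,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    statistic: str = "z",
    q: float = 0.0,
    n_perm: int = 1000,
    inner_reps: int = 10,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationTestResult:
    """Permutation test for a difference in a DAR parameter between two groups.

    Parameters
    ----------
    samples_a, samples_b
        Sample ids of the two groups (each at least 4 samples).
    statistic
        ``"z"`` (power-law slope) or ``"Dmax"`` (PLEC maximum).
    inner_reps
        Random accumulation orders averaged per (pseudo-)group.
    """
    if statistic not in ("z", "Dmax"):
        raise ValueError("statistic must be 'z' or 'Dmax'")
    ids_a, ids_b = list(samples_a), list(samples_b)
    if len(ids_a) < 4 or len(ids_b) < 4:
        raise ValueError("both groups need at least 4 samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    # canonical group order, so swapping A and B cannot change the
    # random stream and the result is exactly symmetric
    if sorted(ids_b) < sorted(ids_a):
        ids_a, ids_b = ids_b, ids_a

    mat_a = table.data.loc[ids_a].to_numpy(dtype=float)
    mat_b = table.data.loc[ids_b].to_numpy(dtype=float)

    stat_a = _group_statistic(mat_a, statistic, q, inner_reps, rng)
    stat_b = _group_statistic(mat_b, statistic, q, inner_reps, rng)
    observed = abs(stat_a - stat_b)

    pooled = np.vstack([mat_a, mat_b])
    n_a, n_tot = mat_a.shape[0], pooled.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n_tot)
        sa = _group_statistic(pooled[perm[:n_a]], statistic, q, inner_reps, rng)
        sb = _group_statistic(pooled[perm[n_a:]], statistic, q, inner_reps, rng)
        null[i] = abs(sa - sb)

    valid = null[np.isfinite(null)]
    n_invalid = n_perm - valid.size
    inconclusive = (not np.isfinite(observed)) or n_invalid > n_perm // 2
    if inconclusive:
        p = float("nan")
        significant = 0
    else:
        p = float((1 + np.sum(valid >= observed)) / (valid.size + 1))
        significant = int(p < alpha)
    return PermutationTestResult(
        statistic_name=statistic,
        q=float(q),
        observed_diff=observed,
        null_diffs=null,
        p_value=p,
        significant=significant,
        alpha=alpha,
        inconclusive=inconclusive,
        n_invalid=n_invalid,
    )


def _code(digits: list[str]) -> str:
    return f"{digits[0]},{''.join(digits[1:])}" if len(digits) > 1 else digits[0]


def pairwise_matrix(
    table: AbundanceTable,
    sites: Sequence[str] | None = None,
    statistic: str = "Dmax",
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    n_perm: int = 1000,
    inner_reps: int = 10,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SignificanceMatrix:
    """All-pairs permutation tests between sites, coded one digit per q.

    Each unordered pair of sites is tested at every q; the cell code
    concatenates the 0/1 calls (``"0,000"`` style), with ``-`` for an
    inconclusive test.  No multiple-testing correction is applied.
    """
    rng = np.random.default_rng(seed)
    site_list = tuple(sites) if sites is not None else tuple(table.sites())
    qs = tuple(float(q) for q in q_grid)
    samples = {s: table.samples_at_site(s) for s in site_list}

    codes = pd.DataFrame(pd.NA, index=site_list, columns=site_list, dtype=object)
    sig = {q: pd.DataFrame(np.nan, index=site_list, columns=site_list) for q in qs}
    for sa, sb in combinations(site_list, 2):
        digits = []
        for q in qs:
            res = randomization_test(
                table,
                samples[sa],
                samples[sb],
                statistic=statistic,
                q=q,
                n_perm=n_perm,
                inner_reps=inner_reps,
                alpha=alpha,
                rng=rng,
            )
            if res.inconclusive:
                digits.append("-")
            else:
                digits.append(str(res.significant))
                sig[q].loc[sa, sb] = sig[q].loc[sb, sa] = res.significant
        codes.loc[sa, sb] = codes.loc[sb, sa] = _code(digits)

    pct = pd.DataFrame(0.0, index=list(qs), columns=site_list)
    for q in qs:
        for s in site_list:
            row = sig[q].loc[s].drop(labels=[s])
            conclusive = row.dropna()
            pct.loc[q, s] = (
                100.0 * conclusive.mean() if len(conclusive) else float("nan")
            )
    pct.index.name = "q"
    return SignificanceMatrix(
        sites=site_list,
        q_grid=qs,
        statistic_name=statistic,
        codes=codes,
        significant=sig,
        percentages=pct,
        alpha=alpha,
    )
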
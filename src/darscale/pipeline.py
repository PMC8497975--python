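"""Resampling designs assembling DAR parameter profiles.

Two designs are implemented:

* **inter-individual** — for one body site, the accumulation units are
  the site's samples (one per subject).  The accumulation order is
  randomly permuted for each of ``n_resamples`` (default 100) resamples,
  PL and PLEC models are fit per diversity order q, and per-q means and
  standard errors over the successful fits are reported.

* **intra-DT (intra-individual)** — the accumulation units are the body
  sites themselves, accumulated in a fixed anatomical order (oral cavity
  to gut).  Each of ``n_resamples`` (default 1000) replicates draws one
  random sample per site to form a pseudo-individual, then fits per q.

Aggregation conventions (per q):

* ``N_success`` counts resamples whose PL fit met the fit-success rule;
  means/SEs of z, c, g, R and p are over those resamples.
* ``g`` is computed per resample as ``2 - 2**z`` and then averaged
  (not ``g`` of the mean z).
* ``mean_d`` is over resamples with a successful PLEC fit; ``D_max`` and
  ``RIP`` (``100 * c_PL / D_max``) are over resamples where the PLEC
  maximum exists (d < 0 < z).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import dar
from .hill import DEFAULT_Q_GRID
from .io_tables import RANKS, AbundanceTable, collapse_to_level
from .synthetic import DT_SITES

#: Default anatomical accumulation order, oral cavity -> oropharynx -> gut.
DEFAULT_SITE_ORDER: tuple[str, ...] = DT_SITES

PROFILE_COLUMNS = [
    "mean_z", "se_z", "mean_c", "mean_d", "mean_g", "mean_Dmax", "se_Dmax",
    "mean_RIP", "R", "p_value", "N_success", "n_resamples",
]

__all__ = [
    "DEFAULT_SITE_ORDER",
    "DARProfileSet",
    "RunSettings",
    "inter_individual_profiles",
    "intra_individual_profiles",
    "run_all_levels",
    "tidy_frame",
]


@dataclass
class DARProfileSet:
    """Per-q DAR parameter summary for one grouping (site or intra-DT).

    ``stats`` is indexed by diversity order q with columns
    :data:`PROFILE_COLUMNS`; ``resample_log`` optionally keeps the
    per-resample fit parameters the means were computed from.
    """

    grouping: str
    taxon_level: str
    q_grid: tuple[float, ...]
    stats: pd.DataFrame
    n_resamples: int
    resample_log: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        out = self.stats.copy()
        out.insert(0, "grouping", self.grouping)
        out.insert(1, "taxon_level", self.taxon_level)
        out.index.name = "q"
        out.to_csv(path, sep="\t")


def _fit_ordered_rows(rows: np.ndarray, q_grid, resample: int) -> list[dict]:
    """PL + PLEC fits of one accumulation order, one record per q."""
    records = []
    for q in q_grid:
        curve = dar.accrual_curve_from_matrix(rows, q)
        pl = dar.fit_pl(curve)
        plec = dar.fit_plec(curve)
        has_max = np.isfinite(plec.D_max)
        records.append(
            {
                "resample": resample,
                "q": float(q),
                "z": pl.z,
                "c": pl.c,
                "g": dar.pdo_from_z(pl.z),
                "R": pl.R,
                "p_value": pl.p_value,
                "pl_success": pl.success,
                "d": plec.d,
                "plec_success": plec.success,
                "Dmax": plec.D_max,
                "RIP": dar.rip(pl.c, plec.D_max) if has_max else float("nan"),
            }
        )
    return records


def _aggregate(
    records: list[dict],
    q_grid,
    n_resamples: int,
    grouping: str,
    taxon_level: str,
    keep_log: bool,
) -> DARProfileSet:
    log = pd.DataFrame(records)
    rows = []
    for q in q_grid:
        sub = log[log["q"] == float(q)]
        ok = sub[sub["pl_success"]]
        n_ok = len(ok)
        plec_ok = sub[sub["plec_success"]]
        with_max = sub[np.isfinite(sub["Dmax"]) & sub["pl_success"]]

        def _m(frame, col):
            return float(frame[col].mean()) if len(frame) else float("nan")

        def _se(frame, col):
            if len(frame) < 2:
                return float("nan")
            return float(frame[col].std(ddof=1) / np.sqrt(len(frame)))

        rows.append(
            {
                "q": float(q),
                "mean_z": _m(ok, "z"),
                "se_z": _se(ok, "z"),
                "mean_c": _m(ok, "c"),
                "mean_d": _m(plec_ok, "d"),
                "mean_g": _m(ok, "g"),
                "mean_Dmax": _m(with_max, "Dmax"),
                "se_Dmax": _se(with_max, "Dmax"),
                "mean_RIP": _m(with_max, "RIP"),
                "R": _m(ok, "R"),
                "p_value": _m(ok, "p_value"),
                "N_success": n_ok,
                "n_resamples": n_resamples,
            }
        )
    stats = pd.DataFrame(rows).set_index("q")
    return DARProfileSet(
        grouping=grouping,
        taxon_level=taxon_level,
        q_grid=tuple(float(q) for q in q_grid),
        stats=stats,
        n_resamples=n_resamples,
        resample_log=log if keep_log else None,
    )


def inter_individual_profiles(
    table: AbundanceTable,
    site: str,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    n_resamples: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    taxon_level: str = "genus",
    keep_log: bool = False,
) -> DARProfileSet:
    """Inter-individual DAR profile of one body site.

    Each resample permutes the accumulation order of the site's samples
    (one sample per subject), builds the accrual curve per q, fits both
    models and averages the parameters over successful fits.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ids = table.samples_at_site(site)
    if len(ids) < 4:
        raise dar.InsufficientDataError(
            f"site {site!r} has {len(ids)} usable samples; need at least 4"
        )
    matrix = table.data.loc[ids].to_numpy(dtype=float)
    records: list[dict] = []
    for r in range(n_resamples):
        perm = rng.permutation(matrix.shape[0])
        records.extend(_fit_ordered_rows(matrix[perm], q_grid, r))
    return _aggregate(records, q_grid, n_resamples, site, taxon_level, keep_log)


def intra_individual_profiles(
    table: AbundanceTable,
    site_order: Sequence[str] = DEFAULT_SITE_ORDER,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    n_resamples: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    taxon_level: str = "genus",
    keep_log: bool = False,
) -> DARProfileSet:
    """Intra-DT DAR profile across body sites.

    Each replicate draws one random sample per site and accumulates the
    sites in the fixed anatomical ``site_order``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    meta = table.metadata.loc[table.data.index]
    site_samples = {}
    for site in site_order:
        ids = sorted(meta.index[meta["site"] == site])
        if not ids:
            raise ValueError(f"site {site!r} has no samples in the table")
        site_samples[site] = ids
    matrices = {
        site: table.data.loc[ids].to_numpy(dtype=float)
        for site, ids in site_samples.items()
    }
    records: list[dict] = []
    for r in range(n_resamples):
        rows = np.stack(
            [
                matrices[site][rng.integers(len(site_samples[site]))]
                for site in site_order
            ]
        )
        records.extend(_fit_ordered_rows(rows, q_grid, r))
    return _aggregate(
        records, q_grid, n_resamples, "intra-DT", taxon_level, keep_log
    )


@dataclass(frozen=True)
class RunSettings:
    """Configuration of a multi-level pipeline run."""

    levels: tuple[str, ...] = ("genus",)
    sites: tuple[str, ...] | None = None  # None = all sites in the table
    include_intra: bool = True
    site_order: tuple[str, ...] = DEFAULT_SITE_ORDER
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID
    n_inter: int = 100
    n_intra: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for level in self.levels:
            if level not in RANKS:
                raise ValueError(f"unknown taxon level {level!r}")


def run_all_levels(
    table: AbundanceTable, settings: RunSettings
) -> list[DARProfileSet]:
    """Collapse to each configured level and run both designs per level."""
    rng = np.random.default_rng(settings.seed)
    results: list[DARProfileSet] = []
    for level in settings.levels:
        collapsed = collapse_to_level(table, level)
        sites = settings.sites or tuple(collapsed.sites())
        for site in sites:
            results.append(
                inter_individual_profiles(
                    collapsed,
                    site,
                    q_grid=settings.q_grid,
                    n_resamples=settings.n_inter,
                    rng=rng,
                    taxon_level=level,
                )
            )
        if settings.include_intra:
            results.append(
                intra_individual_profiles(
                    collapsed,
                    site_order=settings.site_order,
                    q_grid=settings.q_grid,
                    n_resamples=settings.n_intra,
                    rng=rng,
                    taxon_level=level,
                )
            )
    return results


def tidy_frame(profiles: Sequence[DARProfileSet]) -> pd.DataFrame:
    """One row per grouping x level x q, suitable for TSV output."""
    frames = []
    for prof in profiles:
        out = prof.stats.reset_index()
        out.insert(0, "grouping", prof.grouping)
        out.insert(1, "taxon_level", prof.taxon_level)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
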
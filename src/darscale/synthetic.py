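"""Seeded synthetic microbiome cohorts with tunable diversity scaling.

The generator emulates the shape of a multi-site human digestive-tract
16S survey: ~10 body sites x O(100) subjects, one sample per subject and
site, taxa on a nested 5-level taxonomy (phylum..genus), heavy-tailed
(lognormal) abundances and core-satellite occupancy structure.

Occupancy is the mechanism that makes the richness-accrual slope z
tunable: each taxon t of a site's pool has a presence probability
``pi_t ~ Beta(a, b)``, drawn once per cohort, and each subject carries
taxon t with probability ``pi_t``.  The expected pooled richness over n
subjects then has the closed form

    E[S(n)] = T * (1 - B(a, b + n) / B(a, b)),

whose log-log slope over an area range plays the role of the target
power-law exponent; :func:`calibrate_occupancy` inverts it.

The generator makes no attempt to reproduce real taxon identities,
compositional covariances, or sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_tables import RANKS, AbundanceTable

#: The ten digestive-tract site labels, oral cavity to gut.
DT_SITES: tuple[str, ...] = (
    "BM", "KG", "HP", "TD", "PT", "Th", "Sal", "SupP", "SubP", "Stool",
)

__all__ = [
    "DT_SITES",
    "CalibrationError",
    "CohortSpec",
    "calibrate_occupancy",
    "expected_pooled_richness",
    "generate_cohort",
    "generate_taxonomy",
    "occupancy_slope",
]


class CalibrationError(ValueError):
    """Raised when no Beta occupancy reaches the requested slope."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror a 242-subject, 10-site digestive-tract survey binned
    at five taxonomic levels.  ``occupancy_beta`` defaults to shapes whose
    closed-form richness-accrual slope over 1..242 subjects is ~0.29, the
    regime of genus-level inter-individual scaling; see
    :func:`calibrate_occupancy`.
    """

    n_subjects: int = 242
    sites: tuple[str, ...] = DT_SITES
    taxonomy_counts: tuple[int, int, int, int, int] = (14, 30, 60, 120, 400)
    pool_size: int = 300
    pool_overlap: float = 0.6
    site_pool_sizes: tuple[int, ...] | None = None
    occupancy_beta: tuple[float, float] = (1.0, 13.99)
    lognormal_sigma: float = 1.5
    read_depth: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = self.taxonomy_counts
        if len(counts) != len(RANKS):
            raise ValueError(f"taxonomy_counts must have {len(RANKS)} entries")
        if any(c <= 0 for c in counts):
            raise ValueError("taxonomy counts must be positive")
        if any(a > b for a, b in zip(counts, counts[1:])):
            raise ValueError("taxonomy counts must be non-decreasing down ranks")
        if not 0 <= self.pool_overlap <= 1:
            raise ValueError("pool_overlap must be in [0, 1]")
        if self.pool_size > counts[-1]:
            raise ValueError("pool_size cannot exceed the number of genera")
        if self.site_pool_sizes is not None:
            if len(self.site_pool_sizes) != len(self.sites):
                raise ValueError("site_pool_sizes must match the number of sites")
            if max(self.site_pool_sizes) > counts[-1]:
                raise ValueError("site pool sizes cannot exceed the number of genera")
        a, b = self.occupancy_beta
        if a <= 0 or b <= 0:
            raise ValueError("occupancy Beta shapes must be positive")
        if self.n_subjects < 1 or self.read_depth < 1:
            raise ValueError("n_subjects and read_depth must be positive")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


# ------------------------------------------------------------ taxonomy

_RANK_TAGS = ("p", "c", "o", "f", "g")


def generate_taxonomy(spec: CohortSpec) -> pd.DataFrame:
    """Random nested lineage map: genus -> family -> ... -> phylum.

    Every child rank is assigned a parent such that each parent has at
    least one child; deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = spec.taxonomy_counts
    names = [
        [f"{_RANK_TAGS[r]}{i + 1:04d}" for i in range(counts[r])]
        for r in range(len(counts))
    ]
    # parent index of each taxon at rank r (r >= 1)
    parents: list[np.ndarray] = [np.array([], dtype=int)]
    for r in range(1, len(counts)):
        n_parent, n_child = counts[r - 1], counts[r]
        # each parent gets one child, the rest are assigned at random
        assign = np.concatenate(
            [
                rng.permutation(n_parent),
                rng.integers(0, n_parent, size=n_child - n_parent),
            ]
        )
        parents.append(rng.permutation(assign))

    rows = []
    for g in range(counts[-1]):
        idx = g
        lineage = [names[-1][idx]]
        for r in range(len(counts) - 1, 0, -1):
            idx = int(parents[r][idx])
            lineage.append(names[r - 1][idx])
        rows.append(tuple(reversed(lineage)))
    return pd.DataFrame(rows, index=names[-1], columns=list(RANKS))


# ------------------------------------------------------- occupancy math


def expected_pooled_richness(
    a: float, b: float, n, pool_size: int = 1
) -> np.ndarray:
    """Closed-form E[S(n)] = T * (1 - B(a, b+n)/B(a, b)) for pi ~ Beta(a, b)."""
    n = np.asarray(n, dtype=float)
    log_ratio = special.betaln(a, b + n) - special.betaln(a, b)
    return pool_size * (1.0 - np.exp(log_ratio))


def occupancy_slope(a: float, b: float, n_range: Sequence[int]) -> float:
    """Log-log OLS slope of the expected richness-accrual curve over ``n_range``."""
    n = np.asarray(list(n_range), dtype=float)
    if n.size < 3:
        raise ValueError("n_range must contain at least 3 areas")
    y = np.log(expected_pooled_richness(a, b, n))
    x = np.log(n)
    return float(stats.linregress(x, y).slope)


def calibrate_occupancy(
    target_z: float,
    n_range: Sequence[int] = range(1, 101),
    pool_size: int = 300,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Beta occupancy shapes whose expected-richness slope matches ``target_z``.

    Fixes ``a = 1`` (then ``E[S(n)] = T * n / (b + n)``) and bisects on
    ``b``: the slope is monotone increasing in ``b`` and spans (0, 1), so
    any target in that open interval is reachable.  Purely closed-form —
    no simulation.  ``pool_size`` does not affect the slope; it is
    accepted so calibration and generation share one vocabulary.
    """
    if not 0 < target_z < 1:
        raise CalibrationError(
            f"target slope must lie in (0, 1); got {target_z} "
            "(achievable range of the Beta occupancy model is (0, 1))"
        )
    a = 1.0
    lo, hi = 1e-9, 1e9
    ns = list(n_range)
    s_lo, s_hi = occupancy_slope(a, lo, ns), occupancy_slope(a, hi, ns)
    if not s_lo < target_z < s_hi:
        raise CalibrationError(
            f"target {target_z} outside achievable slope range "
            f"[{s_lo:.4f}, {s_hi:.4f}] over this n_range"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisect in log space
        if occupancy_slope(a, mid, ns) < target_z:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    b = float(np.sqrt(lo * hi))
    if abs(occupancy_slope(a, b, ns) - target_z) > max(tol, 1e-4):
        raise CalibrationError("bisection failed to reach the target slope")
    return a, b


# --------------------------------------------------------- generation


def _site_pools(spec: CohortSpec, genera: list[str], rng) -> dict[str, np.ndarray]:
    """Per-site genus pools: a shared core plus site-specific draws.

    With ``site_pool_sizes`` set, pools are instead nested prefixes of a
    single master pool (maximal cross-site overlap, differing only in
    size) — the regime for contrasting sites by pool size alone.
    """
    if spec.site_pool_sizes is not None:
        master = rng.choice(
            len(genera), size=max(spec.site_pool_sizes), replace=False
        )
        return {
            site: np.sort(master[:size])
            for site, size in zip(spec.sites, spec.site_pool_sizes)
        }
    n_core = int(round(spec.pool_overlap * spec.pool_size))
    n_extra = spec.pool_size - n_core
    all_idx = np.arange(len(genera))
    core = rng.choice(all_idx, size=n_core, replace=False)
    non_core = np.setdiff1d(all_idx, core)
    if n_extra > non_core.size:
        raise ValueError(
            "taxonomy too small for the requested pool_size/pool_overlap"
        )
    pools = {}
    for site in spec.sites:
        extra = rng.choice(non_core, size=n_extra, replace=False)
        pools[site] = np.sort(np.concatenate([core, extra]))
    return pools


def generate_cohort(spec: CohortSpec) -> AbundanceTable:
    """Generate a seeded cohort table (one sample per subject x site).

    Per site: a genus pool with per-taxon mean log-abundances
    ``~ Normal(0, sigma^2)`` and occupancy ``pi ~ Beta(a, b)``.  Per
    subject x site: each pool taxon is present with probability ``pi``;
    present taxa get lognormal relative abundances (per-sample deviation
    ``sigma/2``) and counts are multinomial at ``read_depth``.
    """
    rng = np.random.default_rng(spec.seed)
    lineages = generate_taxonomy(spec)
    genera = list(lineages.index)
    pools = _site_pools(spec, genera, rng)
    a, b = spec.occupancy_beta
    sigma = spec.lognormal_sigma

    used = sorted(set(np.concatenate(list(pools.values())).tolist()))
    col_of = {g: j for j, g in enumerate(used)}
    subjects = [f"S{i + 1:03d}" for i in range(spec.n_subjects)]

    counts = np.zeros((spec.n_subjects * len(spec.sites), len(used)), dtype=float)
    sample_ids, meta_rows = [], []
    row = 0
    for site in spec.sites:
        pool = pools[site]
        cols = np.array([col_of[g] for g in pool])
        pi = rng.beta(a, b, size=pool.size)
        mean_log = rng.normal(0.0, sigma, size=pool.size)
        anchor = int(np.argmax(pi))  # fallback so no sample is empty
        for i, subj in enumerate(subjects):
            present = rng.random(pool.size) < pi
            if not present.any():
                present[anchor] = True
            w = np.zeros(pool.size)
            k = int(present.sum())
            w[present] = np.exp(
                mean_log[present] + 0.5 * sigma * rng.normal(size=k)
            )
            p = w / w.sum()
            counts[row, cols] = rng.multinomial(spec.read_depth, p)
            sample_ids.append(f"{subj}_{site}")
            meta_rows.append((subj, site))
            row += 1

    data = pd.DataFrame(counts, index=sample_ids, columns=[genera[j] for j in used])
    metadata = pd.DataFrame(
        meta_rows, index=sample_ids, columns=["subject_id", "site"]
    )
    metadata.index.name = "sample_id"
    return AbundanceTable(
        data=data, lineages=lineages.loc[data.columns].copy(), metadata=metadata
    )
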
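"""Synthetic cohort generator: determinism, structure, calibration."""

import numpy as np
import pytest

from darscale.io_tables import RANKS
from darscale.synthetic import (
    CalibrationError,
    CohortSpec,
    calibrate_occupancy,
    expected_pooled_richness,
    generate_cohort,
    generate_taxonomy,
    occupancy_slope,
)

SMALL = dict(
    n_subjects=8,
    sites=("A", "B"),
    pool_size=40,
    taxonomy_counts=(4, 8, 15, 25, 60),
)


def test_taxonomy_shape_and_nesting():
    spec = CohortSpec(taxonomy_counts=(2, 3, 5, 8, 20), pool_size=20, seed=1)
    lin = generate_taxonomy(spec)
    assert lin.shape == (20, 5)
    assert list(lin.columns) == list(RANKS)
    assert (lin != "").all().all()
    # each genus maps to exactly one parent chain; each rank's label count
    # cannot exceed its configured size
    for rank, n in zip(RANKS, (2, 3, 5, 8, 20)):
        assert lin[rank].nunique() <= n
    # nesting: a family never spans two orders
    assert (lin.groupby("family")["order"].nunique() == 1).all()


def test_taxonomy_deterministic_under_seed():
    spec = CohortSpec(taxonomy_counts=(2, 3, 5, 8, 20), pool_size=20, seed=5)
    assert generate_taxonomy(spec).equals(generate_taxonomy(spec))


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        CohortSpec(taxonomy_counts=(5, 3, 5, 8, 20), pool_size=10)  # not nested
    with pytest.raises(ValueError):
        CohortSpec(pool_size=1000)  # pool exceeds genera
    with pytest.raises(ValueError):
        CohortSpec(occupancy_beta=(0.0, 1.0))
    with pytest.raises(ValueError):
        CohortSpec(pool_overlap=1.5)


def test_cohort_shape_and_read_depth():
    spec = CohortSpec(**SMALL, read_depth=500, seed=2)
    table = generate_cohort(spec)
    assert table.shape[0] == 8 * 2
    np.testing.assert_array_equal(table.data.sum(axis=1), 500.0)
    table.validate()  # all AbundanceTable invariants hold


def test_cohort_deterministic_and_seed_sensitive():
    a = generate_cohort(CohortSpec(**SMALL, seed=3))
    b = generate_cohort(CohortSpec(**SMALL, seed=3))
    c = generate_cohort(CohortSpec(**SMALL, seed=4))
    assert a.data.equals(b.data)
    assert not a.data.equals(c.data)


def test_near_certain_occupancy_gives_full_pool_and_no_accrual():
    from darscale.pipeline import inter_individual_profiles

    spec = CohortSpec(
        n_subjects=10, sites=("A",), pool_size=30,
        taxonomy_counts=(3, 5, 8, 15, 60), occupancy_beta=(5000.0, 1.0),
        read_depth=200_000, seed=6,
    )
    table = generate_cohort(spec)
    # every subject carries (essentially) the whole pool: flat richness accrual
    prof = inter_individual_profiles(table, "A", q_grid=(0,), n_resamples=10,
                                     seed=0)
    assert prof.stats.loc[0.0, "N_success"] == 0  # constant-curve failure
    richness = (table.data > 0).sum(axis=1)
    assert richness.min() >= 28


def test_expected_pooled_richness_matches_simulation():
    a, b, pool, n = 1.0, 3.0, 50, 12
    rng = np.random.default_rng(8)
    reps = 200
    sims = np.empty(reps)
    for r in range(reps):
        pi = rng.beta(a, b, size=pool)
        present = rng.random((n, pool)) < pi
        sims[r] = np.count_nonzero(present.any(axis=0))
    expected = expected_pooled_richness(a, b, n, pool)
    se = sims.std(ddof=1) / np.sqrt(reps)
    assert abs(sims.mean() - expected) < 3 * se + 1e-9


def test_calibration_hits_target_slope():
    a, b = calibrate_occupancy(0.3, range(1, 101), 300)
    assert 0.28 <= occupancy_slope(a, b, range(1, 101)) <= 0.32


def test_calibration_small_target_pushes_occupancy_up():
    means = []
    for target in (0.002, 0.02, 0.1, 0.3, 0.6):
        a, b = calibrate_occupancy(target, range(1, 101), 300)
        means.append(a / (a + b))
    # target -> 0 pushes mean occupancy toward 1, monotonically
    assert np.all(np.diff(means) < 0)
    assert means[0] > 0.95


def test_calibration_rejects_infeasible_targets():
    for bad in (0.0, 1.0, 1.5, -0.2):
        with pytest.raises(CalibrationError):
            calibrate_occupancy(bad, range(1, 101), 300)


def test_slope_monotone_in_mean_occupancy():
    # smaller mean occupancy (larger b at fixed a) => steeper accrual
    ns = range(1, 61)
    for a in (0.5, 1.0, 2.0):
        slopes = [occupancy_slope(a, b, ns) for b in (0.5, 2.0, 8.0, 32.0)]
        assert np.all(np.diff(slopes) > 0)


def test_site_pool_sizes_are_nested():
    # near-certain occupancy and deep sampling so the realized support
    # of each site coincides with its pool
    spec = CohortSpec(
        n_subjects=6, sites=("A", "B"), pool_size=50,
        taxonomy_counts=(4, 8, 15, 25, 80), site_pool_sizes=(20, 50),
        occupancy_beta=(500.0, 1.0), read_depth=200_000, seed=9,
    )
    table = generate_cohort(spec)
    support = lambda site: set(
        table.data.columns[
            (table.data.loc[table.samples_at_site(site, False)] > 0).any()
        ]
    )
    assert support("A") <= support("B")
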
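"""Accrual curves, PL/PLEC regression, and derived parameters."""

import numpy as np
import pandas as pd
import pytest

from darscale import dar
from darscale.io_tables import AbundanceTable, RANKS


def _curve(areas, diversities, q=0.0):
    return dar.AccrualCurve(
        areas=np.asarray(areas, float),
        diversities=np.asarray(diversities, float),
        q=q,
    )


# ------------------------------------------------------------- pooling


def test_pool_single_sample_is_identity(tiny_table):
    pooled = dar.pool_samples(tiny_table, ["s1"])
    np.testing.assert_array_equal(pooled, tiny_table.data.loc["s1"].to_numpy())


def test_pool_union_of_disjoint_supports():
    data = pd.DataFrame(
        np.vstack([np.r_[np.ones(5), np.zeros(7)], np.r_[np.zeros(5), np.ones(7)]]),
        index=["a", "b"],
        columns=[f"t{i}" for i in range(12)],
    )
    lineages = pd.DataFrame(
        [("P", "C", "O", "F", t) for t in data.columns],
        index=data.columns,
        columns=list(RANKS),
    )
    meta = pd.DataFrame(
        {"subject_id": ["u1", "u2"], "site": ["X", "X"]}, index=data.index
    )
    table = AbundanceTable(data=data, lineages=lineages, metadata=meta)
    assert np.count_nonzero(dar.pool_samples(table, ["a", "b"])) == 12


def test_pool_is_permutation_invariant(tiny_table):
    forward = dar.pool_samples(tiny_table, ["s1", "s2", "s3"])
    backward = dar.pool_samples(tiny_table, ["s3", "s1", "s2"])
    np.testing.assert_allclose(forward, backward)
    with pytest.raises(LookupError):
        dar.pool_samples(tiny_table, ["s1", "nope"])


# ------------------------------------------------------------- accrual


def test_accrual_identical_samples_is_flat(tiny_table):
    table = tiny_table
    table.data.loc["s2"] = table.data.loc["s1"]
    table.data.loc["s3"] = table.data.loc["s1"]
    curve = dar.accrual_curve(table, ["s1", "s2", "s3"], q=0)
    richness = np.count_nonzero(table.data.loc["s1"].to_numpy())
    np.testing.assert_array_equal(curve.diversities, [richness] * 3)


def test_accrual_disjoint_supports_add_richness():
    n, r = 5, 3
    rows = np.zeros((n, n * r))
    for i in range(n):
        rows[i, i * r : (i + 1) * r] = 1.0
    curve = dar.accrual_curve_from_matrix(rows, q=0)
    np.testing.assert_array_equal(curve.diversities, r * np.arange(1, n + 1))


def test_accrual_nested_samples_flat_after_first():
    # each sample's support contains the next one's; accumulate the
    # largest first so nothing new accrues -- verified against the
    # brute-force union of supports
    rng = np.random.default_rng(0)
    supports = [np.arange(20), np.arange(12), np.arange(5)]
    rows = np.zeros((3, 20))
    for i, sup in enumerate(supports):
        rows[i, sup] = rng.uniform(0.5, 2.0, size=sup.size)
    curve = dar.accrual_curve_from_matrix(rows, q=0)
    union = set()
    expected = []
    for i in range(3):
        union |= set(np.flatnonzero(rows[i]))
        expected.append(len(union))
    np.testing.assert_array_equal(curve.diversities, expected)
    assert curve.diversities[0] == curve.diversities[-1] == 20


def test_accrual_curve_areas_validated():
    with pytest.raises(ValueError):
        _curve([2, 3, 4], [1, 2, 3])  # must start at 1


# ------------------------------------------------------------ PL fits


def test_fit_pl_exact_power_law():
    a = np.arange(1, 11, dtype=float)
    fit = dar.fit_pl(_curve(a, 3.0 * a**0.5))
    assert fit.z == pytest.approx(0.5, abs=1e-10)
    assert fit.c == pytest.approx(3.0, abs=1e-10)
    assert fit.R == pytest.approx(1.0, abs=1e-10)
    assert fit.success


def test_fit_pl_constant_curve_fails():
    fit = dar.fit_pl(_curve(np.arange(1, 8), np.full(7, 11.0)))
    assert not fit.success
    assert fit.z == 0.0
    assert np.isnan(fit.R) and np.isnan(fit.p_value)


def _ols_normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


def test_fit_pl_matches_normal_equations_on_noisy_curve():
    rng = np.random.default_rng(11)
    a = np.arange(1, 26, dtype=float)
    d = 2.5 * a**0.3 * np.exp(rng.normal(0, 0.1, a.size))
    fit = dar.fit_pl(_curve(a, d))
    X = np.column_stack([np.ones_like(a), np.log(a)])
    ln_c, z = _ols_normal_equations(X, np.log(d))
    assert fit.z == pytest.approx(z, abs=1e-10)
    assert fit.ln_c == pytest.approx(ln_c, abs=1e-10)


def test_fit_pl_requires_three_points():
    with pytest.raises(dar.InsufficientDataError):
        dar.fit_pl(_curve([1, 2], [1.0, 2.0]))
    with pytest.raises(ValueError):
        dar.fit_pl(_curve([1, 2, 3], [1.0, 0.0, 2.0]))


# ---------------------------------------------------------- PLEC fits


def test_fit_plec_exact_model():
    a = np.arange(1, 31, dtype=float)
    fit = dar.fit_plec(_curve(a, 2.0 * a**0.4 * np.exp(-0.03 * a)))
    assert fit.z == pytest.approx(0.4, abs=1e-8)
    assert fit.c == pytest.approx(2.0, abs=1e-8)
    assert fit.d == pytest.approx(-0.03, abs=1e-8)
    assert fit.success
    assert fit.A_max == pytest.approx(0.4 / 0.03, rel=1e-8)


def test_fit_plec_growing_cutoff_has_no_maximum():
    a = np.arange(1, 21, dtype=float)
    fit = dar.fit_plec(_curve(a, 2.0 * a**0.4 * np.exp(0.01 * a)))
    assert fit.d > 0
    assert np.isnan(fit.A_max) and np.isnan(fit.D_max)
    assert fit.success  # the fit itself is still reported


def test_fit_plec_matches_normal_equations_on_noisy_curve():
    rng = np.random.default_rng(5)
    a = np.arange(1, 31, dtype=float)
    d = 4.0 * a**0.5 * np.exp(-0.02 * a) * np.exp(rng.normal(0, 0.05, a.size))
    fit = dar.fit_plec(_curve(a, d))
    X = np.column_stack([np.ones_like(a), np.log(a), a])
    ln_c, z, dd = _ols_normal_equations(X, np.log(d))
    assert fit.ln_c == pytest.approx(ln_c, abs=1e-10)
    assert fit.z == pytest.approx(z, abs=1e-10)
    assert fit.d == pytest.approx(dd, abs=1e-10)


def test_fit_plec_flat_and_insufficient():
    assert not dar.fit_plec(_curve(np.arange(1, 6), np.full(5, 4.0))).success
    with pytest.raises(dar.InsufficientDataError):
        dar.fit_plec(_curve([1, 2, 3], [1.0, 2.0, 3.0]))


# -------------------------------------------- derived parameters


@pytest.mark.parametrize(
    "z, expected",
    [(1.0, 0.0), (0.0, 1.0), (0.294, 2 - np.exp(0.294 * np.log(2)))],
)
def test_pdo_reference_values(z, expected):
    assert dar.pdo_from_z(z) == pytest.approx(expected, abs=1e-12)


def test_pdo_is_decreasing_and_unit_interval():
    zs = np.linspace(0, 1, 50)
    gs = np.array([dar.pdo_from_z(z) for z in zs])
    assert np.all(np.diff(gs) < 0)
    assert np.all((gs >= 0) & (gs <= 1))


def _plec_fit(c, z, d):
    a_max = -z / d if d < 0 and z > 0 else float("nan")
    d_max = c * a_max**z * np.exp(-z) if np.isfinite(a_max) else float("nan")
    return dar.PLECFit(
        z=z, ln_c=np.log(c), d=d, R=1.0, p_value=0.0, success=True,
        n_points=30, A_max=a_max, D_max=d_max,
    )


def test_mad_reference_value():
    a_max, d_max = dar.mad_from_plec(_plec_fit(1.0, 0.5, -0.05))
    assert a_max == pytest.approx(10.0, abs=1e-12)
    assert d_max == pytest.approx(np.sqrt(10) * np.exp(-0.5), rel=1e-12)


def test_mad_equals_plec_curve_maximum():
    # the closed form must equal the PLEC model at A_max, and be the
    # maximum of the curve on a dense grid
    for c, z, d in [(1, 0.5, -0.05), (5, 0.3, -0.01), (0.7, 0.9, -0.2)]:
        a_max, d_max = dar.mad_from_plec(_plec_fit(c, z, d))
        assert d_max == pytest.approx(
            dar.plec_value(c, z, d, a_max), rel=1e-10
        )
        grid = np.linspace(a_max * 0.2, a_max * 3, 2000)
        assert d_max >= dar.plec_value(c, z, d, grid).max() - 1e-9 * d_max


def test_mad_undefined_for_growing_cutoff():
    with pytest.raises(dar.UndefinedMaximumError):
        dar.mad_from_plec(_plec_fit(1.0, 0.5, 0.01))


def test_mad_linear_in_c():
    _, d1 = dar.mad_from_plec(_plec_fit(1.0, 0.5, -0.05))
    a2, d2 = dar.mad_from_plec(_plec_fit(2.0, 0.5, -0.05))
    assert d2 == pytest.approx(2 * d1, rel=1e-12)
    assert a2 == pytest.approx(10.0, abs=1e-12)


def test_rip_values_and_errors():
    assert dar.rip(8.0, 8.0) == pytest.approx(100.0)
    assert dar.rip(2.0, 8.0) == pytest.approx(25.0)
    with pytest.raises(ValueError):
        dar.rip(0.0, 8.0)
    with pytest.raises(ValueError):
        dar.rip(2.0, -1.0)
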
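"""Trial-design calculators: design effects, t-corrected cRCT sizing,
stepped-wedge GLS variance and the reference planning grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.power import TTestIndPower

from clusterpa import (
    AllocationError,
    DesignSpec,
    achieved_power,
    cluster_period_variances,
    design_effect_crct,
    hh_treatment_variance,
    required_schools,
    required_schools_ancova,
    required_schools_crct,
    required_schools_sw,
)
from clusterpa.design import default_planning_grid, planning_table

PRIMARY = dict(delta=5.0, sd_total=23.2, m=25, alpha=0.05, power=0.80)
SECONDARY = dict(delta=5.0, sd_total=27.5, m=50, alpha=0.05, power=0.80)


def gls_variance_oracle(n_schools, steps, vb, vw):
    """Brute force: invert the full (I*T x I*T) covariance of
    cluster-period means and read off the treatment-effect variance."""
    T = steps + 1
    per = n_schools // steps
    X = np.zeros((n_schools, T))
    for s in range(steps):
        X[s * per:(s + 1) * per, s + 1:] = 1.0
    design = []
    for i in range(n_schools):
        for t in range(T):
            row = np.zeros(T + 1)
            row[t] = 1.0  # period fixed effect
            row[T] = X[i, t]  # treatment
            design.append(row)
    design = np.array(design)
    v_cell = vw * np.eye(T) + vb * np.ones((T, T))
    v_full = np.kron(np.eye(n_schools), v_cell)
    info = design.T @ np.linalg.inv(v_full) @ design
    return np.linalg.inv(info)[T, T]


@pytest.mark.parametrize(
    "m, icc, expected", [(25, 0.08, 2.92), (1, 0.3, 1.0), (50, 0.05, 3.45)]
)
def test_design_effect(m, icc, expected):
    assert design_effect_crct(m, icc) == pytest.approx(expected)


@pytest.mark.parametrize(
    "params, icc, expected_total",
    [
        (PRIMARY, 0.08, 82),
        (PRIMARY, 0.10, 94),
        (SECONDARY, 0.05, 68),
        (SECONDARY, 0.08, 96),
    ],
)
def test_crct_reference_school_counts(params, icc, expected_total):
    res = required_schools_crct(DesignSpec(design="crct", icc=icc, **params))
    assert res.total_schools == expected_total
    assert res.allocation == (expected_total // 2,) * 2


def test_crct_m1_matches_classical_two_sample_t_sizing():
    spec = DesignSpec(design="crct", delta=5.0, sd_total=20.0, icc=0.0, m=1)
    res = required_schools_crct(spec)
    n_cont = TTestIndPower().solve_power(
        effect_size=5.0 / 20.0, alpha=0.05, power=0.80, alternative="two-sided"
    )
    assert res.total_schools // 2 == int(np.ceil(n_cont - 1e-9))


def test_ancova_reduces_to_crct_on_equal_inputs():
    crct = required_schools_crct(DesignSpec(design="crct", icc=0.08, **PRIMARY))
    anc = required_schools_ancova(
        DesignSpec(design="crct_baseline_adjusted", icc=0.08, **PRIMARY)
    )
    assert anc.total_schools == crct.total_schools


def test_ancova_smaller_adjusted_sd_needs_fewer_schools():
    base = required_schools_crct(DesignSpec(design="crct", icc=0.08, **PRIMARY))
    params = dict(PRIMARY, sd_total=0.9 * PRIMARY["sd_total"])
    adj = required_schools_ancova(
        DesignSpec(design="crct_baseline_adjusted", icc=0.08, **params)
    )
    assert adj.total_schools <= base.total_schools


@pytest.mark.parametrize(
    "cohort, expected",
    [(False, (25.84, 37.03)), (True, (35.74, 27.13))],
)
def test_cluster_period_variance_decomposition(cohort, expected):
    vb, vw = cluster_period_variances(
        23.2, 0.08, 0.6, 0.5 if cohort else 0.0, 25, cohort
    )
    assert vb == pytest.approx(expected[0], abs=0.01)
    assert vw == pytest.approx(expected[1], abs=0.01)


def test_cac_one_recovers_classical_exchangeable_model():
    sd, icc, m = 27.5, 0.05, 50
    vb, vw = cluster_period_variances(sd, icc, 1.0, 0.0, m, cohort=False)
    assert vb == pytest.approx(icc * sd**2)
    assert vw == pytest.approx((1 - icc) * sd**2 / m)


def test_hh_variance_no_between_component_two_clusters():
    # v_between = 0, 2 steps, I = 2: GLS reduces to 2 v_w
    vw = 3.7
    assert hh_treatment_variance(2, 2, 0.0, vw) == pytest.approx(
        gls_variance_oracle(2, 2, 0.0, vw)
    )
    assert hh_treatment_variance(2, 2, 0.0, vw) == pytest.approx(2 * vw)


def test_hh_variance_reference_cell():
    vb, vw = cluster_period_variances(23.2, 0.08, 0.6, 0.0, 25, cohort=False)
    var = hh_treatment_variance(62, 2, vb, vw)
    assert var == pytest.approx(3.085, abs=0.001)
    assert np.sqrt(var) == pytest.approx(1.757, abs=0.001)


def test_hh_variance_matches_gls_oracle_over_random_designs():
    rng = np.random.default_rng(0)
    for _ in range(40):
        steps = int(rng.integers(2, 4))  # T = steps + 1 <= 4
        n = steps * int(rng.integers(1, 12 // steps + 1))  # I <= 12
        vb = float(rng.uniform(0.0, 50.0))
        vw = float(rng.uniform(0.5, 50.0))
        closed = hh_treatment_variance(n, steps, vb, vw)
        oracle = gls_variance_oracle(n, steps, vb, vw)
        assert closed == pytest.approx(oracle, rel=1e-8)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    vb=st.floats(0.0, 100.0),
    vw=st.floats(0.1, 100.0),
    steps=st.integers(2, 3),
    mult=st.integers(1, 6),
)
def test_hh_variance_homogeneous_of_degree_one(vb, vw, steps, mult):
    n = steps * mult
    assert hh_treatment_variance(n, steps, 2 * vb, 2 * vw) == pytest.approx(
        2 * hh_treatment_variance(n, steps, vb, vw), rel=1e-12
    )


def test_hh_variance_rejects_bad_allocation():
    with pytest.raises(AllocationError):
        hh_treatment_variance(7, 2, 1.0, 1.0)


SW_GRID = [
    # (design, steps, params, icc, expected)
    ("sw_cross_sectional", 2, PRIMARY, 0.08, 62),
    ("sw_cross_sectional", 2, PRIMARY, 0.10, 68),
    ("sw_cross_sectional", 2, SECONDARY, 0.05, 50),
    ("sw_cross_sectional", 2, SECONDARY, 0.08, 64),
    ("sw_cohort", 2, PRIMARY, 0.08, 48),
    ("sw_cohort", 2, PRIMARY, 0.10, 54),
    ("sw_cohort", 2, SECONDARY, 0.05, 40),
    ("sw_cohort", 2, SECONDARY, 0.08, 54),
    ("sw_cross_sectional", 3, PRIMARY, 0.08, 39),
    ("sw_cross_sectional", 3, PRIMARY, 0.10, 42),
    ("sw_cross_sectional", 3, SECONDARY, 0.05, 30),
    ("sw_cross_sectional", 3, SECONDARY, 0.08, 39),
    ("sw_cohort", 3, PRIMARY, 0.08, 30),
    ("sw_cohort", 3, PRIMARY, 0.10, 33),
    ("sw_cohort", 3, SECONDARY, 0.05, 24),
    ("sw_cohort", 3, SECONDARY, 0.08, 33),
]


@pytest.mark.parametrize("design, steps, params, icc, expected", SW_GRID)
def test_stepped_wedge_reference_school_counts(design, steps, params, icc,
                                               expected):
    spec = DesignSpec(design=design, steps=steps, icc=icc, cac=0.6, iac=0.5,
                      **params)
    res = required_schools_sw(spec)
    assert res.total_schools == expected
    assert res.total_schools % steps == 0
    assert res.achieved_power >= 0.80


def test_minimality_of_every_grid_cell():
    # one size class down must fall below the target power
    for design, steps, params, icc, expected in SW_GRID:
        spec = DesignSpec(design=design, steps=steps, icc=icc, cac=0.6,
                          iac=0.5, **params)
        smaller = expected - steps
        if smaller >= steps:
            assert achieved_power(spec, smaller) < 0.80
    for params, icc, total in [(PRIMARY, 0.08, 82), (PRIMARY, 0.10, 94),
                               (SECONDARY, 0.05, 68), (SECONDARY, 0.08, 96)]:
        spec = DesignSpec(design="crct", icc=icc, **params)
        assert achieved_power(spec, total - 2) < 0.80
        assert achieved_power(spec, total) >= 0.80


def test_schools_monotone_in_icc():
    totals = [
        required_schools(DesignSpec(design="crct", icc=icc, **PRIMARY)).total_schools
        for icc in (0.0, 0.02, 0.04, 0.08, 0.12)
    ]
    assert totals == sorted(totals)
    sw = [
        required_schools(
            DesignSpec(design="sw_cross_sectional", steps=2, icc=icc, cac=0.6,
                       **PRIMARY)
        ).total_schools
        for icc in (0.02, 0.05, 0.08, 0.12)
    ]
    assert sw == sorted(sw)


def test_cohort_never_needs_more_than_cross_sectional():
    for steps in (2, 3):
        for params in (PRIMARY, SECONDARY):
            for icc in (0.05, 0.08, 0.10):
                common = dict(steps=steps, icc=icc, cac=0.6, iac=0.5, **params)
                cs = required_schools(
                    DesignSpec(design="sw_cross_sectional", **common))
                co = required_schools(DesignSpec(design="sw_cohort", **common))
                assert co.total_schools <= cs.total_schools


def test_more_pupils_per_school_never_needs_more_schools():
    for icc in (0.05, 0.08):
        a = required_schools(
            DesignSpec(design="crct", **dict(PRIMARY, m=25), icc=icc))
        b = required_schools(
            DesignSpec(design="crct", **dict(PRIMARY, m=50), icc=icc))
        assert b.total_schools <= a.total_schools


def test_null_effect_power_equals_alpha():
    null = DesignSpec(design="crct", icc=0.08, **dict(PRIMARY, delta=0.0))
    assert achieved_power(null, 82) == pytest.approx(0.05)
    null_sw = DesignSpec(design="sw_cross_sectional", steps=2, icc=0.08,
                         cac=0.6, **dict(PRIMARY, delta=0.0))
    assert achieved_power(null_sw, 62) == pytest.approx(0.05)


def test_misspecified_icc_power_loss():
    # sized at an understated ICC, evaluated at the true one
    res = required_schools_crct(DesignSpec(design="crct", icc=0.04, **PRIMARY))
    assert res.total_schools == 56
    power = achieved_power(
        DesignSpec(design="crct", icc=0.04, **PRIMARY), 56, true_icc=0.08
    )
    assert round(100 * power) == 64
    res2 = required_schools_crct(DesignSpec(design="crct", icc=0.02, **PRIMARY))
    assert res2.total_schools == 44
    power2 = achieved_power(
        DesignSpec(design="crct", icc=0.02, **PRIMARY), 44, true_icc=0.08
    )
    assert round(100 * power2) == 53


def test_planning_table_reproduces_reference_grid():
    table = planning_table(*default_planning_grid())
    assert table.loc["crct"].tolist() == [82, 94, 68, 96]
    assert table.loc["sw_cross_sectional_2step"].tolist() == [62, 68, 50, 64]
    assert table.loc["sw_cohort_2step"].tolist() == [48, 54, 40, 54]
    assert table.loc["sw_cross_sectional_3step"].tolist() == [39, 42, 30, 39]
    assert table.loc["sw_cohort_3step"].tolist() == [30, 33, 24, 33]
    # upper-bound ICC columns never need fewer schools than the point
    assert (table["primary_upper"] >= table["primary_point"]).all()
    assert (table["secondary_upper"] >= table["secondary_point"]).all()


def test_spec_validation():
    with pytest.raises(ValueError):
        DesignSpec(design="crossover", delta=5, sd_total=20, icc=0.05, m=25)
    with pytest.raises(ValueError):
        DesignSpec(design="crct", delta=-1, sd_total=20, icc=0.05, m=25)
    with pytest.raises(ValueError):
        DesignSpec(design="crct", delta=5, sd_total=20, icc=1.0, m=25)
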
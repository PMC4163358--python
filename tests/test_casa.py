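"""Unit and property tests of the NPP equation chain."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

_hyp = settings(
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)

from grasscasa import (
    AlignmentError,
    CasaInputs,
    GridStack,
    annual_sum,
    compute_apar,
    compute_lue,
    compute_npp,
    compute_topt,
    dew_point_from_precipitable_water,
    run_casa,
    temperature_stress_1,
    temperature_stress_2,
    vapor_pressure_deficit,
    water_stress,
)
from grasscasa import _reference as ref


@pytest.mark.parametrize(
    "sol, fpar, expected",
    [(1000.0, 0.5, 250.0), (1200.0, 1.0, 600.0), (800.0, 0.0, 0.0)],
)
def test_apar_hand_values(make_stack, params, sol, fpar, expected):
    """APAR is half the product of solar radiation and absorbed-PAR fraction."""
    out = compute_apar(make_stack(sol), make_stack(fpar), params)
    assert out.values == pytest.approx(expected)


def test_apar_mask_union_and_alignment(make_stack, params, georef):
    mask = np.zeros((12, 2, 2), bool)
    mask[3, 0, 1] = True
    out = compute_apar(make_stack(500.0, mask=mask), make_stack(0.5), params)
    assert out.mask[3, 0, 1] and out.mask.sum() == 1
    other = GridStack(np.zeros((12, 3, 3)), georef)
    with pytest.raises(AlignmentError, match="fpar"):
        compute_apar(make_stack(500.0), other, params)


class TestTopt:
    def test_temperature_of_greenest_month(self, make_stack):
        fpar = np.full(12, 0.2)
        fpar[7] = 0.9  # month 8
        temps = np.arange(12, dtype=float) + 5.0
        topt = compute_topt(make_stack(temps), make_stack(fpar))
        assert topt.values == pytest.approx(temps[7])

    def test_tie_broken_by_earliest_month(self, make_stack):
        temps = np.linspace(-3, 14, 12)
        topt = compute_topt(make_stack(temps), make_stack(0.5))
        assert topt.values == pytest.approx(temps[0])

    def test_matches_scalar_argmax_oracle(self, make_stack):
        rng = np.random.default_rng(11)
        fpar = rng.random((12, 2, 2))
        temps = rng.normal(5, 10, (12, 2, 2))
        topt = compute_topt(make_stack(temps), make_stack(fpar))
        for r in range(2):
            for c in range(2):
                expect = ref.topt_scalar(list(fpar[:, r, c]), list(temps[:, r, c]))
                assert topt.values[r, c] == pytest.approx(expect)

    def test_all_masked_cell_is_masked(self, make_stack):
        mask = np.zeros((12, 2, 2), bool)
        mask[:, 1, 1] = True
        topt = compute_topt(make_stack(10.0), make_stack(0.5, mask=mask))
        assert topt.mask[1, 1] and not topt.mask[0, 0]


@pytest.mark.parametrize("topt, expected", [(20.0, 1.0), (0.0, 0.8), (40.0, 0.8)])
def test_te1_quadratic(make_grid, topt, expected):
    """Te1 peaks at 1.0 for a 20 degC optimum and falls to 0.8 at 0/40 degC."""
    out = temperature_stress_1(make_grid(np.full((2, 2), topt)))
    assert out.values == pytest.approx(expected)


@pytest.mark.parametrize(
    "topt, t, expected, tol",
    [
        (20.0, 20.0, 0.9912235531162353, 1e-12),
        (20.0, 30.0, 0.5800755457753924, 1e-12),
        (20.0, -40.0, 0.0, 1e-4),
    ],
)
def test_te2_hand_values(make_grid, make_stack, params, topt, t, expected, tol):
    out = temperature_stress_2(make_grid(np.full((2, 2), topt)), make_stack(t), params)
    assert out.values == pytest.approx(expected, abs=tol)


def test_te2_saturates_instead_of_overflowing(make_grid, make_stack, params):
    out = temperature_stress_2(
        make_grid(np.full((2, 2), 20.0)), make_stack(-1e6), params
    )
    assert np.all(np.isfinite(out.values)) and np.all(out.values >= 0)


@given(topt=st.floats(-10, 35), offset=st.floats(-60, 60))
@_hyp
def test_te2_bounded_and_near_unity_at_optimum(make_grid, make_stack, params, topt, offset):
    """Te2 stays in (0, 1.1814) and its maximum sits within 1% of T = Topt."""
    out = temperature_stress_2(
        make_grid(np.full((2, 2), topt)), make_stack(topt + offset), params
    )
    assert 0.0 < out.values[0, 0, 0] < params.te2_scale
    # numeric scan: Te2 depends only on T - Topt; its single peak sits just
    # above the optimum and exceeds Te2(Topt, Topt) by less than 1%
    ts = np.linspace(topt - 30, topt + 30, 601)
    vals = [ref.te2_scalar(topt, t, params) for t in ts]
    t_star = ts[int(np.argmax(vals))]
    assert abs(t_star - topt) <= 2.0
    assert max(vals) <= ref.te2_scalar(topt, topt, params) * 1.01


class TestDewPoint:
    def test_hand_values(self, make_stack, params):
        out = dew_point_from_precipitable_water(
            make_stack(math.exp(params.dew_intercept)), params
        )
        assert out.values == pytest.approx(0.0, abs=1e-12)
        out = dew_point_from_precipitable_water(make_stack(12.0), params)
        assert out.values == pytest.approx(9.20417210595919)

    def test_round_trip_with_forward_regression(self, make_stack, params):
        td = 7.3
        u = ref.precipitable_water_scalar(td, params)
        out = dew_point_from_precipitable_water(make_stack(u), params)
        assert out.values == pytest.approx(td, rel=1e-14)

    def test_nonpositive_water_masked(self, make_stack, params):
        vals = np.full((12, 2, 2), 10.0)
        vals[0, 0, 0] = -1.0
        out = dew_point_from_precipitable_water(make_stack(vals), params)
        assert out.mask[0, 0, 0] and out.mask.sum() == 1


class TestVPD:
    def test_zero_when_surface_at_or_below_dew_point(self, make_stack, params):
        same = vapor_pressure_deficit(make_stack(290.0), make_stack(290.0), params)
        assert same.values == pytest.approx(0.0, abs=1e-15)
        colder = vapor_pressure_deficit(make_stack(280.0), make_stack(290.0), params)
        assert colder.values == pytest.approx(0.0)

    def test_hand_value(self, make_stack, params):
        out = vapor_pressure_deficit(make_stack(293.0), make_stack(283.0), params)
        assert out.values == pytest.approx(1.1133080605354817)

    def test_degenerate_temperature_masked(self, make_stack, params):
        vals = np.full((12, 2, 2), 290.0)
        vals[0, 0, 0] = 30.0  # below the 36 K singularity
        out = vapor_pressure_deficit(make_stack(vals), make_stack(280.0), params)
        assert out.mask[0, 0, 0] and out.mask.sum() == 1


class TestWaterStress:
    @pytest.mark.parametrize(
        "d, expected",
        [(0.0, 1.0), (1.0, 0.6456257076624561), (20.0, 0.0)],
    )
    def test_hand_values(self, make_stack, params, d, expected):
        out = water_stress(make_stack(d), params)
        assert out.values == pytest.approx(expected)

    def test_negative_vpd_rejected(self, make_stack, params):
        with pytest.raises(ValueError, match="non-negative"):
            water_stress(make_stack(-0.5), params)

    @given(st.floats(0, 30), st.floats(0, 30))
    @_hyp
    def test_monotone_nonincreasing_and_bounded(self, make_stack, params, d1, d2):
        lo, hi = sorted([d1, d2])
        w_lo = water_stress(make_stack(lo), params).values[0, 0, 0]
        w_hi = water_stress(make_stack(hi), params).values[0, 0, 0]
        assert w_hi <= w_lo + 1e-12
        assert 0.0 <= w_hi <= w_lo <= 1.0


def test_lue_hand_values(make_grid, make_stack, params):
    ones = make_stack(1.0)
    out = compute_lue(make_grid(np.ones((2, 2))), ones, ones, params)
    assert out.values == pytest.approx(params.eps_max)
    out = compute_lue(make_grid(np.full((2, 2), 0.9)), make_stack(0.8), make_stack(0.7), params)
    assert out.values == pytest.approx(0.304416)
    out = compute_lue(make_grid(np.zeros((2, 2))), ones, ones, params)
    assert out.values == pytest.approx(0.0)


def test_npp_product_and_annual_conservation(make_stack):
    npp = compute_npp(make_stack(100.0), make_stack(0.25))
    assert npp.values == pytest.approx(25.0)
    rng = np.random.default_rng(5)
    vals = rng.random((12, 2, 2)) * 50
    mask = rng.random((12, 2, 2)) < 0.2
    stack = make_stack(vals, mask=mask)
    annual = annual_sum(stack)
    expect = np.where(mask, 0.0, vals).sum(axis=0)
    assert annual.values == pytest.approx(expect)
    assert np.array_equal(annual.mask, mask.all(axis=0))


def test_npp_bilinear_in_sol_and_lue_independent_of_it(scene16):
    """Scaling SOL by k scales APAR and NPP by k and leaves LUE untouched."""
    _, inputs, _ = scene16
    base = run_casa(inputs)
    scaled_inputs = CasaInputs(
        sol=GridStack(inputs.sol.values * 3.0, inputs.sol.georef, inputs.sol.mask.copy()),
        fpar=inputs.fpar, temperature=inputs.temperature,
        lst=inputs.lst, precipitable_water=inputs.precipitable_water,
    )
    scaled = run_casa(scaled_inputs)
    assert scaled.apar.values == pytest.approx(base.apar.values * 3.0)
    assert scaled.npp.values == pytest.approx(base.npp.values * 3.0)
    assert scaled.lue.values == pytest.approx(base.lue.values)


def test_run_casa_matches_scalar_oracle_on_random_grids(georef, params):
    """Every chained grid value equals the per-cell scalar-loop evaluation."""
    rng = np.random.default_rng(17)
    shape = (5, 7)
    sol = rng.uniform(100, 700, (12,) + shape)
    fpar = rng.uniform(0, 1, (12,) + shape)
    temp = rng.uniform(-15, 25, (12,) + shape)
    lst = temp + rng.uniform(0, 5, (12,) + shape) + 273.0
    pw = rng.uniform(1, 40, (12,) + shape)
    inputs = CasaInputs(
        sol=GridStack(sol, georef), fpar=GridStack(fpar, georef),
        temperature=GridStack(temp, georef), lst=GridStack(lst, georef),
        precipitable_water=GridStack(pw, georef),
    )
    out = run_casa(inputs, params)
    for r in range(shape[0]):
        for c in range(shape[1]):
            cell = ref.npp_chain_scalar(
                list(sol[:, r, c]), list(fpar[:, r, c]), list(temp[:, r, c]),
                list(lst[:, r, c]), list(pw[:, r, c]), params,
            )
            assert out.topt.values[r, c] == pytest.approx(cell["topt"], rel=1e-12)
            assert out.te1.values[r, c] == pytest.approx(cell["te1"], rel=1e-12)
            for m in range(12):
                assert out.npp.values[m, r, c] == pytest.approx(cell["npp"][m], rel=1e-9)
            assert out.npp_annual.values[r, c] == pytest.approx(cell["npp_annual"], rel=1e-9)


def test_run_casa_propagates_all_masked_fpar(scene16):
    _, inputs, _ = scene16
    masked = CasaInputs(
        sol=inputs.sol,
        fpar=GridStack(inputs.fpar.values, inputs.fpar.georef,
                       np.ones_like(inputs.fpar.values, bool)),
        temperature=inputs.temperature, lst=inputs.lst,
        precipitable_water=inputs.precipitable_water,
    )
    out = run_casa(masked)
    assert out.npp.mask.all() and out.npp_annual.mask.all()


def test_run_casa_rejects_misaligned_input(scene16, georef):
    _, inputs, _ = scene16
    bad = CasaInputs(
        sol=inputs.sol, fpar=inputs.fpar, temperature=inputs.temperature,
        lst=GridStack(np.full((12, 3, 3), 280.0), georef),
        precipitable_water=inputs.precipitable_water,
    )
    with pytest.raises(AlignmentError, match="lst"):
        run_casa(bad)
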
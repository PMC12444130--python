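"""Washout-model unit and property tests.

Closed-form expectations are computed by independent oracles inside the
tests: a truncated exponential series for e^(−1), forward-Euler integration
for e^(−2), and bisection on the forward model for the time inversion.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biliwash import (
    BilirubinSeries,
    ExchangeParams,
    ExtendedModelParams,
    concentration_at,
    simulate_extended,
    standard_curve,
    standard_rate,
    time_to_target,
)


def exp_by_series(x: float, terms: int = 40) -> float:
    """Independent evaluation of e^x by Taylor-series summation."""
    total, term = 0.0, 1.0
    for n in range(1, terms + 1):
        total += term
        term *= x / n
    return total


def euler_decay(c0: float, lam: float, t_end: float, h: float = 0.001) -> float:
    """Forward-Euler integration of db/dt = -lam*b, an independent oracle."""
    b = c0
    n = round(t_end / h)
    for _ in range(n):
        b -= h * lam * b
    return b


class TestConcentrationAt:
    def test_one_time_constant_matches_series_oracle(self, standard_params):
        expected = 498.1 * exp_by_series(-1.0)
        assert concentration_at(498.1, 60.0, standard_params) == pytest.approx(
            expected, rel=1e-12
        )
        assert round(concentration_at(498.1, 60.0, standard_params), 1) == 183.2

    def test_identity_at_t0_and_zero_rate(self, standard_params):
        assert concentration_at(498.1, 0.0, standard_params) == 498.1
        still = ExchangeParams(282.0, 0.0, 120.0)
        assert concentration_at(498.1, 90.0, still) == 498.1

    def test_two_time_constants_match_euler_oracle(self, standard_params):
        got = concentration_at(100.0, 120.0, standard_params)
        oracle = euler_decay(100.0, 1.0 / 60.0, 120.0)
        assert got == pytest.approx(oracle, rel=1e-4)
        assert got == pytest.approx(13.5335, abs=1e-3)

    @pytest.mark.parametrize(
        "c0,t,err",
        [(-1.0, 10.0, "c0"), (100.0, -5.0, "t")],
    )
    def test_negative_inputs_rejected_naming_argument(self, standard_params, c0, t, err):
        with pytest.raises(ValueError, match=err):
            concentration_at(c0, t, standard_params)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        c0=st.floats(0.0, 1e3),
        alpha=st.floats(0.0, 10.0),
        t=st.floats(0.0, 240.0),
    )
    def test_scale_equivariance(self, c0, alpha, t):
        params = ExchangeParams(282.0, standard_rate(282.0))
        lhs = concentration_at(alpha * c0, t, params)
        rhs = alpha * concentration_at(c0, t, params)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(t1=st.floats(0.0, 120.0), t2=st.floats(0.0, 120.0))
    def test_semigroup_property(self, t1, t2):
        params = ExchangeParams(282.0, standard_rate(282.0))
        direct = concentration_at(400.0, t1 + t2, params)
        staged = concentration_at(concentration_at(400.0, t1, params), t2, params)
        assert staged == pytest.approx(direct, rel=1e-12)

    def test_strictly_decreasing_in_time_and_rate(self):
        params = ExchangeParams(282.0, 4.7)
        ts = np.linspace(0, 120, 25)
        vals = concentration_at(498.1, ts, params)
        assert np.all(np.diff(vals) < 0)
        faster = ExchangeParams(282.0, 9.4)
        assert concentration_at(498.1, 60, faster) < concentration_at(498.1, 60, params)


class TestStandardRate:
    def test_double_volume_over_two_hours(self):
        assert standard_rate(282.0) == pytest.approx(4.7)
        assert standard_rate(60.0, 120.0, 2.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("v", [100.0, 282.0, 500.0])
    def test_standardized_curve_is_volume_invariant(self, v):
        params = ExchangeParams(v, standard_rate(v))
        ratio = concentration_at(321.0, 60.0, params) / 321.0
        assert ratio == pytest.approx(math.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("kwargs", [{"blood_volume_mL": 0.0},
                                        {"blood_volume_mL": 282.0, "duration_min": -1.0},
                                        {"blood_volume_mL": 282.0, "volumes_exchanged": 0.0}])
    def test_nonpositive_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            standard_rate(**kwargs)


class TestStandardCurve:
    def test_half_hour_grid_matches_closed_form(self, standard_params):
        times = [0, 30, 60, 90, 120]
        ser = standard_curve(498.1, standard_params, times)
        expected = [498.1 * exp_by_series(-t / 60.0) for t in times]
        np.testing.assert_allclose(ser.concentrations_umol_L, expected, rtol=1e-12)
        assert [round(x, 1) for x in ser.concentrations_umol_L] == [
            498.1, 302.1, 183.2, 111.1, 67.4,
        ]
        assert ser.label == "standard-model"

    def test_zero_baseline_and_zero_rate_degenerate_curves(self, standard_params):
        zero = standard_curve(0.0, standard_params, [0, 60, 120])
        assert np.all(zero.concentrations_umol_L == 0)
        const = standard_curve(498.1, ExchangeParams(282.0, 0.0), [0, 60, 120])
        assert np.all(const.concentrations_umol_L == 498.1)

    def test_empty_grid_rejected(self, standard_params):
        with pytest.raises(ValueError):
            standard_curve(498.1, standard_params, [])


class TestTimeToTarget:
    def test_matches_bisection_oracle(self, standard_params):
        target = 278.4
        lo, hi = 0.0, 500.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if concentration_at(498.1, mid, standard_params) > target:
                lo = mid
            else:
                hi = mid
        t = time_to_target(498.1, target, standard_params)
        assert t == pytest.approx((lo + hi) / 2, abs=1e-9)
        assert round(t, 1) == 34.9

    def test_round_trip_inverse(self, standard_params):
        t = time_to_target(498.1, 100.0, standard_params)
        assert concentration_at(498.1, t, standard_params) == pytest.approx(
            100.0, rel=1e-9
        )

    def test_trivial_and_exact_cases(self, standard_params):
        assert time_to_target(498.1, 498.1, standard_params) == 0.0
        assert time_to_target(498.1, 498.1 * math.exp(-1), standard_params) == (
            pytest.approx(60.0, rel=1e-12)
        )

    def test_invalid_targets_rejected(self, standard_params):
        with pytest.raises(ValueError, match="exceeds"):
            time_to_target(400.0, 500.0, standard_params)
        with pytest.raises(ValueError):
            time_to_target(400.0, 0.0, standard_params)
        with pytest.raises(ValueError, match="unreachable"):
            time_to_target(400.0, 200.0, ExchangeParams(282.0, 0.0))


class TestSimulateExtended:
    def test_zero_extension_reduces_to_closed_form(self, standard_params):
        times = np.arange(0.0, 121.0, 1.0)
        ser = simulate_extended(498.1, standard_params, ExtendedModelParams(), times)
        closed = concentration_at(498.1, times, standard_params)
        np.testing.assert_allclose(ser.concentrations_umol_L, closed, rtol=1e-6)

    def test_pure_production_is_linear_in_plasma(self):
        # no exchange, no tissue transfer: db/dt = p / (V in litres)
        params = ExchangeParams(282.0, 0.0)
        ext = ExtendedModelParams(production_umol_per_min=0.5)
        ser = simulate_extended(100.0, params, ext, [0.0, 30.0, 60.0])
        slope = 0.5 / 0.282
        np.testing.assert_allclose(
            ser.concentrations_umol_L, [100.0, 100.0 + 30 * slope, 100.0 + 60 * slope],
            rtol=1e-9,
        )

    def test_production_and_rebound_lift_the_curve(self, standard_params):
        times = np.arange(0.0, 121.0, 15.0)
        ext = ExtendedModelParams(0.5, 2.0, 282.0, 498.1)
        lifted = simulate_extended(498.1, standard_params, ext, times)
        base = concentration_at(498.1, times, standard_params)
        assert np.all(lifted.concentrations_umol_L[1:] > base[1:])
        # independent fine-step RK4 reference at the endpoint
        fine = simulate_extended(498.1, standard_params, ext, times, max_step_min=0.001)
        assert lifted.concentrations_umol_L[-1] == pytest.approx(
            fine.concentrations_umol_L[-1], rel=1e-9
        )

    def test_grid_must_start_at_zero(self, standard_params):
        with pytest.raises(ValueError):
            simulate_extended(498.1, standard_params, ExtendedModelParams(), [15.0, 30.0])


class TestDomainTypes:
    def test_series_invariants_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            BilirubinSeries([0.0, 10.0, 10.0], [3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="first sample"):
            BilirubinSeries([5.0, 10.0], [3.0, 2.0])
        with pytest.raises(ValueError, match="non-negative"):
            BilirubinSeries([0.0, 10.0], [3.0, -2.0])

    def test_exchange_params_volumes_exchanged(self):
        p = ExchangeParams(282.0, 4.7, 120.0)
        assert p.volumes_exchanged == pytest.approx(2.0)
        assert ExchangeParams.from_weight(3520.0).blood_volume_mL == pytest.approx(281.6)

    def test_extension_params_validation(self):
        with pytest.raises(ValueError):
            ExtendedModelParams(production_umol_per_min=-0.1)
        with pytest.raises(ValueError):
            ExtendedModelParams(transfer_mL_per_min=1.0, tissue_volume_mL=0.0)
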
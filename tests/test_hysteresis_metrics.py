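import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corneapuff import (
    DisplacementTrace,
    ForceTrace,
    HysteresisCurve,
    KVParams,
    PulseSpec,
    build_hysteresis,
    compute_all_metrics,
    generate_force_pulse,
    high_strain_slope,
    hysteresis_area,
    hysteresis_ratio,
    kv_response,
    loading_energy,
    low_strain_slope,
    secant_slope,
)
from corneapuff.errors import (
    AlignmentError,
    InsufficientDataError,
    InsufficientWindowError,
    NoDeformationError,
    SlopeUndefinedError,
    UndefinedRatioError,
)
from conftest import make_triangle_loop


def curve_from_arrays(x_um, F):
    split = int(np.argmax(x_um))
    return HysteresisCurve(x=np.asarray(x_um, float), F=np.asarray(F, float),
                           split_index=split, mad=float(x_um[split]))


def two_integral_oracle(h: HysteresisCurve) -> float:
    """Independent area: trapezoids over each branch, sorted ascending in x."""
    xl, Fl = h.loading
    xu, Fu = h.unloading
    up = np.trapezoid(Fl[np.argsort(xl)], np.sort(xl) * 1e-6)
    down = np.trapezoid(Fu[np.argsort(xu)], np.sort(xu) * 1e-6)
    return up - down


class TestBuildHysteresis:
    def test_identical_timestamps_pair_without_interpolation(self):
        t = np.linspace(0, 0.01, 100)
        x = DisplacementTrace(time=t, x=np.sin(np.pi * t / 0.01) * 500)
        f = ForceTrace(time=t, force=np.sin(np.pi * t / 0.01) * 0.1)
        h = build_hysteresis(x, f)
        np.testing.assert_array_equal(h.F, f.force)
        np.testing.assert_array_equal(h.x, x.x)

    def test_force_resampled_matches_linear_interpolation(self):
        """Piecewise-linear force at 2x rate resamples exactly."""
        tx = np.linspace(0, 0.01, 101)
        tf = np.linspace(0, 0.01, 201)
        f_lin = 5.0 * tf + 0.01  # linear in time => interp is exact
        x = DisplacementTrace(time=tx, x=np.sin(np.pi * tx / 0.01) * 500)
        h = build_hysteresis(x, ForceTrace(time=tf, force=f_lin))
        np.testing.assert_allclose(h.F, 5.0 * tx + 0.01, rtol=1e-12)

    def test_split_at_triangle_peak(self):
        t = np.arange(1600.0) / 50e3
        xx = np.concatenate([np.linspace(0, 1000, 801), np.linspace(1000, 0, 800)[1:]])
        x = DisplacementTrace(time=t, x=xx)
        f = ForceTrace(time=t, force=np.ones_like(t) * 0.1)
        h = build_hysteresis(x, f)
        assert h.split_index == 800
        assert h.mad == 1000.0

    def test_tie_at_maximum_breaks_to_earliest_sample(self):
        t = np.linspace(0, 1, 6)
        x = DisplacementTrace(time=t, x=np.array([0.0, 500.0, 500.0, 500.0, 200.0, 0.0]))
        f = ForceTrace(time=t, force=np.ones(6) * 0.1)
        assert build_hysteresis(x, f).split_index == 1

    def test_non_overlapping_clocks_raise(self):
        x = DisplacementTrace(time=np.linspace(0, 1, 10), x=np.ones(10))
        f = ForceTrace(time=np.linspace(5, 6, 10), force=np.ones(10))
        with pytest.raises(AlignmentError):
            build_hysteresis(x, f)

    def test_no_deformation_raises(self):
        t = np.linspace(0, 1, 10)
        x = DisplacementTrace(time=t, x=np.zeros(10))
        f = ForceTrace(time=t, force=np.ones(10))
        with pytest.raises(NoDeformationError):
            build_hysteresis(x, f)


class TestHysteresisArea:
    def test_reversible_loop_has_zero_area(self):
        x = np.concatenate([np.linspace(0, 1000, 50), np.linspace(1000, 0, 50)[1:]])
        F = 0.1 * x / 1000.0  # same path both ways
        assert hysteresis_area(curve_from_arrays(x, F)) == pytest.approx(0.0, abs=1e-18)

    def test_worked_example_linear_loading_quadratic_unloading(self):
        """Closed-form: 6e-5 J loading minus 4e-5 J unloading = 2e-5 J."""
        x, F = make_triangle_loop(n_load=5000, n_unload=5001)
        h = curve_from_arrays(x, F)
        assert hysteresis_area(h) == pytest.approx(2.0e-5, rel=1e-3)
        assert loading_energy(h) == pytest.approx(6.0e-5, rel=1e-3)
        # cross-check against the independent dense two-integral oracle
        assert hysteresis_area(h) == pytest.approx(two_integral_oracle(h), rel=1e-9)

    def test_kv_sinusoid_steady_state_ellipse(self):
        """Loop area of the steady-state ellipse is pi*c*w*X^2."""
        k, c, F0 = 100.0, 0.5, 0.1
        w = 2 * np.pi * 50.0
        t = np.arange(0.0, 0.4, 1e-5)
        f = ForceTrace(time=t, force=F0 * np.sin(w * t))
        xr = kv_response(f, KVParams(k=k, c=c))
        T = 2 * np.pi / w
        mask = (t >= 0.38) & (t < 0.38 + T)
        h = curve_from_arrays(xr.x[mask], f.force[mask])
        X = F0 / np.hypot(k, c * w)
        assert hysteresis_area(h) == pytest.approx(np.pi * c * w * X**2, rel=0.01)

    def test_too_few_points_rejected(self):
        from corneapuff.errors import CorneaPuffError

        with pytest.raises(CorneaPuffError):
            curve_from_arrays([0.0, 1.0, 0.5], [0.0, 1.0, 0.5])


class TestHysteresisRatio:
    def test_worked_example_ratio(self):
        x, F = make_triangle_loop(n_load=5000, n_unload=5001)
        assert hysteresis_ratio(curve_from_arrays(x, F)) == pytest.approx(100 / 3, rel=1e-3)

    def test_reversible_loop_zero_ratio(self):
        x = np.concatenate([np.linspace(0, 800, 40), np.linspace(800, 0, 40)[1:]])
        F = 0.1 * (x / 800.0) ** 1.5
        assert hysteresis_ratio(curve_from_arrays(x, F)) == pytest.approx(0.0, abs=1e-9)

    def test_total_dissipation_is_100pct(self):
        # force drops vertically to zero at the peak, then unloads at F = 0
        x_up = np.linspace(0, 800.0, 41)
        x_down = np.concatenate([[800.0], np.linspace(800.0, 0, 41)[1:]])
        x = np.concatenate([x_up, x_down])
        F = np.concatenate([0.1 * x_up / 800.0, np.zeros(41)])
        assert hysteresis_ratio(curve_from_arrays(x, F)) == pytest.approx(100.0, rel=1e-6)

    def test_zero_loading_energy_rejected(self):
        x = np.concatenate([np.linspace(0, 800, 40), np.linspace(800, 0, 40)[1:]])
        F = np.where(np.arange(len(x)) < 40, 0.0, 0.1)
        with pytest.raises(UndefinedRatioError):
            hysteresis_ratio(curve_from_arrays(x, F))


class TestSlopes:
    def test_linear_loading_secant_equals_stiffness(self):
        x = np.concatenate([np.linspace(0, 1000, 500), np.linspace(1000, 0, 500)[1:]])
        F = 100.0 * x * 1e-6  # k = 100 N/m
        h = curve_from_arrays(x, F)
        assert secant_slope(h) == pytest.approx(100.0, rel=1e-9)
        assert low_strain_slope(h) == pytest.approx(100.0, rel=1e-9)
        assert high_strain_slope(h) == pytest.approx(100.0, rel=1e-9)

    def test_quadratic_loading_secant_algebraic(self):
        """F = a x^2 gives S_sec = 1.1 * a * MAD."""
        a = 80.0  # N/m^2 scale in SI after conversion
        mad_um = 1000.0
        x = np.concatenate([np.linspace(0, mad_um, 2000),
                            np.linspace(mad_um, 0, 2000)[1:]])
        F = a * (x * 1e-6) ** 2
        h = curve_from_arrays(x, F)
        assert secant_slope(h) == pytest.approx(1.1 * a * mad_um * 1e-6, rel=1e-6)

    def test_constant_force_zero_secant(self):
        x = np.concatenate([np.linspace(0, 1000, 100), np.linspace(1000, 0, 100)[1:]])
        F = np.full_like(x, 0.05)
        assert secant_slope(curve_from_arrays(x, F)) == pytest.approx(0.0, abs=1e-12)

    def test_bilinear_loading_recovers_both_segment_slopes(self):
        """Piecewise slopes 44 then 82 N/m are recovered exactly."""
        x_up = np.linspace(0, 600.0, 1201)
        F_up = np.where(x_up <= 300.0, 44.0 * x_up * 1e-6,
                        44.0 * 300e-6 + 82.0 * (x_up - 300.0) * 1e-6)
        x = np.concatenate([x_up, np.linspace(600.0, 0, 1201)[1:]])
        F = np.concatenate([F_up, F_up[::-1][1:]])
        h = curve_from_arrays(x, F)
        assert low_strain_slope(h) == pytest.approx(44.0, rel=1e-6)
        assert high_strain_slope(h) == pytest.approx(82.0, rel=1e-6)

    def test_j_curve_high_strain_exceeds_low_strain(self):
        """Convex (J-shaped) loading is stiffer at high strain."""
        x_up = np.linspace(0, 900.0, 2000)
        F_up = 0.01 * (np.exp(3.0 * x_up / 900.0) - 1.0)
        x = np.concatenate([x_up, np.linspace(900.0, 0, 2000)[1:]])
        F = np.concatenate([F_up, F_up[::-1][1:]])
        h = curve_from_arrays(x, F)
        s_lo, s_hi = low_strain_slope(h), high_strain_slope(h)
        assert s_hi > s_lo
        assert s_lo < secant_slope(h) < s_hi

    def test_window_exceeding_mad_rejected(self):
        """MAD = 130 um puts the low-strain window past the loading span."""
        x = np.concatenate([np.linspace(0, 130.0, 200), np.linspace(130.0, 0, 200)[1:]])
        F = 0.05 * x / 130.0
        h = curve_from_arrays(x, F)
        with pytest.raises(InsufficientWindowError):
            low_strain_slope(h)

    def test_short_loading_span_rejected_for_high_strain(self):
        x = np.concatenate([np.linspace(0, 100.0, 100), np.linspace(100.0, 0, 100)[1:]])
        F = 0.05 * x / 100.0
        with pytest.raises(InsufficientWindowError):
            high_strain_slope(curve_from_arrays(x, F))

    def test_never_reaching_10pct_mad_impossible_by_construction(self):
        # a loading branch starting above 10% MAD uses its first sample
        x = np.concatenate([np.linspace(500.0, 1000.0, 50),
                            np.linspace(1000.0, 0.0, 50)[1:]])
        F = 100.0 * x * 1e-6
        assert secant_slope(curve_from_arrays(x, F)) == pytest.approx(100.0, rel=1e-9)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**20))
def test_shoelace_equals_two_integral_form_on_monotone_loops(seed):
    """Loop line integral equals the difference of branch integrals."""
    rng = np.random.default_rng(seed)
    mad = rng.uniform(100.0, 2000.0)
    n_up = rng.integers(5, 60)
    n_down = rng.integers(5, 60)
    x_up = np.sort(rng.uniform(0, mad, n_up))
    x_up[0], x_up[-1] = 0.0, mad
    x_down = np.sort(rng.uniform(0, mad, n_down))[::-1]
    x_down[0], x_down[-1] = mad, 0.0
    F_up = rng.uniform(0, 0.2, n_up)
    F_down = rng.uniform(0, 0.2, n_down)
    x = np.concatenate([x_up, x_down[1:]])
    F = np.concatenate([F_up, F_down[1:]])
    h = curve_from_arrays(x, F)
    oracle = two_integral_oracle(h)
    scale = abs(np.trapezoid(F_up, x_up * 1e-6)) + abs(np.trapezoid(F_down[::-1], x_down[::-1] * 1e-6))
    assert abs(hysteresis_area(h) - oracle) <= 1e-9 * max(scale, 1e-12)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(c=st.floats(0.0, 1.5), k=st.floats(50.0, 400.0))
def test_kv_loops_are_passively_dissipative(c, k):
    """HA >= 0 and 0 <= HR <= 100 for any Kelvin-Voigt loop with c >= 0."""
    f = generate_force_pulse(PulseSpec())
    x = kv_response(f, KVParams(k=k, c=c))
    h = build_hysteresis(x, f)
    ha = hysteresis_area(h)
    assert ha >= -1e-15
    hr = hysteresis_ratio(h)
    assert -1e-9 <= hr <= 100.0 + 1e-9


def test_ha_monotone_in_c_and_vanishing_in_elastic_limit():
    f = generate_force_pulse(PulseSpec())
    has = []
    for c in [0.0, 0.1, 0.25, 0.5, 1.0]:
        x = kv_response(f, KVParams(k=120.0, c=c))
        has.append(hysteresis_area(build_hysteresis(x, f)))
    assert abs(has[0]) < 1e-15
    assert np.all(np.diff(has) > 0)


def test_secant_slope_bounded_by_local_slopes_for_monotone_loading():
    x_up = np.linspace(0, 800.0, 400)
    F_up = 0.02 * (np.exp(2.5 * x_up / 800.0) - 1.0)
    x = np.concatenate([x_up, np.linspace(800.0, 0, 400)[1:]])
    F = np.concatenate([F_up, F_up[::-1][1:]])
    h = curve_from_arrays(x, F)
    local = np.diff(F_up) / (np.diff(x_up) * 1e-6)
    assert local.min() <= secant_slope(h) <= local.max()


def test_unit_coherence_of_area():
    """HA in joules equals the um-N shoelace sum times 1e-6."""
    x, F = make_triangle_loop(n_load=300, n_unload=301)
    h = curve_from_arrays(x, F)
    raw = 0.5 * np.sum((F + np.roll(F, -1)) * (np.roll(x, -1) - x))
    assert hysteresis_area(h) == pytest.approx(raw * 1e-6, rel=1e-12)


class TestComputeAllMetrics:
    def test_full_synthetic_record_populates_all_metrics(self, phantom_response):
        f, x = phantom_response
        from corneapuff import CCTTriplet
        cct = CCTTriplet(cct_bef=1000.0, cct_max=970.0, cct_aft=999.0)
        m = compute_all_metrics(x, f, cct)
        vals = m.to_dict()
        assert all(np.isfinite(v) for v in vals.values()), m.failures
        assert not m.failures

    def test_missing_cct_flags_thickness_only(self, phantom_response):
        f, x = phantom_response
        m = compute_all_metrics(x, f, cct=None)
        assert np.isnan(m.cct_bef)
        assert "cct" in m.failures
        assert np.isfinite(m.ha) and np.isfinite(m.mad)

    def test_deterministic(self, phantom_response):
        f, x = phantom_response
        m1 = compute_all_metrics(x, f)
        m2 = compute_all_metrics(x, f)
        assert m1.to_dict() == m2.to_dict()
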